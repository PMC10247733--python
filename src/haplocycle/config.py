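"""Simulation and pipeline configuration.

The cell-cycle model lives on the unit circle: each of the five phases
(G1S, S, G2, G2M, MG1, in progression order) owns a fixed arc of width
2*pi/5, and a cell's true phase is the phase whose arc contains its angular
position theta.  Dwell fractions control how much of a group's population
sits in each arc; ploidy groups share the arcs (so gene programs peak at
the same angles in both groups) but differ in occupancy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

#: Cell-cycle phases in progression order.
PHASES: tuple[str, ...] = ("G1S", "S", "G2", "G2M", "MG1")

#: Group labels used throughout: "haploid" = near-haploid, "diploid" = diploidized.
GROUPS: tuple[str, str] = ("haploid", "diploid")

_ARC = 2.0 * np.pi / len(PHASES)


def phase_arc(phase: str) -> tuple[float, float]:
    """Half-open angular interval [lo, hi) owned by ``phase``."""
    i = PHASES.index(phase)
    return i * _ARC, (i + 1) * _ARC


def phase_center(phase: str) -> float:
    """Peak angle of genes belonging to ``phase`` (arc midpoint)."""
    lo, hi = phase_arc(phase)
    return 0.5 * (lo + hi)


def phase_of_angle(theta: float | np.ndarray) -> np.ndarray:
    """Phase label(s) for angular position(s) in [0, 2*pi)."""
    idx = np.floor(np.asarray(theta) / _ARC).astype(int) % len(PHASES)
    return np.asarray(PHASES)[idx]


def _default_dwell() -> dict[str, dict[str, float]]:
    # Haploid cells dwell longer in G2/G2M and shorter in S than diploid
    # cells; exact fractions are a modeling choice (see docs/methods.md).
    return {
        "haploid": {"G1S": 0.25, "S": 0.20, "G2": 0.17, "G2M": 0.23, "MG1": 0.15},
        "diploid": {"G1S": 0.30, "S": 0.25, "G2": 0.15, "G2M": 0.15, "MG1": 0.15},
    }


@dataclass
class BulkConfig:
    """Bulk RNA-seq emulation: gene rows plus ERCC spike-in rows.

    Samples are haploid/diploid clones; spike-in true abundance is identical
    across samples while gene abundance scales with the group dosage factor,
    and every row is multiplied by a sample depth factor.
    """

    n_genes: int = 500
    n_ercc: int = 20
    n_samples_per_group: int = 3
    depth_factors: tuple[float, ...] | None = None  # len = 2 * n_samples_per_group
    mean_count: float = 200.0
    noise: str = "poisson"  # "poisson" | "none"


@dataclass
class ScreenConfig:
    """Pooled CRISPR knockout screen emulation with planted haploid essentials."""

    n_genes: int = 400
    guides_per_gene: int = 4
    n_control_guides: int = 200  # non-targeting controls
    n_essential: int = 20  # haploid-specific essential genes
    depletion_log2: float = 3.0  # guide abundance x 2^-d in the haploid endpoint
    mean_guide_count: float = 400.0
    nb_dispersion: float = 0.05


@dataclass
class FociConfig:
    """DNA-damage foci emulation.

    Per-cell DAPI intensity follows a two-mode (G1-like / G2-like) mixture
    scaled by ploidy; gamma-H2AX focus counts are Poisson with mean
    damage_rate x DNA content; a set fraction of gamma-H2AX foci receive a
    RAD51 partner within the co-localization radius.
    """

    n_cells_per_group: int = 300
    n_replicates: int = 3
    damage_rate: float = 4.0  # mean gH2AX foci per haploid genome equivalent
    coloc_fraction: float = 0.7
    rad51_background: float = 1.0  # mean unmatched RAD51 foci per cell
    nucleus_size: float = 30.0  # square field side, image units
    match_radius: float = 0.5
    dapi_cv: float = 0.08  # lognormal sigma of intensity around each mode
    g2_fraction: float = 0.3  # fraction of cells in the 2x-content mode


@dataclass
class SimConfig:
    """Generator configuration for the synthetic two-ploidy single-cell study.

    ``dosage_factor`` is the diploid per-cell transcript scale relative to
    haploid (the pure genome-doubling expectation is 2.0).  ``dwell_fractions``
    maps group -> phase -> occupancy fraction (must sum to 1 per group).
    Planted stage-specific dosage deviations multiply diploid-cell expression
    of ``n_deviant_genes`` genes by ``2**deviation_log2`` only in
    ``deviation_stage``, on top of the global dosage factor.
    """

    n_cells_per_group: int = 2000
    n_genes: int = 2000
    n_signature_genes_per_phase: int = 40
    dosage_factor: float = 2.0
    dwell_fractions: dict[str, dict[str, float]] = field(default_factory=_default_dwell)
    program_amplitude: float = 3.0  # fold-elevation of a phase gene at its peak
    program_concentration: float = 8.0  # cosine-bump sharpness (higher = narrower)
    nb_dispersion: float = 0.5  # NB: var = mu + alpha * mu^2; 0 = Poisson
    dropout_rate: float = 0.1
    mean_depth: float = 5000.0  # expected total UMIs per haploid cell
    n_deviant_genes: int = 0
    deviation_stage: str = "G2M"
    deviation_log2: float = -0.5
    seed: int = 0
    bulk: BulkConfig = field(default_factory=BulkConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    foci: FociConfig = field(default_factory=FociConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_cells_per_group", "n_genes", "n_signature_genes_per_phase"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.dosage_factor <= 0:
            raise ConfigError("dosage_factor must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigError("dropout_rate must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.program_amplitude <= 0:
            raise ConfigError("program_amplitude must be > 0")
        if self.deviation_stage not in PHASES:
            raise ConfigError(f"deviation_stage must be one of {PHASES}")
        for group, dwell in self.dwell_fractions.items():
            if set(dwell) != set(PHASES):
                raise ConfigError(f"dwell_fractions[{group!r}] must cover exactly {PHASES}")
            total = sum(dwell.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"dwell_fractions[{group!r}] sum to {total!r}, expected 1 +- 1e-9"
                )
            if any(f < 0 for f in dwell.values()):
                raise ConfigError(f"dwell_fractions[{group!r}] contains negatives")
        if 5 * self.n_signature_genes_per_phase + self.n_deviant_genes > self.n_genes:
            raise ConfigError("n_genes too small for signature + deviant genes")


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def save_config(cfg: SimConfig, path: str | Path) -> None:
    """Write a SimConfig as nested-section YAML."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML written by :func:`save_config` (missing
    keys take defaults; unknown keys are a config error)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    sub = {}
    for name, cls in (("bulk", BulkConfig), ("screen", ScreenConfig), ("foci", FociConfig)):
        if name in raw:
            block = raw.pop(name) or {}
            unknown = set(block) - {f.name for f in dataclasses.fields(cls)}
            if unknown:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
            if "depth_factors" in block and block["depth_factors"] is not None:
                block["depth_factors"] = tuple(block["depth_factors"])
            sub[name] = cls(**block)
    unknown = set(raw) - {f.name for f in dataclasses.fields(SimConfig)}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return SimConfig(**raw, **sub)
    except TypeError as exc:  # e.g. wrong value type
        raise ConfigError(str(exc)) from exc
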