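"""Synthetic-data generators for the two-ploidy single-cell study design.

The single-cell generator emulates the statistical structure the analysis
assumes: two populations (near-haploid and diploidized) whose per-cell total
transcript content differs by a global dosage factor; cyclic cell-cycle gene
programs (cosine bumps on the circle, peaking at each phase's arc center)
with ploidy-specific phase dwell fractions; negative-binomial counting noise
and Bernoulli dropout; optionally, stage-specific dosage deviations planted
in the diploid group for recovery tests.

Companion generators produce bulk count tables with ERCC spike-in rows, a
pooled-screen guide count table with planted haploid-essential genes, and a
DNA-damage foci table with a configured gamma-H2AX / RAD51 co-localization
fraction.

Each ``simulate_*`` call draws from its own RNG stream derived from
``(config.seed, call name)``, so generators are individually reproducible
and mutually independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import GROUPS, PHASES, FociConfig, SimConfig, phase_center, phase_of_angle
from .errors import ConfigError
from .io import GeneSet

__all__ = [
    "GroundTruth",
    "BulkTruth",
    "simulate_cells",
    "simulate_bulk",
    "simulate_screen",
    "simulate_foci",
]


def _rng(seed: int, call: str) -> np.random.Generator:
    """One stream per simulate_* call, derived from seed + call name."""
    return np.random.default_rng([seed, zlib.crc32(call.encode())])


@dataclass
class GroundTruth:
    """Generating truth for :func:`simulate_cells`.

    ``cells`` has one row per cell: group, true_phase, true_theta.
    ``genes`` has one row per gene: phase ("" for non-program genes),
    deviation_stage, deviation_log2 (0 if not planted).
    """

    cells: pd.DataFrame
    genes: pd.DataFrame

    def phase_gene_sets(self) -> list[GeneSet]:
        """Per-phase signature gene sets from the generating memberships."""
        return [
            GeneSet(p, set(self.genes.index[self.genes["phase"] == p]))
            for p in PHASES
        ]

    @property
    def deviant_genes(self) -> pd.Index:
        return self.genes.index[self.genes["deviation_log2"] != 0.0]


def _program_factor(theta: np.ndarray, peak: float, amplitude: float, kappa: float) -> np.ndarray:
    """Cosine-bump expression factor in [1, amplitude], peaking at ``peak``."""
    bump = ((1.0 + np.cos(theta - peak)) / 2.0) ** kappa
    return 1.0 + (amplitude - 1.0) * bump


def _sample_theta(rng: np.random.Generator, dwell: dict[str, float], n: int) -> np.ndarray:
    """Angles from the group's dwell distribution: phase ~ Categorical(dwell),
    theta ~ Uniform(phase arc)."""
    probs = np.array([dwell[p] for p in PHASES])
    phase_idx = rng.choice(len(PHASES), size=n, p=probs)
    arc = 2.0 * np.pi / len(PHASES)
    return (phase_idx + rng.uniform(size=n)) * arc


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via Gamma-Poisson; alpha=0 is Poisson."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a cells x genes UMI count matrix for the two ploidy groups.

    Per-gene mean for a cell at angle theta is
    ``baseline * program_factor(theta) * group_dosage * 2**planted_deviation``;
    counts are NB-sampled then thinned by dropout.  Returns an AnnData with
    sparse integer ``X``, obs columns ``group``, ``true_phase``,
    ``true_theta``, and var columns ``phase``, ``deviation_stage``,
    ``deviation_log2``, alongside the same truth as a :class:`GroundTruth`.
    """
    config.validate()
    rng = _rng(config.seed, "simulate_cells")
    n, g = config.n_cells_per_group, config.n_genes

    gene_ids = np.array([f"g{i:05d}" for i in range(g)])
    gene_phase = np.full(g, "", dtype=object)
    k = config.n_signature_genes_per_phase
    for i, p in enumerate(PHASES):
        gene_phase[i * k : (i + 1) * k] = p
    # planted deviant genes drawn from the non-program tail
    dev_log2 = np.zeros(g)
    if config.n_deviant_genes:
        dev_idx = np.arange(5 * k, 5 * k + config.n_deviant_genes)
        dev_log2[dev_idx] = config.deviation_log2

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    # normalize so a haploid cell at a uniform angle averages mean_depth UMIs
    grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    mean_factor = np.ones(g)
    for p in PHASES:
        sel = gene_phase == p
        mean_factor[sel] = _program_factor(
            grid[:, None], phase_center(p), config.program_amplitude,
            config.program_concentration,
        ).mean()
    baseline *= config.mean_depth / float(baseline @ mean_factor)

    peaks = np.array([phase_center(p) if p else np.nan for p in gene_phase])
    blocks, obs_rows = [], []
    for group in GROUPS:
        theta = _sample_theta(rng, config.dwell_fractions[group], n)
        true_phase = phase_of_angle(theta)
        factor = np.ones((n, g))
        prog = ~np.isnan(peaks)
        factor[:, prog] = _program_factor(
            theta[:, None], peaks[prog][None, :], config.program_amplitude,
            config.program_concentration,
        )
        dosage = config.dosage_factor if group == "diploid" else 1.0
        mu = baseline[None, :] * factor * dosage
        if group == "diploid" and config.n_deviant_genes:
            in_stage = true_phase == config.deviation_stage
            mu[np.ix_(in_stage, dev_log2 != 0.0)] *= 2.0 ** config.deviation_log2
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        if config.dropout_rate > 0:
            counts = rng.binomial(counts, 1.0 - config.dropout_rate)
        blocks.append(sparse.csr_matrix(counts))
        obs_rows.append(pd.DataFrame({
            "group": group, "true_phase": true_phase, "true_theta": theta,
        }))

    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = pd.Index([f"cell{i:05d}" for i in range(len(obs))], name="cell_id")
    var = pd.DataFrame(
        {
            "phase": gene_phase,
            "deviation_stage": np.where(dev_log2 != 0.0, config.deviation_stage, ""),
            "deviation_log2": dev_log2,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    adata = ad.AnnData(X=sparse.vstack(blocks).tocsr(), obs=obs, var=var)
    truth = GroundTruth(cells=obs.copy(), genes=var.copy())
    return adata, truth


@dataclass
class BulkTruth:
    """Closed-form expectations behind :func:`simulate_bulk`."""

    gene_abundance: pd.Series  # per-gene haploid-sample abundance
    depth_factors: pd.Series  # per-sample depth multiplier
    dosage_factor: float  # diploid/haploid gene ratio


def simulate_bulk(config: SimConfig) -> tuple[pd.DataFrame, BulkTruth]:
    """Bulk count table: gene rows plus ERCC spike-in rows.

    Spike-in true abundance is identical across samples; gene abundance
    carries the group dosage factor in diploid samples; every row is scaled
    by a per-sample depth factor.  ``noise="none"`` returns exact expected
    values (closed-form testable); ``"poisson"`` adds counting noise.
    """
    bc = config.bulk
    if bc.n_ercc < 1:
        raise ConfigError("bulk.n_ercc must be >= 1")
    rng = _rng(config.seed, "simulate_bulk")
    n_samples = 2 * bc.n_samples_per_group
    depth = bc.depth_factors
    if depth is None:
        depth = tuple(rng.uniform(0.5, 2.0, size=n_samples))
    if len(depth) != n_samples:
        raise ConfigError(
            f"bulk.depth_factors must have length {n_samples}, got {len(depth)}"
        )
    samples = [f"haploid_{i+1}" for i in range(bc.n_samples_per_group)] + [
        f"diploid_{i+1}" for i in range(bc.n_samples_per_group)
    ]
    gene_ids = [f"b{i:05d}" for i in range(bc.n_genes)]
    ercc_ids = [f"ERCC-{i+1:05d}" for i in range(bc.n_ercc)]
    gene_ab = rng.lognormal(np.log(bc.mean_count), 1.0, size=bc.n_genes)
    ercc_ab = rng.lognormal(np.log(bc.mean_count), 1.0, size=bc.n_ercc)

    cols = {}
    for j, s in enumerate(samples):
        dosage = config.dosage_factor if s.startswith("diploid") else 1.0
        expected = np.concatenate([gene_ab * dosage, ercc_ab]) * depth[j]
        if bc.noise == "poisson":
            cols[s] = rng.poisson(expected).astype(float)
        elif bc.noise == "none":
            cols[s] = expected
        else:
            raise ConfigError(f"unknown bulk.noise {bc.noise!r}")
    table = pd.DataFrame(cols, index=pd.Index(gene_ids + ercc_ids, name="gene_id"))
    truth = BulkTruth(
        gene_abundance=pd.Series(gene_ab, index=gene_ids),
        depth_factors=pd.Series(depth, index=samples),
        dosage_factor=config.dosage_factor,
    )
    return table, truth


def simulate_screen(config: SimConfig) -> tuple[pd.DataFrame, list[str]]:
    """Guide count table (input, haploid_end, diploid_end) with planted
    haploid-essential genes.

    Planted genes have every guide's abundance multiplied by
    ``2**-depletion_log2`` in the haploid endpoint only.  Non-targeting
    control guides map to gene ``"control"``.  Returns (table, planted gene
    list).
    """
    scfg = config.screen
    rng = _rng(config.seed, "simulate_screen")
    genes = [f"s{i:04d}" for i in range(scfg.n_genes)]
    essential = list(rng.choice(genes, size=scfg.n_essential, replace=False))
    rows = []
    for gene in genes + ["control"]:
        n_guides = scfg.guides_per_gene if gene != "control" else scfg.n_control_guides
        for j in range(n_guides):
            rows.append((f"{gene}_sg{j+1}", gene))
    guide_df = pd.DataFrame(rows, columns=["guide", "gene"])
    n_guides_total = len(guide_df)
    abundance = rng.lognormal(np.log(scfg.mean_guide_count), 0.5, size=n_guides_total)
    depleted = guide_df["gene"].isin(essential).to_numpy()
    out = {}
    for sample in ("input", "haploid_end", "diploid_end"):
        mu = abundance.copy()
        if sample == "haploid_end":
            mu[depleted] *= 2.0 ** -scfg.depletion_log2
        out[sample] = _nb_counts(rng, mu, scfg.nb_dispersion)
    table = pd.concat([guide_df, pd.DataFrame(out)], axis=1)
    return table, sorted(essential)


def simulate_foci(config: SimConfig) -> "FociTable":
    """Per-cell DAPI intensities and gamma-H2AX / RAD51 focus centroids.

    DNA content is a two-mode mixture (1x / 2x the group ploidy); gamma-H2AX
    counts are Poisson(damage_rate x content); a ``coloc_fraction`` of
    gamma-H2AX foci get a RAD51 focus within ``match_radius``; remaining
    RAD51 foci are uniform background.
    """
    from .foci import FociTable  # local import to avoid a cycle

    fc: FociConfig = config.foci
    rng = _rng(config.seed, "simulate_foci")
    cell_rows, focus_rows = [], []
    cid = 0
    for rep in range(1, fc.n_replicates + 1):
        for group in GROUPS:
            ploidy = 2.0 if group == "diploid" else 1.0
            for _ in range(fc.n_cells_per_group):
                cid += 1
                cell_id = f"fc{cid:06d}"
                content = ploidy * (2.0 if rng.uniform() < fc.g2_fraction else 1.0)
                dapi = content * rng.lognormal(0.0, fc.dapi_cv)
                n_gh = rng.poisson(fc.damage_rate * content)
                gx = rng.uniform(0, fc.nucleus_size, size=n_gh)
                gy = rng.uniform(0, fc.nucleus_size, size=n_gh)
                for x, y in zip(gx, gy):
                    focus_rows.append((cell_id, "gH2AX", x, y))
                # matched RAD51 foci: offset uniformly within 0.9 * radius
                matched = rng.uniform(size=n_gh) < fc.coloc_fraction
                r = 0.9 * fc.match_radius * np.sqrt(rng.uniform(size=n_gh))
                ang = rng.uniform(0, 2 * np.pi, size=n_gh)
                for i in np.flatnonzero(matched):
                    focus_rows.append(
                        (cell_id, "RAD51", gx[i] + r[i] * np.cos(ang[i]),
                         gy[i] + r[i] * np.sin(ang[i]))
                    )
                for _ in range(rng.poisson(fc.rad51_background)):
                    focus_rows.append(
                        (cell_id, "RAD51", rng.uniform(0, fc.nucleus_size),
                         rng.uniform(0, fc.nucleus_size))
                    )
                cell_rows.append((cell_id, group, rep, dapi))
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "group", "replicate", "dapi_intensity"]
    ).set_index("cell_id")
    foci = pd.DataFrame(focus_rows, columns=["cell_id", "channel", "x", "y"])
    return FociTable(cells=cells, foci=foci)
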