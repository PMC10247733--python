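"""Cell-cycle phase scoring from five metagene signatures.

Each phase signature (G1S, S, G2, G2M, MG1) is first filtered against the
dataset: a gene must be detected (raw UMI > 0) in at least a minimum
fraction of cells and must correlate (Pearson r above a threshold) with the
mean imputed expression of the detection-passing signature genes.  Each
cell's phase score is the mean z-scored imputed expression over the
retained members; the argmax score assigns the phase, with exact ties left
"unassigned" so downstream proportions are not biased by ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import PHASES
from .errors import DegenerateDataError, ParameterError
from .io import GeneSet

__all__ = [
    "SignatureFilterParams",
    "filter_signature",
    "score_phases",
    "phase_proportions",
]

UNASSIGNED = "unassigned"


@dataclass
class SignatureFilterParams:
    min_expressing_fraction: float = 0.05
    r_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.min_expressing_fraction <= 1:
            raise ParameterError("min_expressing_fraction must be in [0, 1]")
        if not 0 <= self.r_min <= 1:
            raise ParameterError("r_min must be in [0, 1]")


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x, dtype=float)


def _pearson_vs_mean(expr: np.ndarray, mean_profile: np.ndarray) -> np.ndarray:
    """Pearson r of each column of expr with mean_profile; 0 where either
    side is constant."""
    xc = expr - expr.mean(axis=0)
    mc = mean_profile - mean_profile.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (mc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ mc) / denom
    return np.where(np.isfinite(r), r, 0.0)


def filter_signature(
    adata: ad.AnnData,
    sig: GeneSet,
    params: SignatureFilterParams | None = None,
    layer: str = "imputed",
    group_col: str | None = "group",
) -> GeneSet:
    """Dataset-specific signature filtering.

    Stage (i): keep members detected (raw UMI > 0) in at least
    ``min_expressing_fraction`` of cells.  Stage (ii): keep those whose
    imputed expression has Pearson r >= ``r_min`` with the mean imputed
    expression of the stage-(i) set (the mean is computed once, over the
    stage-(i) genes).  When ``group_col`` names an obs column, the
    correlation test runs within each group and a gene passes if it passes
    in either group (the permissive choice for mixed-ploidy datasets);
    ``group_col=None`` uses all cells jointly.
    """
    params = params or SignatureFilterParams()
    present = [g for g in sorted(sig.members) if g in adata.var_names]
    if not present:
        raise DegenerateDataError(
            f"signature {sig.name!r}: no members present in the dataset"
        )
    raw = _dense(adata[:, present].X)
    detected_frac = (raw > 0).mean(axis=0)
    stage1 = [g for g, f in zip(present, detected_frac)
              if f >= params.min_expressing_fraction]
    if not stage1:
        raise DegenerateDataError(
            f"signature {sig.name!r}: no members detected in >= "
            f"{params.min_expressing_fraction:.0%} of cells"
        )
    imputed = _dense(adata[:, stage1].layers[layer])
    if group_col is not None and group_col in adata.obs:
        groups = adata.obs[group_col].to_numpy()
        passed = np.zeros(len(stage1), dtype=bool)
        for grp in pd.unique(groups):
            sub = imputed[groups == grp]
            r = _pearson_vs_mean(sub, sub.mean(axis=1))
            passed |= r >= params.r_min
    else:
        r = _pearson_vs_mean(imputed, imputed.mean(axis=1))
        passed = r >= params.r_min
    kept = [g for g, p in zip(stage1, passed) if p]
    if not kept:
        raise DegenerateDataError(
            f"signature {sig.name!r}: no members with r >= {params.r_min} "
            "against the signature mean"
        )
    return GeneSet(sig.name, set(kept))


def score_phases(
    adata: ad.AnnData,
    signatures: list[GeneSet],
    layer: str = "imputed",
    zscore: bool = True,
) -> pd.DataFrame:
    """Per-cell metagene scores and phase assignment.

    Each gene of ``layer`` is standardized across cells (optional raw-mean
    mode with ``zscore=False``); a phase score is the per-cell mean over the
    signature's members; the assigned phase achieves the maximum score, with
    exact ties mapped to ``"unassigned"``.

    Returns a DataFrame indexed by cell id with one column per phase plus
    ``"phase"``.
    """
    by_name = {s.name: s for s in signatures}
    missing = [p for p in PHASES if p not in by_name]
    if missing:
        raise ParameterError(f"missing phase signatures: {missing}")
    scores = {}
    for phase in PHASES:
        members = [g for g in sorted(by_name[phase].members) if g in adata.var_names]
        if not members:
            raise DegenerateDataError(f"signature {phase!r} has no genes in the dataset")
        expr = _dense(adata[:, members].layers[layer])
        if zscore:
            sd = expr.std(axis=0)
            sd[sd == 0] = 1.0
            expr = (expr - expr.mean(axis=0)) / sd
        scores[phase] = expr.mean(axis=1)
    df = pd.DataFrame(scores, index=adata.obs_names.rename("cell_id"))
    mat = df.to_numpy()
    best = mat.argmax(axis=1)
    top = mat[np.arange(len(df)), best]
    tied = (mat == top[:, None]).sum(axis=1) > 1
    phase = np.asarray(PHASES)[best].astype(object)
    phase[tied] = UNASSIGNED
    df["phase"] = phase
    return df


def phase_proportions(scores: pd.DataFrame, groups: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-group phase fractions over assigned cells.

    Fractions sum to 1 within each group over the five phases; the fraction
    of unassigned cells is reported separately in the ``"unassigned"``
    column (relative to all cells of the group).
    """
    groups = np.asarray(groups)
    if len(groups) != len(scores):
        raise ParameterError("group labels must match the score table length")
    rows = {}
    for grp in pd.unique(groups):
        sub = scores.loc[groups == grp, "phase"]
        assigned = sub[sub != UNASSIGNED]
        counts = assigned.value_counts()
        frac = {p: counts.get(p, 0) / max(len(assigned), 1) for p in PHASES}
        frac["unassigned"] = (sub == UNASSIGNED).mean()
        frac["n_cells"] = len(sub)
        rows[grp] = frac
    return pd.DataFrame(rows).T.rename_axis("group")
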