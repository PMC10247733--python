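"""Dosage-ratio and stage-specific differential-expression analysis.

The biological null for a pure genome doubling is a 2:1 diploid:haploid
expression ratio (log2 ratio = 1) for every gene.  This module provides
ERCC spike-in normalization for bulk tables (absolute scale across
samples), per-stage per-gene diploid/haploid ratio tables on de-scaled
imputed single-cell expression with Wilcoxon rank-sum p-values and BH
q-values, and the cutoff census counting genes whose ratio falls below a
configured log2 cutoff in each cell-cycle stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PHASES
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "DEParams",
    "ercc_normalize",
    "wilcoxon_rank_sum",
    "bh_correct",
    "stage_ratios",
    "stage_ratio_table",
    "cutoff_census",
]

N_TOP_ERCC = 5


@dataclass
class DEParams:
    """Differential-expression thresholds.

    ``fc_min`` is the minimum linear fold change (either direction),
    ``q_max`` the BH-adjusted significance threshold, ``ratio_cutoff_log2``
    the census cutoff on the diploid:haploid log2 ratio.
    """

    fc_min: float = 1.25
    q_max: float = 0.01
    ratio_cutoff_log2: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ParameterError("fc_min must be > 1")
        if not 0 < self.q_max < 1:
            raise ParameterError("q_max must be in (0, 1)")


def ercc_normalize(bulk: pd.DataFrame, ercc_prefix: str = "ERCC-") -> pd.DataFrame:
    """Normalize each sample by the mean count of the top-5 ERCC spike-ins.

    The five spike-ins with the highest mean count across all samples are
    selected once; every row of each sample is divided by the mean of those
    five rows in that sample.  Spike-in rows are identified by index prefix
    and retained in the output.
    """
    is_ercc = bulk.index.str.startswith(ercc_prefix)
    if is_ercc.sum() < N_TOP_ERCC:
        raise DegenerateDataError(
            f"need >= {N_TOP_ERCC} ERCC rows, found {int(is_ercc.sum())}"
        )
    ercc = bulk.loc[is_ercc]
    top5 = ercc.mean(axis=1).nlargest(N_TOP_ERCC).index
    denom = bulk.loc[top5].mean(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise DegenerateDataError(f"zero top-5 ERCC mean in sample(s) {bad}")
    return bulk / denom


def _exact_tied_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group splits,
    valid with ties (midranks).  Cost C(n1+n2, n1); small samples only."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2.0)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(comb)].sum()
        stat = abs(r1 - n1 * (len(pooled) + 1) / 2.0)
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small samples (scipy's exact null when untied and both
    n <= 25; full enumeration with midranks when tied and the split count
    is tractable), tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both samples must be non-empty")
    small = max(len(x), len(y)) <= 25
    tied = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if small and not tied:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    if tied and len(x) + len(y) <= 12:
        return _exact_tied_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def stage_ratios(
    expr_diploid: np.ndarray,
    expr_haploid: np.ndarray,
    genes,
    stage: str,
    min_cells: int = 20,
    test_diploid: np.ndarray | None = None,
    test_haploid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene diploid/haploid ratio table for one stage.

    Inputs are cells x genes expression (absolute scale, cells already
    restricted to the stage).  log2 ratio is finite only when both group
    means are positive; p-values are Wilcoxon rank-sum per gene (vectorized
    tie-corrected normal approximation for the typical n >> 25 case),
    q-values BH-corrected across the genes of this stage.

    The rank-sum test runs on ``test_diploid``/``test_haploid`` when given
    (defaulting to the ratio matrices).  Passing depth-normalized
    expression there lets the test ask the interesting question — deviation
    beyond the global dosage factor — while the ratio keeps the absolute
    2:1 structure; with absolute-scale values the global shift alone makes
    every gene significant.
    """
    d = np.asarray(expr_diploid, dtype=float)
    h = np.asarray(expr_haploid, dtype=float)
    td = d if test_diploid is None else np.asarray(test_diploid, dtype=float)
    th = h if test_haploid is None else np.asarray(test_haploid, dtype=float)
    if d.shape[0] < min_cells or h.shape[0] < min_cells:
        raise DegenerateDataError(
            f"stage {stage!r}: need >= {min_cells} cells per group, "
            f"got diploid {d.shape[0]} / haploid {h.shape[0]}"
        )
    mean_d, mean_h = d.mean(axis=0), h.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.where(
            (mean_d > 0) & (mean_h > 0), np.log2(mean_d / mean_h), np.nan
        )
    if max(td.shape[0], th.shape[0]) > 25:
        res = stats.mannwhitneyu(td, th, alternative="two-sided",
                                 method="asymptotic", axis=0)
        p = np.atleast_1d(res.pvalue)
    else:
        p = np.array([wilcoxon_rank_sum(td[:, j], th[:, j]) for j in range(td.shape[1])])
    return pd.DataFrame(
        {
            "stage": stage,
            "mean_diploid": mean_d,
            "mean_haploid": mean_h,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "q_value": bh_correct(p),
            "n_diploid": d.shape[0],
            "n_haploid": h.shape[0],
        },
        index=pd.Index(genes, name="gene"),
    )


def stage_ratio_table(
    adata,
    phase_labels,
    stages=PHASES,
    layer: str = "imputed",
    test_layer: str | None = "imputed_norm",
    group_col: str = "group",
    min_cells: int = 20,
) -> pd.DataFrame:
    """Stage x gene ratio table over an imputed AnnData.

    ``phase_labels`` are the assigned phases (one per cell); cells of each
    stage are split by ``obs[group_col]`` into haploid/diploid and passed to
    :func:`stage_ratios` — ratios on the de-scaled (absolute-scale) imputed
    layer, rank-sum tests on the depth-normalized layer (falling back to
    ``layer`` if ``test_layer`` is None or absent).
    """
    from scipy import sparse

    def dense(name):
        arr = adata.layers[name]
        return arr.toarray() if sparse.issparse(arr) else np.asarray(arr, dtype=float)

    phase_labels = np.asarray(phase_labels, dtype=object)
    groups = adata.obs[group_col].to_numpy()
    x = dense(layer)
    t = dense(test_layer) if test_layer and test_layer in adata.layers else x
    out = []
    for stage in stages:
        in_stage = phase_labels == stage
        d_mask = in_stage & (groups == "diploid")
        h_mask = in_stage & (groups == "haploid")
        if d_mask.sum() == 0 or h_mask.sum() == 0:
            raise DegenerateDataError(f"stage {stage!r} absent in one group")
        out.append(
            stage_ratios(x[d_mask], x[h_mask], adata.var_names, stage, min_cells,
                         test_diploid=t[d_mask], test_haploid=t[h_mask])
        )
    return pd.concat(out).reset_index().set_index(["stage", "gene"])


def cutoff_census(
    table: pd.DataFrame, params: DEParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-stage count of genes with log2 ratio below the cutoff.

    Returns (census, ecdf_data, linear_equivalent).  ``census`` has one row
    per stage with the below-cutoff gene count, the number of ratio-defined
    genes, and the count excluded for a zero group mean; ``ecdf_data`` holds
    per-stage sorted log2 ratios with cumulative fractions for plotting;
    ``linear_equivalent`` is 2**cutoff on the linear fold scale.
    """
    params = params or DEParams()
    cutoff = params.ratio_cutoff_log2
    linear = float(2.0 ** cutoff)
    t = table.reset_index()
    rows, ecdf_parts = [], []
    for stage, sub in t.groupby("stage", sort=False):
        ratios = sub["log2_ratio"]
        defined = ratios.dropna()
        rows.append({
            "stage": stage,
            "n_below_cutoff": int((defined < cutoff).sum()),
            "n_genes_defined": len(defined),
            "n_excluded_zero_mean": int(ratios.isna().sum()),
        })
        srt = np.sort(defined.to_numpy())
        ecdf_parts.append(pd.DataFrame({
            "stage": stage, "log2_ratio": srt,
            "ecdf": np.arange(1, len(srt) + 1) / max(len(srt), 1),
        }))
    census = pd.DataFrame(rows).set_index("stage")
    census.attrs["cutoff_log2"] = cutoff
    census.attrs["cutoff_linear"] = linear
    return census, pd.concat(ecdf_parts, ignore_index=True), linear
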