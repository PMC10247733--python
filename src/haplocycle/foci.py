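"""DNA-damage foci quantification.

Cells stained for gamma-H2AX (double-strand break marker) and RAD51
(homologous-recombination filament) are binned by nuclear DAPI intensity as
a DNA-content proxy (low -> G1/S, medium -> S, high -> G2/M), compared
between ploidy groups as ratios of mean focus counts tested against the
dosage expectation (one-sample t-test on replicate ratios), and scored with
two co-localization metrics: the fraction of gamma-H2AX foci occupied by a
RAD51 focus within a match radius, and the converse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "FociTable",
    "ColocParams",
    "dapi_bin",
    "foci_ratio",
    "colocalize",
    "colocalize_cells",
    "stage_stratified_report",
]

BINS = ("low", "medium", "high")
BIN_TO_STAGE = {"low": "G1/S", "medium": "S", "high": "G2/M"}


@dataclass
class FociTable:
    """Per-cell DAPI intensities plus focus centroids.

    ``cells``: indexed by cell_id with columns group, replicate,
    dapi_intensity.  ``foci``: one row per focus with cell_id, channel
    ("gH2AX" or "RAD51"), x, y.
    """

    cells: pd.DataFrame
    foci: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.cells["dapi_intensity"] <= 0).any():
            raise ParameterError("dapi_intensity must be > 0")
        if not np.isfinite(self.foci[["x", "y"]].to_numpy(dtype=float)).all():
            raise ParameterError("focus coordinates must be finite")

    def counts(self, channel: str) -> pd.Series:
        """Per-cell focus count for one channel (0 for cells without foci)."""
        c = self.foci[self.foci["channel"] == channel].groupby("cell_id").size()
        return c.reindex(self.cells.index, fill_value=0).astype(int)

    def cell_foci(self, cell_id: str, channel: str) -> np.ndarray:
        sub = self.foci[(self.foci["cell_id"] == cell_id) & (self.foci["channel"] == channel)]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask: pd.Series) -> "FociTable":
        cells = self.cells[mask.reindex(self.cells.index, fill_value=False)]
        return FociTable(
            cells=cells, foci=self.foci[self.foci["cell_id"].isin(cells.index)]
        )


@dataclass
class ColocParams:
    match_radius: float = 0.5  # image units (um-equivalent)
    dapi_bin_quantiles: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        q1, q2 = self.dapi_bin_quantiles
        if not 0 < q1 < q2 < 1:
            raise ParameterError("dapi_bin_quantiles must satisfy 0 < q1 < q2 < 1")
        if self.match_radius <= 0:
            raise ParameterError("match_radius must be > 0")


def dapi_bin(table: FociTable, params: ColocParams | None = None) -> pd.Series:
    """Per-cell DNA-content bin in {low, medium, high}.

    Cut points are within-group quantiles of dapi_intensity, so each group's
    bins reflect its own content distribution (haploid and diploid scales
    differ by construction).  All-equal intensities within a group make the
    quantiles degenerate and raise.
    """
    params = params or ColocParams()
    q1, q2 = params.dapi_bin_quantiles
    out = pd.Series(index=table.cells.index, dtype=object, name="dapi_bin")
    for grp, sub in table.cells.groupby("group", sort=False):
        v = sub["dapi_intensity"].to_numpy(dtype=float)
        lo, hi = np.quantile(v, [q1, q2])
        if lo == hi:
            raise DegenerateDataError(
                f"group {grp!r}: degenerate DAPI quantiles (all intensities equal?)"
            )
        bins = np.where(v <= lo, "low", np.where(v <= hi, "medium", "high"))
        out.loc[sub.index] = bins
    return out


def foci_ratio(
    table_a: FociTable,
    table_b: FociTable,
    channel: str = "gH2AX",
    expected_ratio: float = 2.0,
) -> tuple[pd.Series, float]:
    """Replicate-wise ratio of mean focus counts A/B with a one-sample
    t-test against the dosage expectation.

    Replicates are matched by the ``replicate`` column; the two-sided
    one-sample Student's t-test compares the replicate ratios to
    ``expected_ratio``.  Fewer than 2 replicates, a zero denominator mean,
    or zero variance across replicates make the test undefined (p = NaN in
    the zero-variance case, errors otherwise).
    """
    counts_a = table_a.counts(channel).groupby(table_a.cells["replicate"]).mean()
    counts_b = table_b.counts(channel).groupby(table_b.cells["replicate"]).mean()
    common = counts_a.index.intersection(counts_b.index)
    if len(common) < 2:
        raise DegenerateDataError("need >= 2 matched replicates for the t-test")
    if (counts_b[common] == 0).any():
        raise DegenerateDataError("zero mean focus count in a denominator replicate")
    ratios = (counts_a[common] / counts_b[common]).rename("ratio")
    if np.allclose(ratios, ratios.iloc[0]):
        return ratios, float("nan")
    p = float(stats.ttest_1samp(ratios, popmean=expected_ratio).pvalue)
    return ratios, p


def colocalize(foci_a: np.ndarray, foci_b: np.ndarray, match_radius: float) -> tuple[float, float]:
    """Occupancy fractions for one cell.

    A focus of A is occupied iff some focus of B lies within
    ``match_radius`` (Euclidean); returns (fraction of A occupied, fraction
    of B occupied).  An empty list on either side yields NaN for that
    side's fraction.
    """
    a = np.asarray(foci_a, dtype=float).reshape(-1, 2)
    b = np.asarray(foci_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 and len(b) == 0:
        return float("nan"), float("nan")
    if len(a) == 0:
        return float("nan"), 0.0
    if len(b) == 0:
        return 0.0, float("nan")
    d = cdist(a, b)
    frac_a = float((d.min(axis=1) <= match_radius).mean())
    frac_b = float((d.min(axis=0) <= match_radius).mean())
    return frac_a, frac_b


def colocalize_cells(
    table: FociTable,
    channel_a: str = "gH2AX",
    channel_b: str = "RAD51",
    match_radius: float = 0.5,
) -> pd.DataFrame:
    """Per-cell occupancy fractions plus the across-cell averages.

    Cells without foci of the relevant channel are excluded from that
    side's average; the returned frame's ``attrs`` record the averages and
    contributing cell counts.
    """
    rows = []
    grouped = {ch: dict(list(g.groupby("cell_id")))
               for ch, g in table.foci.groupby("channel")}
    for cell_id in table.cells.index:
        a = grouped.get(channel_a, {}).get(cell_id)
        b = grouped.get(channel_b, {}).get(cell_id)
        fa, fb = colocalize(
            a[["x", "y"]].to_numpy() if a is not None else np.empty((0, 2)),
            b[["x", "y"]].to_numpy() if b is not None else np.empty((0, 2)),
            match_radius,
        )
        rows.append({"cell_id": cell_id, "frac_a_occupied": fa, "frac_b_occupied": fb})
    df = pd.DataFrame(rows).set_index("cell_id")
    df.attrs["mean_frac_a_occupied"] = float(df["frac_a_occupied"].mean())
    df.attrs["mean_frac_b_occupied"] = float(df["frac_b_occupied"].mean())
    df.attrs["n_cells_a"] = int(df["frac_a_occupied"].notna().sum())
    df.attrs["n_cells_b"] = int(df["frac_b_occupied"].notna().sum())
    return df


def stage_stratified_report(
    table: FociTable,
    params: ColocParams | None = None,
    expected_ratio: float = 2.0,
    group_a: str = "diploid",
    group_b: str = "haploid",
) -> pd.DataFrame:
    """Per-DAPI-bin foci counts, group ratios, and co-localization metrics.

    Composes :func:`dapi_bin`, :func:`foci_ratio` and
    :func:`colocalize_cells` within each bin; adds two-sample Student's
    t-tests (equal variance) between groups on per-cell gamma-H2AX counts
    and per-cell occupancy fractions.  Empty or single-replicate bins are
    reported with NaN statistics rather than raising.
    """
    params = params or ColocParams()
    bins = dapi_bin(table, params)
    rows = []
    for b in BINS:
        sub = table.subset(bins == b)
        row: dict = {"dapi_bin": b, "stage": BIN_TO_STAGE[b],
                     "n_cells": len(sub.cells)}
        for grp in (group_a, group_b):
            g = sub.subset(sub.cells["group"] == grp)
            row[f"mean_gH2AX_{grp}"] = float(g.counts("gH2AX").mean()) if len(g.cells) else np.nan
            row[f"mean_RAD51_{grp}"] = float(g.counts("RAD51").mean()) if len(g.cells) else np.nan
        ga = sub.subset(sub.cells["group"] == group_a)
        gb = sub.subset(sub.cells["group"] == group_b)
        if len(ga.cells) and len(gb.cells):
            try:
                ratios, p = foci_ratio(ga, gb, "gH2AX", expected_ratio)
                row["gH2AX_ratio"] = float(ratios.mean())
                row["gH2AX_ratio_p_vs_expected"] = p
            except DegenerateDataError:
                row["gH2AX_ratio"] = np.nan
                row["gH2AX_ratio_p_vs_expected"] = np.nan
            row["gH2AX_count_p_between_groups"] = float(
                stats.ttest_ind(ga.counts("gH2AX"), gb.counts("gH2AX")).pvalue
            )
            for grp, g in ((group_a, ga), (group_b, gb)):
                cc = colocalize_cells(g, match_radius=params.match_radius)
                row[f"frac_gH2AX_occupied_{grp}"] = cc.attrs["mean_frac_a_occupied"]
                row[f"frac_RAD51_occupied_{grp}"] = cc.attrs["mean_frac_b_occupied"]
            cca = colocalize_cells(ga, match_radius=params.match_radius)
            ccb = colocalize_cells(gb, match_radius=params.match_radius)
            va = cca["frac_a_occupied"].dropna()
            vb = ccb["frac_a_occupied"].dropna()
            row["occupancy_p_between_groups"] = (
                float(stats.ttest_ind(va, vb).pvalue) if len(va) > 1 and len(vb) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("dapi_bin")
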