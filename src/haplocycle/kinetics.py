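"""Growth kinetics: doubling times, stage-duration allocation, and
growth-competition fitness.

Doubling time comes from a least-squares fit of log2(count) against time.
Stage durations are allocated proportionally to the observed phase
fractions (duration_s = proportion_s * doubling_time), with an optional
exponential-age-structure correction that accounts for the
young-cell excess of asynchronous exponential cultures.  Competition
assays are summarized as the marked:unmarked ratio series normalized to
its baseline, with a per-doubling fitness difference from a log-linear
fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError

__all__ = ["doubling_time", "stage_durations", "competition_curve"]


def doubling_time(time_h, counts) -> float:
    """Doubling time in hours from one growth curve.

    Least-squares fit of log2(count) vs time; doubling time is 1/slope.
    Requires >= 3 strictly increasing time points and positive counts.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(t) < 3:
        raise DegenerateDataError("need >= 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time points must be strictly increasing")
    if np.any(c <= 0):
        raise DegenerateDataError("counts must be positive for a log fit")
    slope = stats.linregress(t, np.log2(c)).slope
    if slope <= 0:
        raise DegenerateDataError("non-growing culture: slope <= 0")
    return float(1.0 / slope)


def doubling_times(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate doubling times plus group means from a tidy growth
    table with columns group, replicate, time_h, count."""
    rows = [
        {"group": grp, "replicate": rep,
         "doubling_time_h": doubling_time(sub["time_h"], sub["count"])}
        for (grp, rep), sub in curve.groupby(["group", "replicate"])
    ]
    per_rep = pd.DataFrame(rows)
    per_rep["group_mean_h"] = per_rep.groupby("group")["doubling_time_h"].transform("mean")
    return per_rep


def stage_durations(
    phase_proportions: dict[str, float] | pd.Series,
    doubling_time_h: float,
    mode: str = "proportional",
) -> pd.Series:
    """Hours spent in each cell-cycle stage.

    ``mode="proportional"`` allocates duration_s = proportion_s * Td (the
    durations sum to Td exactly).  ``mode="exponential"`` corrects for the
    steady-state age distribution of an exponentially growing culture, in
    which young cells are over-represented: a phase occupying the age
    interval [x1, x2] (fractions of the cycle) has observed proportion
    2 * (2^-x1 - 2^-x2), which is inverted sequentially in phase order.
    The proportions must follow cycle order when using the exponential
    mode.
    """
    props = pd.Series(phase_proportions, dtype=float)
    total = props.sum()
    if abs(total - 1.0) > 0.01:
        raise ParameterError(f"phase proportions sum to {total:.4f}, expected 1 +- 0.01")
    props = props / total
    if mode == "proportional":
        return props * doubling_time_h
    if mode == "exponential":
        x_prev, durations = 0.0, {}
        for phase, p in props.items():
            inner = 2.0 ** -x_prev - p / 2.0
            if inner <= 0:
                raise DegenerateDataError("proportions inconsistent with exponential ages")
            x_next = -np.log2(inner)
            durations[phase] = (min(x_next, 1.0) - x_prev) * doubling_time_h
            x_prev = min(x_next, 1.0)
        return pd.Series(durations)
    raise ParameterError(f"unknown mode {mode!r}")


def competition_curve(
    time: np.ndarray,
    percent_marked: np.ndarray,
    doubling_time_h: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Normalized enrichment series and per-doubling fitness difference.

    The marked:unmarked ratio p/(100-p) is normalized to its value at the
    first time point; the fitness difference is the slope of log2 of the
    normalized ratio against time, multiplied by the doubling time (log2
    units per doubling; -1 means the marked population halves its relative
    abundance every doubling).
    """
    t = np.asarray(time, dtype=float)
    p = np.asarray(percent_marked, dtype=float)
    if len(t) != len(p) or len(t) < 2:
        raise ParameterError("need matched time/percent series of length >= 2")
    if np.any((p <= 0) | (p >= 100)):
        raise DegenerateDataError("percent_marked must lie strictly in (0, 100)")
    ratio = p / (100.0 - p)
    norm = ratio / ratio[0]
    slope = stats.linregress(t, np.log2(norm)).slope if len(t) > 2 else (
        (np.log2(norm[-1]) - np.log2(norm[0])) / (t[-1] - t[0])
    )
    series = pd.DataFrame({"time": t, "normalized_ratio": norm})
    return series, float(slope * doubling_time_h)
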