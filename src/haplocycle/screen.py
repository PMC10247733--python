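"""Pooled-screen depletion scoring and ploidy-specific essentiality calls.

Guide-level depletion is the log2 fold change of depth-normalized,
pseudocounted guide abundance between a screen endpoint and the input
library.  A gene is called essential in a screen when the median log2FC of
its guides falls below a threshold set from the non-targeting control
distribution AND at least a minimum number of its guides individually fall
below that threshold.  Ploidy-specific hits are the deterministic
intersection: essential in every haploid screen, in no diploid screen, not
a panel-wide common essential, and over-expressed in the stage of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .io import GeneSet

__all__ = [
    "EssentialityCall",
    "guide_log2fc",
    "call_essentials",
    "ploidy_specific_intersection",
]

CONTROL_GENE = "control"


def guide_log2fc(
    table: pd.DataFrame,
    endpoint: str,
    input_sample: str = "input",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-guide log2 fold change endpoint vs input.

    Counts are scaled to equal sample totals before adding the pseudocount,
    so the statistic is invariant to sequencing depth.
    """
    for col in (endpoint, input_sample):
        if col not in table.columns:
            raise ParameterError(f"sample column {col!r} missing")
    end = table[endpoint].to_numpy(dtype=float)
    inp = table[input_sample].to_numpy(dtype=float)
    if end.sum() <= 0 or inp.sum() <= 0:
        raise DegenerateDataError("a sample has zero total counts")
    target = (end.sum() + inp.sum()) / 2.0
    end = end * (target / end.sum()) + pseudocount
    inp = inp * (target / inp.sum()) + pseudocount
    with np.errstate(divide="ignore"):  # pseudocount=0 legitimately yields -inf
        fc = np.log2(end / inp)
    return pd.Series(fc, index=table["guide"], name=f"log2fc_{endpoint}")


@dataclass
class EssentialityCall:
    """Per-screen gene calls plus the control-derived threshold used."""

    calls: pd.DataFrame  # index gene: gene_score, depleted_guides, n_guides, is_essential, rank_pct
    threshold: float
    screen: str = ""

    @property
    def essential_genes(self) -> set[str]:
        return set(self.calls.index[self.calls["is_essential"]])


def call_essentials(
    log2fc: pd.Series,
    mapping: pd.Series,
    score_threshold: float | None = None,
    min_depleted_guides: int = 2,
    control_quantile: float = 0.05,
    screen: str = "",
) -> EssentialityCall:
    """Gene essentiality from per-guide log2FC.

    ``mapping`` maps guide -> target gene (``"control"`` for non-targeting
    guides).  The gene score is the median guide log2FC; a gene is
    essential iff its score <= threshold and at least
    ``min_depleted_guides`` of its guides are individually <= threshold.
    When ``score_threshold`` is None it is set to the ``control_quantile``
    quantile of the control-guide log2FC distribution.
    """
    mapping = mapping.reindex(log2fc.index)
    if mapping.isna().any():
        raise ParameterError("mapping does not cover every guide")
    is_ctrl = mapping == CONTROL_GENE
    if score_threshold is None:
        if not is_ctrl.any():
            raise ParameterError(
                "no control guides to derive the threshold; pass score_threshold"
            )
        score_threshold = float(np.quantile(log2fc[is_ctrl], control_quantile))
    df = pd.DataFrame({"log2fc": log2fc, "gene": mapping})
    df = df[~is_ctrl]
    zero_guide = set()
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        if len(sub) == 0:  # defensive; groupby never yields empty groups
            zero_guide.add(gene)
            continue
        fc = sub["log2fc"].to_numpy()
        depleted = int((fc <= score_threshold).sum())
        score = float(np.median(fc))
        rows.append({
            "gene": gene, "gene_score": score, "n_guides": len(fc),
            "depleted_guides": depleted,
            "is_essential": score <= score_threshold and depleted >= min_depleted_guides,
        })
    if zero_guide:
        warnings.warn(f"excluded {len(zero_guide)} genes with zero guides", stacklevel=2)
    calls = pd.DataFrame(rows).set_index("gene")
    calls["rank_pct"] = calls["gene_score"].rank(pct=True)
    return EssentialityCall(calls=calls, threshold=score_threshold, screen=screen)


def ploidy_specific_intersection(
    haploid_calls: list[EssentialityCall],
    diploid_calls: list[EssentialityCall],
    panel_common_essentials: GeneSet | set | None = None,
    stage_overexpressed: GeneSet | set | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Haploid-specific essential genes with per-candidate provenance.

    A gene passes iff it is essential in EVERY haploid screen, essential in
    NO diploid screen, absent from the common-essential panel, and present
    in the stage-overexpressed set (when one is given).  Returns the passing
    set and a provenance table recording, for every candidate (any gene
    essential in at least one haploid screen), which criterion removed it.
    """
    if not haploid_calls:
        raise ParameterError("need at least one haploid screen")
    common = set(
        panel_common_essentials.members
        if isinstance(panel_common_essentials, GeneSet)
        else (panel_common_essentials or set())
    )
    stage = (
        set(stage_overexpressed.members)
        if isinstance(stage_overexpressed, GeneSet)
        else (None if stage_overexpressed is None else set(stage_overexpressed))
    )
    hap_sets = [c.essential_genes for c in haploid_calls]
    dip_sets = [c.essential_genes for c in diploid_calls]
    candidates = sorted(set.union(*hap_sets))
    rows, passing = [], set()
    for gene in candidates:
        if not all(gene in s for s in hap_sets):
            reason = "not essential in every haploid screen"
        elif any(gene in s for s in dip_sets):
            reason = "essential in a diploid screen"
        elif gene in common:
            reason = "panel common essential"
        elif stage is not None and gene not in stage:
            reason = "not stage-overexpressed"
        else:
            reason = "pass"
            passing.add(gene)
        rows.append({"gene": gene, "status": reason})
    provenance = pd.DataFrame(rows).set_index("gene")
    return passing, provenance
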