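"""Anchor-gene co-expression signatures and gene-set overlap testing.

A co-expression signature around an anchor gene (e.g. RAD51B) is the set of
genes whose imputed expression correlates with the anchor at Pearson
r >= r_min across cells, the anchor included.  Signatures are scored per
cell as the raw mean of member imputed expression, and tested for overlap
against other gene sets with an upper-tail hypergeometric test over an
explicit gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .dosage import wilcoxon_rank_sum
from .errors import DegenerateDataError, ParameterError
from .io import GeneSet

__all__ = [
    "SignatureSpec",
    "coexpression_signature",
    "signature_score",
    "overlap_test",
    "group_score_compare",
]


@dataclass
class SignatureSpec:
    anchor_gene: str
    r_min: float = 0.5
    dataset: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= 1:
            raise ParameterError("r_min must be in [0, 1]")


def _layer(adata, layer: str) -> np.ndarray:
    x = adata.layers[layer] if layer in adata.layers else adata.X
    return x.toarray() if sparse.issparse(x) else np.asarray(x, dtype=float)


def coexpression_signature(adata, spec: SignatureSpec, layer: str = "imputed") -> GeneSet:
    """Genes correlated with the anchor at r >= r_min, anchor included.

    Only nonzero-variance genes are eligible; a missing or constant anchor
    is an error.
    """
    if spec.anchor_gene not in adata.var_names:
        raise DegenerateDataError(f"anchor gene {spec.anchor_gene!r} not in dataset")
    x = _layer(adata, layer)
    j = adata.var_names.get_loc(spec.anchor_gene)
    anchor = x[:, j]
    if anchor.std() == 0:
        raise DegenerateDataError(f"anchor gene {spec.anchor_gene!r} has zero variance")
    sd = x.std(axis=0)
    ac = anchor - anchor.mean()
    xc = x - x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ ac) / (np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((ac ** 2).sum()))
    members = set(np.asarray(adata.var_names)[(sd > 0) & (r >= spec.r_min)])
    members.add(spec.anchor_gene)
    name = f"{spec.anchor_gene}_coexpression"
    return GeneSet(name, members)


def signature_score(adata, gene_set: GeneSet, layer: str = "imputed",
                    zscore: bool = False) -> pd.Series:
    """Per-cell mean imputed expression over the set's members.

    Raw-mean by default; ``zscore=True`` standardizes each gene across
    cells first (makes the score invariant to per-gene scale).
    """
    members = [g for g in sorted(gene_set.members) if g in adata.var_names]
    if not members:
        raise DegenerateDataError(f"gene set {gene_set.name!r} has no genes in dataset")
    x = _layer(adata[:, members], layer)
    if zscore:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return pd.Series(x.mean(axis=1), index=adata.obs_names, name=gene_set.name)


def overlap_test(set_a: GeneSet | set, set_b: GeneSet | set, universe) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value.

    p = P(overlap >= observed) when drawing |B| genes from the universe
    containing |A| successes.  Both sets must be subsets of the universe.
    """
    a = set(set_a.members if isinstance(set_a, GeneSet) else set_a)
    b = set(set_b.members if isinstance(set_b, GeneSet) else set_b)
    u = set(universe)
    if not a <= u or not b <= u:
        raise ParameterError("both sets must be subsets of the universe")
    k = len(a & b)
    # survival function is P(X > k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return k, min(p, 1.0)


def group_score_compare(scores: pd.Series, labels, comparisons=None) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of per-cell scores between label groups.

    ``comparisons`` is an iterable of (label_a, label_b) pairs; by default
    all unordered pairs of observed labels are tested.
    """
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ParameterError("labels must match scores length")
    uniq = list(pd.unique(labels))
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    rows = []
    for a, b in comparisons:
        xa = scores.to_numpy()[labels == a]
        xb = scores.to_numpy()[labels == b]
        rows.append({
            "group_a": a, "group_b": b,
            "n_a": len(xa), "n_b": len(xb),
            "median_a": float(np.median(xa)) if len(xa) else np.nan,
            "median_b": float(np.median(xb)) if len(xb) else np.nan,
            "p_value": wilcoxon_rank_sum(xa, xb),
        })
    return pd.DataFrame(rows)
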