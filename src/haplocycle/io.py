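"""Readers and writers for the package's on-disk formats.

Count matrices travel as 10x-style MTX triplets (MatrixMarket coordinate
file with 1-based indices, barcodes.tsv, features.tsv, optional
cell_meta.csv) or as dense CSV; gene sets as GMT; everything else as
CSV/TSV with a header row.  The in-memory count container is AnnData
(cells x genes); on disk the matrix is stored features x barcodes as 10x
does, and orientation is detected on read from the header dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import FormatError

__all__ = [
    "GeneSet",
    "validate_counts",
    "read_mtx",
    "write_mtx",
    "read_counts_csv",
    "write_counts_csv",
    "read_gene_sets",
    "write_gene_sets",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free, non-empty set of gene symbols.

    Gene identity is matched case-sensitively by symbol string throughout
    the package.
    """

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersect(self, genes) -> "GeneSet":
        return GeneSet(self.name, self.members & set(genes))


def validate_counts(adata: ad.AnnData) -> ad.AnnData:
    """Enforce the count-matrix contract: non-negative values, unique cell
    and gene ids, metadata covering every cell."""
    x = adata.X
    mn = x.min() if sparse.issparse(x) else np.min(x)
    if mn < 0:
        raise FormatError("count matrix contains negative values")
    if adata.obs_names.has_duplicates:
        raise FormatError("duplicate cell ids")
    if adata.var_names.has_duplicates:
        raise FormatError("duplicate gene ids")
    if len(adata.obs) != adata.n_obs:
        raise FormatError("cell metadata does not cover every cell")
    return adata


def write_mtx(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write a 10x-style triplet: matrix.mtx (features x barcodes, 1-based
    coordinates), barcodes.tsv, features.tsv, plus cell_meta.csv if the
    AnnData carries obs columns."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(adata.X.T if sparse.issparse(adata.X) else np.asarray(adata.X).T)
    spio.mmwrite(str(d / "matrix.mtx"), mat, field="integer")
    (d / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (d / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in adata.var_names) + "\n"
    )
    if adata.obs.shape[1]:
        adata.obs.rename_axis("cell_id").to_csv(d / "cell_meta.csv")


def read_mtx(dir_path: str | Path) -> ad.AnnData:
    """Read a 10x-style MTX triplet into a cells x genes AnnData.

    Orientation on disk is detected by comparing header dimensions with the
    barcode and feature counts; square matrices are assumed features x
    barcodes (the 10x convention).  1-based MTX coordinates become the
    0-based internal convention.
    """
    d = Path(dir_path)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (d / name).exists():
            raise FormatError(f"missing {name} in {d}")
    barcodes = [ln.split("\t")[0] for ln in _read_lines(d / "barcodes.tsv")]
    features = [ln.split("\t")[0] for ln in _read_lines(d / "features.tsv")]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcode in {d / 'barcodes.tsv'}")
    try:
        mat = spio.mmread(str(d / "matrix.mtx"))
    except Exception as exc:
        raise FormatError(f"cannot parse {d / 'matrix.mtx'}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    nb, nf = len(barcodes), len(features)
    if mat.shape == (nf, nb):
        mat = mat.T.tocsr()  # on disk features x barcodes
    elif mat.shape != (nb, nf):
        raise FormatError(
            f"{d / 'matrix.mtx'}: dimensions {mat.shape} match neither "
            f"({nb} barcodes x {nf} features) nor its transpose"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = d / "cell_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        missing = obs.index.difference(meta.index)
        if len(missing):
            raise FormatError(f"cell_meta.csv missing {len(missing)} cells")
        obs = meta.loc[obs.index]
    adata = ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene_id")))
    return validate_counts(adata)


def _read_lines(path: Path) -> list[str]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    return lines


def write_counts_csv(adata: ad.AnnData, path: str | Path) -> None:
    """Dense cells x genes CSV with cell ids as index."""
    x = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    pd.DataFrame(x, index=adata.obs_names, columns=adata.var_names).rename_axis(
        "cell_id"
    ).to_csv(path)


def read_counts_csv(path: str | Path) -> ad.AnnData:
    df = pd.read_csv(path, index_col=0)
    adata = ad.AnnData(
        X=sparse.csr_matrix(df.to_numpy()),
        obs=pd.DataFrame(index=df.index.rename("cell_id").astype(str)),
        var=pd.DataFrame(index=pd.Index(df.columns, name="gene_id")),
    )
    return validate_counts(adata)


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: tab-separated, field 1 = name, field 2 = description
    (ignored), fields 3+ = members.  Duplicated members within a set are
    collapsed with a warning; an empty member list is a format error."""
    sets = []
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{gmt_path}:{lineno}: gene set {fields[0]!r} has no members")
        name, members = fields[0], [f for f in fields[2:] if f]
        if not members:
            raise FormatError(f"{gmt_path}:{lineno}: gene set {name!r} has no members")
        if len(set(members)) != len(members):
            warnings.warn(
                f"{gmt_path}:{lineno}: duplicated members in {name!r} collapsed",
                stacklevel=2,
            )
        sets.append(GeneSet(name, set(members)))
    if not sets:
        raise FormatError(f"{gmt_path}: no gene sets")
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.name] + sorted(s.members)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_bundled_phase_signatures() -> list[GeneSet]:
    """Five-phase cell-cycle signature gene lists (G1S, S, G2, G2M, MG1)
    derived from the Whitfield et al. periodic-expression catalog, shipped
    with the package."""
    from importlib.resources import files

    gmt = files("haplocycle.data").joinpath("cell_cycle_phases.gmt")
    sets = []
    for line in gmt.read_text().splitlines():
        if line.strip():
            fields = line.split("\t")
            sets.append(GeneSet(fields[0], set(fields[2:])))
    return sets
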