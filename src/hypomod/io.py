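"""Readers and writers for the on-disk formats used across the pipeline.

Formats are deliberately plain text: MatrixMarket coordinate integer
matrices with barcodes.tsv/features.tsv sidecars (the 10x triplet), GMT
geneset collections, and TSV result tables.  Readers validate rather than
coerce: dimension mismatches, negative counts, or duplicate identifiers are
hard errors.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .datatypes import CountMatrix, GeneSetCollection

__all__ = [
    "read_counts_10x",
    "write_counts_10x",
    "read_gmt",
    "write_gmt",
    "write_results",
    "read_results",
]


def read_counts_10x(path) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx`` (genes in rows), ``barcodes.tsv`` (one cell id per
    line), ``features.tsv`` (gene_id, symbol, and optionally is_mito/is_ribo
    columns).  If a ``cell_meta.tsv`` is present it is attached as cell
    metadata; truth columns written by the simulator keep their ``truth_``
    prefix.
    """
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    bc_file = path / "barcodes.tsv"
    ft_file = path / "features.tsv"
    for f in (mtx_file, bc_file, ft_file):
        if not f.exists():
            raise FileNotFoundError(f"missing required file: {f}")
    X = sp.csr_matrix(spio.mmread(mtx_file))
    barcodes = _read_lines(bc_file)
    if not barcodes:
        raise ValueError(f"{bc_file} is empty")
    features = pd.read_csv(ft_file, sep="\t", header=None, dtype=str)
    if X.shape[0] != len(features):
        raise ValueError(
            f"{ft_file}: {len(features)} features but matrix has {X.shape[0]} rows"
        )
    if X.shape[1] != len(barcodes):
        raise ValueError(
            f"{bc_file}: {len(barcodes)} barcodes but matrix has {X.shape[1]} columns"
        )
    if X.data.size and X.data.min() < 0:
        raise ValueError(f"{mtx_file}: negative counts")
    gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
    symbols = (
        features.iloc[:, 1].to_numpy(dtype=object)
        if features.shape[1] > 1
        else gene_ids.copy()
    )
    if len(set(symbols)) != len(symbols):
        warnings.warn("duplicate gene symbols present; identity is by gene_id")
    gene_meta = pd.DataFrame(
        {
            "symbol": symbols,
            "is_mito": _flag_column(features, 2),
            "is_ribo": _flag_column(features, 3),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    meta_file = path / "cell_meta.tsv"
    if meta_file.exists():
        cell_meta = pd.read_csv(meta_file, sep="\t", index_col="cell_id")
        cell_meta.index = cell_meta.index.astype(object)
    else:
        cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    return CountMatrix(
        X=X,
        gene_ids=gene_ids,
        cell_ids=np.array(barcodes, dtype=object),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )


def write_counts_10x(counts: CountMatrix, path) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv (+ cell_meta.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(counts.X)
    X = sp.coo_matrix((X.data.astype(np.int64), (X.row, X.col)), shape=X.shape)
    spio.mmwrite(path / "matrix.mtx", X, field="integer")
    (path / "barcodes.tsv").write_text("\n".join(map(str, counts.cell_ids)) + "\n")
    ft = pd.DataFrame(
        {
            0: counts.gene_ids,
            1: counts.gene_meta["symbol"].to_numpy(),
            2: counts.gene_meta["is_mito"].astype(int).to_numpy(),
            3: counts.gene_meta["is_ribo"].astype(int).to_numpy(),
        }
    )
    ft.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    if len(counts.cell_meta.columns):
        counts.cell_meta.rename_axis("cell_id").to_csv(path / "cell_meta.tsv", sep="\t")


def _read_lines(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _flag_column(features: pd.DataFrame, col: int) -> np.ndarray:
    if features.shape[1] > col:
        return features.iloc[:, col].astype(str).isin(["1", "True", "true"]).to_numpy()
    return np.zeros(len(features), dtype=bool)


# ----------------------------------------------------------------------
def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per term (id, description, genes...).

    Duplicate genes within a line are deduplicated; a duplicate term id
    across lines is an error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ----------------------------------------------------------------------
def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV with stable column order and full float precision."""
    if table.shape[1] == 0:
        raise ValueError("results table has no columns")
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    table.to_csv(path, sep="\t", index=not isinstance(table.index, pd.RangeIndex),
                 float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
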