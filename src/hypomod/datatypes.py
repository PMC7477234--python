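"""Shared in-memory data model.

The central container is :class:`CountMatrix`: a sparse genes x cells (or
genes x samples) matrix of non-negative integer UMI counts together with
cell-level metadata (sample, treatment group, day, batch) and gene-level
metadata (symbol, mitochondrial/ribosomal flags).  The orientation is fixed
as genes-in-rows throughout the package, matching the on-disk 10x
convention, so no stage ever has to guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "GeneSetCollection"]


@dataclass
class CountMatrix:
    """Sparse genes x cells count matrix with aligned metadata.

    Parameters
    ----------
    X
        scipy sparse matrix, genes in rows, cells (or samples) in columns,
        non-negative integer-valued counts.
    gene_ids, cell_ids
        Unique identifier strings, aligned with the rows/columns of ``X``.
    cell_meta
        DataFrame indexed by cell id.  Expected columns for experimental
        data: ``sample_id``, ``group``, and optionally ``day``, ``batch``,
        ``label``.
    gene_meta
        DataFrame indexed by gene id with at least ``symbol`` and boolean
        ``is_mito`` / ``is_ribo`` columns.
    """

    X: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(
                {
                    "symbol": self.gene_ids,
                    "is_mito": np.zeros(len(self.gene_ids), dtype=bool),
                    "is_ribo": np.zeros(len(self.gene_ids), dtype=bool),
                },
                index=pd.Index(self.gene_ids, name="gene_id"),
            )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.X.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids has {len(self.cell_ids)} entries for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        data = self.X.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValueError(f"cell_meta missing {len(missing)} cell ids, e.g. {sorted(missing)[:3]}")
        # keep metadata aligned with matrix order
        self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        self.gene_meta = self.gene_meta.loc[list(self.gene_ids)]

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        return CountMatrix(
            X=self.X[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].copy(),
        )

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return CountMatrix(
            X=self.X[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            X=self.X.copy(),
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


def _as_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.shape[0] != n:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return arr.astype(int)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG/REACTOME-style terms) plus optional universe."""

    sets: dict  # term_id -> (name, frozenset of genes)
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term_id: str) -> frozenset:
        return self.sets[term_id][1]

    def items(self):
        return self.sets.items()
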