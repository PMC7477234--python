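"""Quality control, normalization, dimensionality reduction, and clustering.

The stage order is fixed: barcode calling -> cell filters -> gene filters ->
log normalization -> variable genes -> covariate regression + scaling ->
PCA -> shared-nearest-neighbor graph clustering -> silhouette filter ->
sample-domination filter.

Cell filters follow the study defaults: cells with <400 or >4000 detected
genes are discarded, as are cells whose combined mitochondrial+ribosomal
UMI share exceeds 20% (single-cell mode) or 5% (single-nucleus mode);
genes detected in fewer than 10 (single-cell) or 5 (single-nucleus) cells
are then removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix

__all__ = [
    "QCThresholds",
    "Embedding",
    "ClusterLabels",
    "call_barcodes",
    "filter_cells_genes",
    "normalize_log",
    "select_variable_genes",
    "regress_and_scale",
    "run_pca",
    "cluster_cells",
    "silhouette_filter",
    "flag_sample_dominated_clusters",
]


@dataclass
class QCThresholds:
    min_genes: int = 400
    max_genes: int = 4000
    max_mito_ribo_fraction: float = 0.20
    min_cells_per_gene: int = 10
    barcode_fraction: float = 0.10
    expected_cells: int = 3000
    # when set, mito and ribo fractions are thresholded separately instead
    # of on their sum
    separate_mito_ribo: bool = False

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito_ribo_fraction <= 1:
            raise ValueError("max_mito_ribo_fraction must be in (0, 1]")
        if not 0 < self.barcode_fraction <= 1:
            raise ValueError("barcode_fraction must be in (0, 1]")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "QCThresholds":
        """Presets: 'sc' (single-cell) or 'sn' (single-nucleus)."""
        if mode == "sc":
            base = dict(max_mito_ribo_fraction=0.20, min_cells_per_gene=10)
        elif mode == "sn":
            base = dict(max_mito_ribo_fraction=0.05, min_cells_per_gene=5)
        else:
            raise ValueError(f"unknown mode {mode!r}; expected 'sc' or 'sn'")
        base.update(overrides)
        return cls(**base)


@dataclass
class Embedding:
    cell_ids: np.ndarray
    coordinates: np.ndarray          # cells x n_pcs
    explained_variance: np.ndarray   # length n_pcs, non-increasing
    loadings: np.ndarray             # genes x n_pcs, orthonormal columns
    gene_ids: np.ndarray | None = None


@dataclass
class ClusterLabels:
    cell_ids: np.ndarray
    labels: np.ndarray               # dense ints from 0
    resolution: float
    silhouette: np.ndarray | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="cluster")


# ----------------------------------------------------------------------
def call_barcodes(barcode_totals: dict, expected_cells: int, fraction: float = 0.10):
    """Keep barcodes whose total UMI count exceeds ``fraction`` times the
    99th percentile of the top-``expected_cells`` barcode totals."""
    if not barcode_totals:
        raise ValueError("no barcodes supplied")
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    barcodes = np.array(list(barcode_totals.keys()), dtype=object)
    totals = np.array([barcode_totals[b] for b in barcodes], dtype=float)
    if expected_cells > len(barcodes):
        warnings.warn(
            f"expected_cells={expected_cells} exceeds {len(barcodes)} barcodes; using all"
        )
        expected_cells = len(barcodes)
    top = np.sort(totals)[::-1][:expected_cells]
    threshold = fraction * np.percentile(top, 99)
    return set(barcodes[totals > threshold])


def filter_cells_genes(counts: CountMatrix, thresholds: QCThresholds) -> CountMatrix:
    """Apply cell filters (detected-gene range, mito/ribo share) then gene
    filters (detection floor), in that fixed order."""
    X = sp.csc_matrix(counts.X)
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    is_mito = counts.gene_meta["is_mito"].to_numpy(bool)
    is_ribo = counts.gene_meta["is_ribo"].to_numpy(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, np.asarray(X[is_mito].sum(axis=0)).ravel() / total, 0.0)
        ribo_frac = np.where(total > 0, np.asarray(X[is_ribo].sum(axis=0)).ravel() / total, 0.0)
    keep_cells = (detected >= thresholds.min_genes) & (detected <= thresholds.max_genes)
    if thresholds.separate_mito_ribo:
        keep_cells &= (mito_frac <= thresholds.max_mito_ribo_fraction) & (
            ribo_frac <= thresholds.max_mito_ribo_fraction
        )
    else:
        keep_cells &= (mito_frac + ribo_frac) <= thresholds.max_mito_ribo_fraction
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filters")
    out = counts.subset_cells(keep_cells)
    gene_cells = np.asarray((out.X > 0).sum(axis=1)).ravel()
    out = out.subset_genes(gene_cells >= thresholds.min_cells_per_gene)
    return out


def qc_report(counts: CountMatrix, thresholds: QCThresholds) -> pd.DataFrame:
    """Per-cell QC metrics with kept/dropped flags (not filtered)."""
    X = sp.csc_matrix(counts.X)
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    is_mito = counts.gene_meta["is_mito"].to_numpy(bool)
    is_ribo = counts.gene_meta["is_ribo"].to_numpy(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mr = np.where(
            total > 0,
            np.asarray(X[is_mito | is_ribo].sum(axis=0)).ravel() / np.maximum(total, 1),
            0.0,
        )
    kept = (
        (detected >= thresholds.min_genes)
        & (detected <= thresholds.max_genes)
        & (mr <= thresholds.max_mito_ribo_fraction)
    )
    return pd.DataFrame(
        {
            "n_genes_detected": detected,
            "total_umis": total,
            "mito_ribo_fraction": mr,
            "kept": kept,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


# ----------------------------------------------------------------------
def normalize_log(counts: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """log1p library-size normalization: log(1 + scale * count / cell_total).

    Returns a dense genes x cells array; zeros stay exactly zero.
    """
    X = sp.csc_matrix(counts.X)
    totals = np.asarray(X.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {list(counts.cell_ids[zero[:5]])}"
        )
    X = X.astype(float)
    X = X.multiply(scale / totals[None, :])
    X = X.tocsr()
    X.data = np.log1p(X.data)
    return np.asarray(X.todense())


def select_variable_genes(norm: np.ndarray, gene_ids, n_top: int = 2000,
                          n_bins: int = 20) -> list:
    """Rank genes by dispersion (variance/mean of normalized values) z-scored
    within equal-occupancy mean bins; return the top ``n_top`` gene ids.
    Ties break deterministically by gene id."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(norm.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_genes = len(gene_ids)
    if n_top > n_genes:
        warnings.warn(f"n_top={n_top} > {n_genes} genes; returning all")
        n_top = n_genes
    # equal-occupancy mean bins
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(np.arange(n_genes) * n_bins // max(n_genes, 1), n_bins - 1)
    z = np.zeros(n_genes)
    for b in range(n_bins):
        m = bin_of == b
        if not m.any():
            continue
        d = disp[m]
        sd = d.std(ddof=0)
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    # zero-variance genes can never outrank varying ones
    z[var == 0] = -np.inf
    key = sorted(range(n_genes), key=lambda i: (-z[i], gene_ids[i]))
    return [gene_ids[i] for i in key[:n_top]]


def regress_and_scale(norm: np.ndarray, covariates: pd.DataFrame,
                      clip: float = 10.0) -> np.ndarray:
    """Regress per-cell covariates out of each gene (OLS), then center,
    scale to unit variance, and clip to +/-``clip``.

    ``norm`` is genes x cells; ``covariates`` has one row per cell.
    Constant covariate columns are dropped with a warning.
    """
    n_genes, n_cells = norm.shape
    if len(covariates) != n_cells:
        raise ValueError("covariates must have one row per cell")
    cols = []
    for c in covariates.columns:
        v = covariates[c].to_numpy(float)
        if np.ptp(v) == 0:
            warnings.warn(f"dropping constant covariate {c!r}")
            continue
        cols.append(v)
    X = np.column_stack([np.ones(n_cells)] + cols)
    # residuals of Y' = norm.T on X, gene-vectorized
    beta, *_ = np.linalg.lstsq(X, norm.T, rcond=None)
    resid = norm.T - X @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes fully explained by the covariates keep their (near-)zero
    # residuals instead of amplifying numerical noise to unit variance
    sd[sd < 1e-10] = 1.0
    scaled = resid / sd
    return np.clip(scaled.T, -clip, clip)


def run_pca(scaled: np.ndarray, cell_ids=None, gene_ids=None,
            n_pcs: int = 30) -> Embedding:
    """Exact SVD principal components of the scaled genes x cells matrix.

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    n_genes, n_cells = scaled.shape
    max_rank = min(n_genes, n_cells)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank bound {max_rank}; truncating")
        n_pcs = max_rank
    Y = scaled.T - scaled.T.mean(axis=0, keepdims=True)  # cells x genes, centered
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # sign convention
    for j in range(n_pcs):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U * S[None, :]
    ev = S ** 2 / max(n_cells - 1, 1)
    if cell_ids is None:
        cell_ids = np.array([str(i) for i in range(n_cells)], dtype=object)
    return Embedding(
        cell_ids=np.asarray(cell_ids, dtype=object),
        coordinates=coords,
        explained_variance=ev,
        loadings=Vt.T,
        gene_ids=None if gene_ids is None else np.asarray(gene_ids, dtype=object),
    )


# ----------------------------------------------------------------------
def _snn_graph(coords: np.ndarray, k: int):
    """kNN graph with shared-neighbor (Jaccard) edge weights."""
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[int(j)])
            union = len(neighbor_sets[i] | neighbor_sets[int(j)])
            w = shared / union
            if w > 0:
                edges.append((i, int(j)))
                weights.append(w)
    return edges, weights


def cluster_cells(embedding: Embedding, k_neighbors: int = 20,
                  resolution: float = 0.1, seed: int = 0) -> ClusterLabels:
    """Leiden modularity clustering of the shared-nearest-neighbor graph in
    PC space.  Deterministic given the seed; cluster ids are dense integers
    ordered by decreasing cluster size."""
    import igraph as ig
    import leidenalg

    coords = embedding.coordinates
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    edges, weights = _snn_graph(coords, k_neighbors)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    # dense ids by decreasing size, ties by first occurrence
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in raw])
    return ClusterLabels(
        cell_ids=embedding.cell_ids.copy(), labels=labels, resolution=resolution
    )


def silhouette_filter(embedding: Embedding, labels: ClusterLabels):
    """Remove cells with silhouette < 0 (Euclidean distances in PC space).

    Returns (retained cell id array, per-cell silhouette array).  Singleton
    clusters get silhouette 0 (retained) with a warning.
    """
    from sklearn.metrics import silhouette_samples

    lab = labels.labels
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette filter requires >=2 clusters")
    if (counts == 1).any():
        warnings.warn("singleton cluster present; its silhouette is defined as 0")
    sil = silhouette_samples(embedding.coordinates, lab)
    keep = sil >= 0
    return embedding.cell_ids[keep], sil


def flag_sample_dominated_clusters(labels: ClusterLabels, sample_of: pd.Series,
                                   fraction: float = 0.5) -> set:
    """Flag clusters in which any single sample contributes at least
    ``fraction`` of the cells (boundary inclusive: flagged at exactly 50%)."""
    samples = sample_of.loc[list(labels.cell_ids)].to_numpy()
    flagged = set()
    for cl in np.unique(labels.labels):
        m = labels.labels == cl
        _, cnt = np.unique(samples[m], return_counts=True)
        if cnt.max() / m.sum() >= fraction:
            flagged.add(int(cl))
    return flagged
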