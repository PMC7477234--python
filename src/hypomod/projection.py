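"""Confidence-thresholded label projection from reference atlases.

A reference is summarized as a projector: its variable genes, per-gene
scaling parameters, PC loadings, and labeled cell embedding.  Query cells
are normalized and scaled with the *reference* parameters, projected onto
the reference PCs, and labeled by majority vote among their k nearest
reference cells; the vote fraction is the confidence.  A label is kept only
when confidence exceeds the threshold (0.75 for the canonical neuron
atlases, 0.50 for the tanycyte/oligodendrocyte references).  Multiple
references are applied iteratively: confidently labeled cells are removed
from the query before the next reference is consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix
from .qc import normalize_log, run_pca, select_variable_genes

__all__ = [
    "ProjectionModel",
    "LabelAssignment",
    "train_reference",
    "project_labels",
    "iterative_projection",
]


@dataclass
class ProjectionModel:
    reference_id: str
    genes: np.ndarray            # variable genes used
    gene_mean: np.ndarray        # per-gene mean of normalized reference values
    gene_sd: np.ndarray          # per-gene sd (>0)
    loadings: np.ndarray         # genes x n_pcs
    ref_embedding: np.ndarray    # ref cells x n_pcs
    ref_labels: np.ndarray
    k_neighbors: int
    # novelty guard: query cells whose mean neighbor distance exceeds this
    # (the 99th percentile of the reference's own mean kNN distances) lie
    # outside the reference manifold and stay unassigned
    max_neighbor_distance: float = np.inf

    def save(self, path) -> None:
        """Write the model as a documented archive (matrices + metadata)."""
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "model.npz",
            gene_mean=self.gene_mean,
            gene_sd=self.gene_sd,
            loadings=self.loadings,
            ref_embedding=self.ref_embedding,
        )
        pd.DataFrame({"gene": self.genes}).to_csv(
            path / "genes.tsv", sep="\t", index=False)
        pd.DataFrame({"label": self.ref_labels}).to_csv(
            path / "labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"reference_id": self.reference_id, "k_neighbors": self.k_neighbors,
              "max_neighbor_distance": self.max_neighbor_distance}]
        ).to_csv(path / "meta.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        from pathlib import Path

        path = Path(path)
        arrays = np.load(path / "model.npz")
        meta = pd.read_csv(path / "meta.tsv", sep="\t").iloc[0]
        return cls(
            reference_id=str(meta["reference_id"]),
            genes=pd.read_csv(path / "genes.tsv", sep="\t")["gene"]
            .to_numpy(dtype=object),
            gene_mean=arrays["gene_mean"],
            gene_sd=arrays["gene_sd"],
            loadings=arrays["loadings"],
            ref_embedding=arrays["ref_embedding"],
            ref_labels=pd.read_csv(path / "labels.tsv", sep="\t")["label"]
            .to_numpy(dtype=object),
            k_neighbors=int(meta["k_neighbors"]),
            max_neighbor_distance=float(meta["max_neighbor_distance"]),
        )


@dataclass
class LabelAssignment:
    table: pd.DataFrame  # index cell_id: label (or NA), confidence, reference_id

    @property
    def labeled(self) -> pd.DataFrame:
        return self.table[self.table["label"].notna()]


def train_reference(ref: CountMatrix, labels: pd.Series, n_pcs: int = 30,
                    k: int = 30, n_var_genes: int = 2000,
                    reference_id: str = "ref") -> ProjectionModel:
    """Fit the projector on a labeled reference dataset."""
    missing = set(ref.cell_ids) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for {len(missing)} reference cells")
    if len(set(labels.loc[list(ref.cell_ids)])) < 2:
        raise ValueError("reference must contain >=2 distinct labels")
    if k > ref.n_cells:
        raise ValueError(f"k={k} exceeds {ref.n_cells} reference cells")
    norm = normalize_log(ref)
    var_genes = select_variable_genes(norm, ref.gene_ids,
                                      n_top=min(n_var_genes, ref.n_genes))
    gidx = ref.gene_index(var_genes)
    sub = norm[gidx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    scaled = (sub - mean[:, None]) / sd[:, None]
    emb = run_pca(scaled, cell_ids=ref.cell_ids, gene_ids=np.asarray(var_genes),
                  n_pcs=min(n_pcs, len(var_genes), ref.n_cells))
    from sklearn.neighbors import NearestNeighbors

    k_self = min(k + 1, ref.n_cells)
    self_dist, _ = (
        NearestNeighbors(n_neighbors=k_self).fit(emb.coordinates)
        .kneighbors(emb.coordinates)
    )
    max_dist = float(np.percentile(self_dist[:, 1:].mean(axis=1), 99))
    return ProjectionModel(
        reference_id=reference_id,
        genes=np.asarray(var_genes, dtype=object),
        gene_mean=mean,
        gene_sd=sd,
        loadings=emb.loadings,
        ref_embedding=emb.coordinates,
        ref_labels=labels.loc[list(ref.cell_ids)].to_numpy(dtype=object),
        k_neighbors=k,
        max_neighbor_distance=max_dist,
    )


def project_labels(model: ProjectionModel, query: CountMatrix,
                   threshold: float = 0.75) -> LabelAssignment:
    """Project query cells into the reference PC space and vote labels.

    Confidence is the vote fraction among the k nearest reference cells; a
    tie is broken by smaller mean neighbor distance, then lexicographically.
    """
    if query.n_cells == 0:
        return LabelAssignment(
            table=pd.DataFrame(columns=["label", "confidence", "reference_id"])
        )
    shared = [g for g in model.genes if g in set(query.gene_ids)]
    if len(shared) == 0:
        raise ValueError("no genes shared between reference model and query")
    if len(shared) < 10:
        warnings.warn(
            f"only {len(shared)} genes shared with reference "
            f"{model.reference_id}; all cells left unassigned"
        )
        tab = pd.DataFrame(
            {"label": pd.NA, "confidence": np.nan, "reference_id": model.reference_id},
            index=pd.Index(query.cell_ids, name="cell_id"),
        )
        return LabelAssignment(table=tab)
    model_pos = {g: i for i, g in enumerate(model.genes)}
    midx = np.array([model_pos[g] for g in shared])
    norm = normalize_log(query)
    qidx = query.gene_index(shared)
    scaled = (norm[qidx] - model.gene_mean[midx][:, None]) / model.gene_sd[midx][:, None]
    coords = scaled.T @ model.loadings[midx]  # query cells x n_pcs

    from sklearn.neighbors import NearestNeighbors

    k = min(model.k_neighbors, model.ref_embedding.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(model.ref_embedding)
    dist, idx = nn.kneighbors(coords)

    labels_out, conf_out = [], []
    for row_idx, row_dist in zip(idx, dist):
        votes: dict = {}
        dists: dict = {}
        for j, d in zip(row_idx, row_dist):
            lab = model.ref_labels[j]
            votes[lab] = votes.get(lab, 0) + 1
            dists.setdefault(lab, []).append(d)
        best = sorted(
            votes,
            key=lambda lab: (-votes[lab], float(np.mean(dists[lab])), str(lab)),
        )[0]
        conf = votes[best] / k
        if conf > threshold and row_dist.mean() <= model.max_neighbor_distance:
            labels_out.append(best)
        else:
            labels_out.append(pd.NA)
        conf_out.append(conf)
    tab = pd.DataFrame(
        {
            "label": labels_out,
            "confidence": conf_out,
            "reference_id": model.reference_id,
        },
        index=pd.Index(query.cell_ids, name="cell_id"),
    )
    tab.loc[tab["label"].isna(), "confidence"] = np.nan
    return LabelAssignment(table=tab)


def iterative_projection(references, query: CountMatrix) -> LabelAssignment:
    """Apply (model, threshold) pairs in order, removing confidently labeled
    cells from the query between references; the final assignment is the
    union.  Per-reference assignment counts are reported via warnings at the
    INFO-equivalent level (returned in the table's reference_id column)."""
    if not references:
        raise ValueError("at least one reference is required")
    remaining = query
    pieces = []
    for model, threshold in references:
        assign = project_labels(model, remaining, threshold=threshold)
        labeled = assign.table["label"].notna()
        pieces.append(assign.table[labeled])
        remaining = remaining.subset_cells((~labeled).to_numpy())
        if remaining.n_cells == 0:
            break
    out = pd.concat(pieces) if pieces else pd.DataFrame()
    unlabeled = pd.DataFrame(
        {"label": pd.NA, "confidence": np.nan, "reference_id": pd.NA},
        index=pd.Index(remaining.cell_ids, name="cell_id"),
    )
    table = pd.concat([out, unlabeled]).loc[list(query.cell_ids)]
    table.index.name = "cell_id"
    return LabelAssignment(table=table)
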