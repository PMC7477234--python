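"""Pseudobulk differential expression and the downsampling DEG test.

Single-cell counts are aggregated per sample (animal) within a cell
population and tested at the sample level with a negative-binomial Wald
GLM: median-of-ratios size factors, per-gene method-of-moments dispersion
(variance model ``mu + alpha * mu**2``), an IRLS log-link fit with
``log(size factor)`` offset, and a Wald test on the treatment coefficient.
The same engine serves pseudobulk, downsampled pseudobulk, and bulk count
tables.

To control for cell-number effects, the repeated-downsampling procedure
draws ten cells per cluster per sample (without replacement), re-runs the
pseudobulk test, and records the DEG count; 100 iterations per cluster
give a DEG-count distribution summarized by median and IQR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import CountMatrix

__all__ = [
    "PseudobulkMatrix",
    "DEResult",
    "DownsampleDistribution",
    "aggregate_pseudobulk",
    "estimate_size_factors",
    "nb_wald_test",
    "classify_degs",
    "downsample_deg_distribution",
    "abundance_test",
]

_DISPERSION_FLOOR = 1e-8


@dataclass
class PseudobulkMatrix:
    counts: np.ndarray          # genes x samples, integer
    gene_ids: np.ndarray
    design: pd.DataFrame        # index sample_id: group (+ batch, day)
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("pseudobulk sample with zero total counts")


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene: baseMean, log2fc, se, stat, p, fdr, category

    def degs(self, fdr: float = 0.05, lfc: float = 0.0) -> pd.DataFrame:
        t = self.table
        return t[(t["fdr"] < fdr) & (t["log2fc"].abs() > lfc)]


@dataclass
class DownsampleDistribution:
    deg_counts: dict            # cluster -> np.ndarray of length n_iter
    summary: pd.DataFrame       # per cluster: median, q25, q75
    n_cells: int
    n_iterations: int
    fdr_threshold: float
    skipped: list = field(default_factory=list)


# ----------------------------------------------------------------------
def aggregate_pseudobulk(counts: CountMatrix, cell_mask, sample_of: pd.Series,
                         design_cols=("group", "batch")) -> PseudobulkMatrix:
    """Sum raw counts across each gene per sample over the masked cells."""
    mask = np.asarray(cell_mask)
    if mask.dtype == bool:
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(int)
    if idx.size == 0:
        raise ValueError("empty cell mask")
    cells = counts.cell_ids[idx]
    samples = sample_of.loc[list(cells)].to_numpy(dtype=object)
    uniq = pd.unique(samples)
    X = sp.csc_matrix(counts.X)[:, idx]
    cols = []
    kept_samples = []
    for s in uniq:
        m = samples == s
        if not m.any():
            warnings.warn(f"sample {s} has no masked cells; excluded")
            continue
        cols.append(np.asarray(X[:, np.flatnonzero(m)].sum(axis=1)).ravel())
        kept_samples.append(s)
    pb = np.column_stack(cols).astype(np.int64)
    design = pd.DataFrame(index=pd.Index(kept_samples, name="sample_id"))
    meta = counts.cell_meta.loc[list(cells)]
    for c in design_cols:
        if c in meta.columns:
            per_sample = meta.groupby(meta["sample_id"])[c].first()
            design[c] = per_sample.loc[kept_samples].to_numpy()
    return PseudobulkMatrix(counts=pb, gene_ids=counts.gene_ids.copy(), design=design)


def estimate_size_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to library-size factors (with a warning) when no gene is
    nonzero in all samples.
    """
    C = pb.counts.astype(float)
    all_nonzero = (C > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no gene nonzero in all samples; using library-size factors")
        libs = C.sum(axis=0)
        sf = libs / np.exp(np.mean(np.log(libs)))
    else:
        logs = np.log(C[all_nonzero])
        log_geomean = logs.mean(axis=1)
        sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
        sf = sf / np.exp(np.mean(np.log(sf)))
    pb.size_factors = sf
    return sf


# ----------------------------------------------------------------------
def _design_matrix(design: pd.DataFrame, use_batch: bool):
    group = design["group"].to_numpy(dtype=object)
    levels = sorted(set(group))
    if "treated" in levels and "control" in levels:
        treat = (group == "treated").astype(float)
    else:
        if len(levels) != 2:
            raise ValueError(f"expected two groups, got {levels}")
        treat = (group == levels[1]).astype(float)
    cols = [np.ones(len(group)), treat]
    names = ["intercept", "group"]
    if use_batch and "batch" in design.columns:
        batches = pd.unique(design["batch"])
        for b in batches[1:]:
            cols.append((design["batch"].to_numpy() == b).astype(float))
            names.append(f"batch_{b}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix not full rank; confounded columns among {names}"
        )
    return X, names


def _mom_dispersion(q: np.ndarray, groups: np.ndarray, inv_sf_mean: float):
    """Per-gene method-of-moments dispersion from within-group moments of
    normalized counts, floored at 1e-8."""
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for g in np.unique(groups):
        m = groups == g
        n_g = int(m.sum())
        if n_g < 2:
            continue
        mean_g = q[:, m].mean(axis=1)
        var_g = q[:, m].var(axis=1, ddof=1)
        num += (n_g - 1) * (var_g - mean_g * inv_sf_mean)
        den += (n_g - 1) * mean_g ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def nb_wald_test(pb: PseudobulkMatrix, use_batch: bool = True,
                 max_iter: int = 50, tol: float = 1e-8) -> DEResult:
    """Negative-binomial Wald differential expression (treated vs control).

    The Wald statistic is referred to a t distribution with residual degrees
    of freedom (n_samples - n_coefficients), which keeps the type-I rate
    near nominal at the small per-arm sample sizes this pipeline targets.
    """
    group = pb.design["group"].to_numpy(dtype=object)
    for arm in pd.unique(group):
        if (group == arm).sum() < 2:
            raise ValueError(f"group {arm!r} has <2 samples")
    if pb.size_factors is None:
        estimate_size_factors(pb)
    sf = pb.size_factors
    X, names = _design_matrix(pb.design, use_batch=use_batch)
    S, P = X.shape
    Y = pb.counts.astype(float)
    G = Y.shape[0]
    offset = np.log(sf)

    q = Y / sf[None, :]
    alpha = _mom_dispersion(q, group, float(np.mean(1.0 / sf)))

    nonzero = Y.sum(axis=1) > 0
    Yf = Y[nonzero]
    af = alpha[nonzero]

    # IRLS, vectorized across genes
    beta = np.linalg.lstsq(X, np.log(q[nonzero] + 0.5).T, rcond=None)[0].T  # Gf x P
    XtX_cache = None
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + af[:, None] * mu)
        z = (eta - offset[None, :]) + (Yf - mu) / mu
        A = np.einsum("gs,sp,sq->gpq", W, X, X)
        b = np.einsum("gs,sp->gp", W * z, X)
        # ridge jitter guards the rare singular system (e.g. all-equal counts)
        A += 1e-10 * np.eye(P)[None, :, :]
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        XtX_cache = A
        if delta < tol:
            break
    cov = np.linalg.inv(XtX_cache)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    stat = np.where(se > 0, beta[:, 1] / se, 0.0)
    df = max(S - P, 1)
    p = 2.0 * stats.t.sf(np.abs(stat), df)

    log2 = np.log(2.0)
    table = pd.DataFrame(
        {
            "baseMean": q.mean(axis=1),
            "log2fc": np.nan,
            "se": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "fdr": np.nan,
            "category": "low",
        },
        index=pd.Index(pb.gene_ids, name="gene"),
    )
    table.loc[nonzero, "log2fc"] = beta[:, 1] / log2
    table.loc[nonzero, "se"] = se / log2
    table.loc[nonzero, "stat"] = stat
    table.loc[nonzero, "p"] = p
    table.loc[nonzero, "fdr"] = _bh(p)
    table.loc[nonzero, "category"] = "ns"
    return DEResult(table=table)


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(res: DEResult, lfc: float = 0.25, fdr: float = 0.05) -> DEResult:
    """Volcano categories: up / down when FDR < ``fdr`` and |log2fc| > ``lfc``."""
    t = res.table.copy()
    tested = t["p"].notna()
    t.loc[tested, "category"] = "ns"
    up = tested & (t["log2fc"] > lfc) & (t["fdr"] < fdr)
    down = tested & (t["log2fc"] < -lfc) & (t["fdr"] < fdr)
    t.loc[up, "category"] = "up"
    t.loc[down, "category"] = "down"
    return DEResult(table=t)


# ----------------------------------------------------------------------
def downsample_deg_distribution(counts: CountMatrix, cluster_of: pd.Series,
                                sample_of: pd.Series, group_of: pd.Series,
                                n_cells: int = 10, n_iter: int = 100,
                                fdr: float = 0.1, seed: int = 0,
                                use_batch: bool = False) -> DownsampleDistribution:
    """Repeated-downsampling DEG distribution per cluster.

    Each iteration samples ``n_cells`` cells per cluster per sample without
    replacement, aggregates to pseudobulk, runs the NB-Wald test, and counts
    genes at FDR < ``fdr``.  Clusters lacking ``n_cells`` in at least two
    samples of each arm are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    cells = counts.cell_ids
    clusters = cluster_of.loc[list(cells)].to_numpy(dtype=object)
    samples = sample_of.loc[list(cells)].to_numpy(dtype=object)
    sample_group = (
        pd.DataFrame({"sample": samples, "group": group_of.loc[list(cells)].to_numpy()})
        .drop_duplicates()
        .set_index("sample")["group"]
    )

    deg_counts: dict = {}
    skipped: list = []
    for cl in pd.unique(clusters):
        in_cl = clusters == cl
        # which samples have enough cells
        ok_samples = []
        for s in pd.unique(samples[in_cl]):
            if (in_cl & (samples == s)).sum() >= n_cells:
                ok_samples.append(s)
        arms = pd.Series([sample_group[s] for s in ok_samples])
        if len(ok_samples) == 0 or (arms.value_counts() < 2).any() or arms.nunique() < 2:
            warnings.warn(f"cluster {cl}: insufficient coverage; skipped")
            skipped.append(cl)
            continue
        counts_vec = np.zeros(n_iter, dtype=int)
        pool = {
            s: np.flatnonzero(in_cl & (samples == s)) for s in ok_samples
        }
        for it in range(n_iter):
            chosen = np.concatenate(
                [rng.choice(pool[s], size=n_cells, replace=False) for s in ok_samples]
            )
            pb = aggregate_pseudobulk(counts, chosen, sample_of)
            res = nb_wald_test(pb, use_batch=use_batch)
            counts_vec[it] = int((res.table["fdr"] < fdr).sum())
        deg_counts[cl] = counts_vec
    rows = []
    for cl, v in deg_counts.items():
        rows.append(
            {
                "cluster": cl,
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster") if rows else pd.DataFrame(
        columns=["median", "q25", "q75"]
    )
    return DownsampleDistribution(
        deg_counts=deg_counts,
        summary=summary,
        n_cells=n_cells,
        n_iterations=n_iter,
        fdr_threshold=fdr,
        skipped=skipped,
    )


# ----------------------------------------------------------------------
def abundance_test(counts_per_animal: pd.DataFrame, group_of: pd.Series) -> pd.DataFrame:
    """Two-sided Student's t test of per-animal cell numbers per cluster,
    Bonferroni-adjusted across clusters.

    ``counts_per_animal``: clusters in rows, animals in columns.
    """
    groups = group_of.loc[list(counts_per_animal.columns)].to_numpy(dtype=object)
    arms = pd.unique(groups)
    if len(arms) != 2:
        raise ValueError(f"expected two groups, got {list(arms)}")
    a_cols = groups == arms[0]
    b_cols = groups == arms[1]
    if a_cols.sum() < 2 or b_cols.sum() < 2:
        raise ValueError("need >=2 animals per group")
    rows = []
    for cl, row in counts_per_animal.iterrows():
        a = row.to_numpy(float)[a_cols]
        b = row.to_numpy(float)[b_cols]
        if np.var(a) == 0 and np.var(b) == 0:
            t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"cluster": cl, "t": float(t_stat), "p": float(p)})
    out = pd.DataFrame(rows).set_index("cluster")
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
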