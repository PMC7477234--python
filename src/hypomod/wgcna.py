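"""Signed weighted co-expression network analysis.

Implements the signed-adjacency / topological-overlap / dendrogram-cut /
eigengene workflow: adjacency ``a_ij = ((1 + cor)/2)^power`` with the soft
power chosen for approximate scale-free topology (fit R^2 >= 0.8, lowest
qualifying power in 1..30, after discarding powers whose mean connectivity
is at or above the 95th percentile across candidates); topological overlap
converted to a distance for hierarchical clustering; a deterministic
quantile-height cut with a minimum module size of 15 genes; module
eigengenes (first PC of each module's standardized submatrix); merging of
modules whose eigengene dissimilarity (1 - Pearson r) is at most 0.2, i.e.
eigengene correlation >= 0.8; and kME (gene-eigengene correlation).

Module-treatment association uses a Gaussian linear mixed model on the
per-cell eigengene with a random intercept per sample and treatment (plus
batch) as fixed effects; p-values use the normal Wald reference and are
BH-FDR corrected across modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SoftThresholdReport",
    "ModuleSet",
    "pick_soft_threshold",
    "signed_adjacency",
    "topological_overlap",
    "cut_modules",
    "module_eigengenes",
    "merge_modules",
    "compute_kme",
    "module_trait_lmm",
    "module_trait_table",
    "module_overlap_hypergeom",
]

GREY = "grey"


@dataclass
class SoftThresholdReport:
    powers: np.ndarray
    r_squared: np.ndarray
    mean_connectivity: np.ndarray
    discarded: np.ndarray  # bool mask over powers
    chosen: int
    reached_fit: bool


@dataclass
class ModuleSet:
    assignment: pd.Series            # gene -> module id ("grey" = unassigned)
    eigengenes: pd.DataFrame         # cells x modules
    kme: pd.DataFrame | None = None  # genes x modules
    power: int | None = None
    merge_history: list = field(default_factory=list)

    def modules(self) -> list:
        return [m for m in self.eigengenes.columns]

    def genes_of(self, module) -> list:
        return list(self.assignment.index[self.assignment == module])


# ----------------------------------------------------------------------
def _gene_correlation(expr: np.ndarray) -> np.ndarray:
    """Pearson correlation between genes (columns of cells x genes expr).
    Zero-variance genes get correlation 0 with everything (warned)."""
    sd = expr.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance genes; correlations set to 0")
    safe = np.where(bad, 1.0, sd)
    z = (expr - expr.mean(axis=0)) / safe
    cor = z.T @ z / expr.shape[0]
    cor[bad, :] = 0.0
    cor[:, bad] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(expr: np.ndarray, power: int) -> np.ndarray:
    """Signed adjacency ``((1 + cor)/2)^power`` over genes; symmetric, unit
    diagonal, values in [0, 1]."""
    if power < 1:
        raise ValueError("power must be >= 1")
    cor = _gene_correlation(np.asarray(expr, float))
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def pick_soft_threshold(expr: np.ndarray, powers=range(1, 31),
                        r2_target: float = 0.8, n_bins: int = 10) -> SoftThresholdReport:
    """Scale-free-topology soft-power selection.

    For each candidate power the signed adjacency's connectivity
    distribution is binned into ``n_bins`` equal-occupancy bins and the fit
    of log10 p(k) on log10 mean(k) is scored; the R^2 is signed so only
    negative-slope (scale-free-like) fits count.  Powers whose mean
    connectivity is at or above the 95th percentile of candidate mean
    connectivities are discarded; the chosen power is the lowest survivor
    with R^2 >= 0.8, else the argmax-R^2 power with a warning.
    """
    expr = np.asarray(expr, float)
    n_cells, n_genes = expr.shape
    if n_genes < 50 or n_cells < 20:
        raise ValueError("need >=50 genes and >=20 cells for power selection")
    cor = _gene_correlation(expr)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)  # connectivity excludes self
    powers = np.asarray(list(powers), dtype=int)
    r2 = np.zeros(len(powers))
    mean_k = np.zeros(len(powers))
    for i, p in enumerate(powers):
        adj = base ** p
        k = adj.sum(axis=1)
        mean_k[i] = k.mean()
        r2[i] = _scale_free_fit(k, n_bins=n_bins)
    cutoff = np.percentile(mean_k, 95)
    discarded = mean_k >= cutoff
    ok = ~discarded & (r2 >= r2_target)
    if ok.any():
        chosen = int(powers[np.flatnonzero(ok)[0]])
        reached = True
    else:
        avail = np.flatnonzero(~discarded)
        pool = avail if avail.size else np.arange(len(powers))
        chosen = int(powers[pool[np.argmax(r2[pool])]])
        reached = False
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_target}; "
            f"falling back to power {chosen} (R^2 = {r2.max():.3f})"
        )
    return SoftThresholdReport(
        powers=powers, r_squared=r2, mean_connectivity=mean_k,
        discarded=discarded, chosen=chosen, reached_fit=reached,
    )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over ``n_bins`` equal-width
    connectivity bins (empty bins dropped); positive only for
    negative-slope, scale-free-like fits."""
    k = k[k > 0]
    if np.unique(np.round(k, 12)).size < n_bins:
        raise ValueError("too few distinct connectivity values for the scale-free fit")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.sum() / k.size))
    xs, ys = np.array(xs), np.array(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0 or len(xs) < 3:
        return 0.0
    slope, _, r, *_ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def topological_overlap(adj: np.ndarray):
    """Topological overlap matrix and its dissimilarity (1 - TOM).

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    i != j with k the connectivity (row sums minus the diagonal); TOM_ii = 1.
    """
    A = np.asarray(adj, float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A0
    tom = (L + A0) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return tom, 1.0 - tom


# ----------------------------------------------------------------------
# deepSplit granularity -> minimum meaningful merge-height gap, as a
# fraction of the branch's merge-height range: a branch is split at the
# midpoint of the largest gap in its sorted merge heights when that gap
# exceeds the fraction.  A smaller fraction splits on smaller gaps, so the
# deepSplit-4 partition refines the deepSplit-2 partition by construction.
_DEEPSPLIT_GAP = {2: 0.25, 4: 0.15}


def _gap_thresholds(heights: np.ndarray, rel_delta: float) -> list:
    """Candidate cut heights: midpoints of merge-height gaps larger than
    ``rel_delta`` times the height range, widest gap first."""
    hs = np.sort(heights)
    if hs.size < 2 or np.ptp(hs) <= 0:
        return []
    gaps = np.diff(hs)
    big = np.flatnonzero(gaps > rel_delta * np.ptp(hs))
    order = big[np.argsort(-gaps[big], kind="stable")]
    return [0.5 * (hs[i] + hs[i + 1]) for i in order]


def cut_modules(dissim: np.ndarray, gene_ids, linkage_method: str | None = None,
                deep_split: int = 2, min_size: int = 15) -> pd.Series:
    """Deterministic largest-gap dendrogram cut into modules of at least
    ``min_size`` genes; genes in smaller clusters are assigned "grey".

    The tree (average linkage below 3000 genes, complete above, unless
    overridden) is cut at the midpoint of the largest gap in its sorted
    merge heights, provided that gap exceeds the deep-split-dependent
    minimum (a smaller minimum for deepSplit 4 gives finer partitions that
    refine coarser ones); each resulting branch with enough genes is
    re-cut recursively by the same rule on its own merge heights.  A branch
    with no meaningful gap — a height continuum, as inside one correlated
    block — is emitted whole.  There is no post-hoc reassignment of greyed
    genes.
    """
    if deep_split not in _DEEPSPLIT_GAP:
        raise ValueError(f"deep_split must be one of {sorted(_DEEPSPLIT_GAP)}")
    rel_delta = _DEEPSPLIT_GAP[deep_split]
    D = np.asarray(dissim, float)
    n = D.shape[0]
    gene_ids = np.asarray(gene_ids, dtype=object)
    if linkage_method is None:
        linkage_method = "average" if n < 3000 else "complete"

    clusters: list[list[int]] = []

    def recurse(idx: np.ndarray) -> None:
        if idx.size < 2:
            clusters.append(list(idx))
            return
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(np.maximum(sub, 0.0), checks=False),
                    method=linkage_method)
        candidates = _gap_thresholds(Z[:, 2], rel_delta) if idx.size >= 2 * min_size else []
        for t in candidates:
            labels = fcluster(Z, t=t, criterion="distance")
            _, sizes = np.unique(labels, return_counts=True)
            # accept only cuts that carve out at least two viable modules
            if (sizes >= min_size).sum() >= 2:
                for cl in np.unique(labels):
                    recurse(idx[labels == cl])
                return
        clusters.append(list(idx))

    recurse(np.arange(n))

    # grey out small clusters; number modules M1, M2, ... by decreasing size
    out = np.array([GREY] * n, dtype=object)
    big = sorted(
        (c for c in clusters if len(c) >= min_size),
        key=lambda c: (-len(c), min(c)),
    )
    for mi, c in enumerate(big, start=1):
        out[np.asarray(c)] = f"M{mi}"
    if (out == GREY).all():
        warnings.warn("all genes unassigned (grey)")
    return pd.Series(out, index=pd.Index(gene_ids, name="gene"), name="module")


# ----------------------------------------------------------------------
def module_eigengenes(expr: np.ndarray, assignment: pd.Series,
                      cell_ids=None) -> pd.DataFrame:
    """First-PC cell embedding of each module's standardized submatrix,
    oriented so the eigengene correlates positively with mean member
    expression.  Columns are unit-norm."""
    expr = np.asarray(expr, float)
    genes = np.asarray(assignment.index, dtype=object)
    if expr.shape[1] != len(genes):
        raise ValueError("expr must be cells x genes aligned with assignment")
    mods = [m for m in pd.unique(assignment.to_numpy()) if m != GREY]
    if not mods:
        raise ValueError("no non-grey module")
    cols = {}
    for m in mods:
        gidx = np.flatnonzero(assignment.to_numpy() == m)
        if gidx.size < 2:
            raise ValueError(f"module {m} has <2 genes")
        sub = expr[:, gidx]
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=0)) / sd
        U, S, Vt = np.linalg.svd(z, full_matrices=False)
        e = U[:, 0]
        mean_expr = z.mean(axis=1)
        if np.corrcoef(e, mean_expr)[0, 1] < 0:
            e = -e
        cols[m] = e
    idx = (pd.Index(cell_ids, name="cell_id") if cell_ids is not None
           else pd.RangeIndex(expr.shape[0]))
    return pd.DataFrame(cols, index=idx)


def merge_modules(expr: np.ndarray, assignment: pd.Series,
                  cut_height: float = 0.2, cell_ids=None):
    """Iteratively merge the closest module pair while the eigengene
    dissimilarity (1 - Pearson r) is at most ``cut_height``; eigengenes are
    recomputed after every merge.  Returns (assignment, eigengenes, history)."""
    assignment = assignment.copy()
    history = []
    while True:
        eig = module_eigengenes(expr, assignment, cell_ids=cell_ids)
        mods = list(eig.columns)
        if len(mods) < 2:
            break
        cor = np.corrcoef(eig.to_numpy().T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        best = cor[i, j]
        # merge iff dissimilarity <= cut_height (correlation >= 1 - cut_height)
        if (1.0 - best) > cut_height + 1e-9:
            break
        a, b = mods[i], mods[j]
        keep, drop = (a, b) if str(a) < str(b) else (b, a)
        assignment[assignment == drop] = keep
        history.append((drop, keep, float(best)))
    eig = module_eigengenes(expr, assignment, cell_ids=cell_ids)
    return assignment, eig, history


def compute_kme(expr: np.ndarray, eigengenes: pd.DataFrame,
                gene_ids) -> pd.DataFrame:
    """kME: Pearson correlation of each gene with each module eigengene."""
    expr = np.asarray(expr, float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    sd = expr.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance genes; kME set to 0")
    safe = np.where(bad, 1.0, sd)
    zg = (expr - expr.mean(axis=0)) / safe
    E = eigengenes.to_numpy()
    ze = (E - E.mean(axis=0)) / E.std(axis=0)
    kme = zg.T @ ze / expr.shape[0]
    kme[bad, :] = 0.0
    return pd.DataFrame(np.clip(kme, -1, 1), index=pd.Index(gene_ids, name="gene"),
                        columns=eigengenes.columns)


# ----------------------------------------------------------------------
def _reml_random_intercept(y, X, groups):
    """Random-intercept Gaussian mixed model fit by REML, profiling the
    single variance ratio lambda = var(sample) / var(residual).

    The per-sample covariance ``I + lambda * 11'`` is inverted in closed
    form (Sherman-Morrison), so the profiled criterion is a cheap scalar
    function of log-lambda.  Returns (beta vector, cov(beta), sigma2,
    lambda)."""
    from scipy.optimize import minimize_scalar

    uniq, inv = np.unique(groups, return_inverse=True)
    n_per = np.bincount(inv)
    N, p = X.shape

    def gls(lam):
        # accumulate X'V^-1X, X'V^-1y, y'V^-1y and log|V| over sample blocks
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        for gi, n_s in enumerate(n_per):
            m = inv == gi
            Xs, ys = X[m], y[m]
            c = lam / (1.0 + lam * n_s)
            sx = Xs.sum(axis=0)
            sy = ys.sum()
            XtVX += Xs.T @ Xs - c * np.outer(sx, sx)
            XtVy += Xs.T @ ys - c * sx * sy
            ytVy += ys @ ys - c * sy * sy
            logdet += np.log1p(lam * n_s)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta  # r'V^-1 r
        return beta, XtVX, rss, logdet

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        _, XtVX, rss, logdet = gls(lam)
        sign, logdet_xx = np.linalg.slogdet(XtVX)
        if sign <= 0 or rss <= 0:
            return np.inf
        return logdet + (N - p) * np.log(rss) + logdet_xx

    opt = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(opt.x))
    if neg_reml(-30.0) <= opt.fun:  # boundary: no between-sample variance
        lam = 0.0
    beta, XtVX, rss, _ = gls(lam)
    sigma2 = rss / (N - p)
    cov = sigma2 * np.linalg.inv(XtVX)
    return beta, cov, sigma2, lam


def module_trait_lmm(eigengene: np.ndarray, treatment: np.ndarray,
                     sample: np.ndarray, batch: np.ndarray | None = None):
    """Per-cell eigengene ~ treatment (+ batch) with a random intercept per
    sample, fit by REML (1-D profiled optimization over the variance
    ratio); returns (beta, se, p) for the treatment effect.

    The Wald statistic is referred to a t distribution with
    ``n_samples - n_fixed_effects`` degrees of freedom — the between-sample
    information that identifies the treatment effect — which is exact for
    balanced designs and keeps null p-values uniform at the small per-arm
    sample counts this pipeline targets.
    """
    y = np.asarray(eigengene, float)
    treat = np.asarray(
        [1.0 if t in (1, True, "treated") else 0.0 for t in np.asarray(treatment)]
    )
    groups = np.asarray(sample, dtype=object)
    arms: dict = {}
    for s, t in zip(groups, treat):
        arms.setdefault(t, set()).add(s)
    if len(arms) < 2 or any(len(v) < 2 for v in arms.values()):
        raise ValueError("need >=2 samples per treatment arm")
    cols = [np.ones_like(y), treat]
    if batch is not None:
        b = np.asarray(batch, dtype=object)
        for lvl in pd.unique(b)[1:]:
            col = (b == lvl).astype(float)
            # skip batch columns confounded with existing columns
            if np.linalg.matrix_rank(np.column_stack(cols + [col])) > len(cols):
                cols.append(col)
    X = np.column_stack(cols)
    beta_vec, cov, _, lam = _reml_random_intercept(y, X, groups)
    if lam == 0.0:
        warnings.warn("no between-sample variance; fit degenerates to OLS")
    beta = float(beta_vec[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    df = max(len(np.unique(groups)) - X.shape[1], 1)
    t_stat = beta / se if se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return beta, se, p


def module_trait_table(eigengenes: pd.DataFrame, treatment, sample,
                       batch=None) -> pd.DataFrame:
    """module_trait_lmm for every module, BH-FDR corrected across modules."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for m in eigengenes.columns:
        beta, se, p = module_trait_lmm(
            eigengenes[m].to_numpy(), treatment, sample, batch
        )
        rows.append({"module": m, "beta": beta, "se": se, "p": p})
    out = pd.DataFrame(rows).set_index("module")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
def module_overlap_hypergeom(modules_a: pd.Series, modules_b: pd.Series,
                             universe) -> pd.DataFrame:
    """Upper-tail hypergeometric p of gene overlap for every module pair
    (grey excluded), Bonferroni-adjusted over all pairs."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    mods_a = [m for m in pd.unique(modules_a.to_numpy()) if m != GREY]
    mods_b = [m for m in pd.unique(modules_b.to_numpy()) if m != GREY]
    rows = []
    for ma in mods_a:
        ga = set(modules_a.index[modules_a == ma]) & universe
        for mb in mods_b:
            gb = set(modules_b.index[modules_b == mb]) & universe
            ov = len(ga & gb)
            p = float(stats.hypergeom.sf(ov - 1, N, len(ga), len(gb)))
            rows.append({"module_a": ma, "module_b": mb, "overlap": ov,
                         "size_a": len(ga), "size_b": len(gb), "p": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
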