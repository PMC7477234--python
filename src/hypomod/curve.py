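"""Principal-curve "pseudoventricle" scoring and binned group testing.

Tanycyte-like populations lining the third ventricle form a 1-D expression
continuum in the first two PCs.  A principal curve fit to that embedding
assigns each cell an arc-length coordinate (lambda), oriented so the
ventral-marker-high end sits at 0 and rescaled to [0, n_bins]; width-1 bins
along the curve are then tested for treatment differences in scaled module
expression with the random-intercept mixed model, Bonferroni-adjusted
within module, and a module is flagged when at least ``k`` consecutive
tested bins are significant.

The curve fit is the projection/smooth iteration of Hastie & Stuetzle:
starting from the first principal component line, alternately (i) order
cells by lambda and smooth each coordinate against lambda with a lowess
smoother (span 0.3), and (ii) re-project cells onto the resulting polyline,
until the total squared projection distance stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PseudoventricleFit",
    "BinnedTestResult",
    "fit_principal_curve",
    "orient_and_scale",
    "score_module_per_cell",
    "binned_group_test",
    "consecutive_significant_run",
]


@dataclass
class PseudoventricleFit:
    curve: np.ndarray           # ordered polyline, points x 2
    lam: np.ndarray             # per-cell arc length (raw, or rescaled to [0, n_bins])
    cell_ids: np.ndarray | None = None
    n_iter: int = 0
    mean_sq_dist: float = np.nan
    oriented: bool = False
    n_bins: int | None = None


@dataclass
class BinnedTestResult:
    table: pd.DataFrame  # per bin: bin, n_treated, n_control, mean/sem per group, p, p_adj, tested
    longest_run: int = 0
    flag: bool = False
    alpha: float = 0.05
    run_k: int = 5


# ----------------------------------------------------------------------
def _project_to_polyline(points: np.ndarray, curve: np.ndarray):
    """Project points onto the polyline; return (lambda = arc length of the
    projection foot, squared distances)."""
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 0
    seg_start, seg_vec, seg_len = seg_start[keep], seg_vec[keep], seg_len[keep]
    if len(seg_len) == 0:
        raise ValueError("degenerate curve (single point)")
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    # points x segments
    diff = points[:, None, :] - seg_start[None, :, :]
    t = np.einsum("psd,sd->ps", diff, seg_vec) / (seg_len ** 2)[None, :]
    t = np.clip(t, 0.0, 1.0)
    foot = seg_start[None, :, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(points.shape[0])
    lam = arc0[best] + t[rows, best] * seg_len[best]
    return lam, d2[rows, best]


def fit_principal_curve(embedding: np.ndarray, max_iter: int = 50,
                        tol: float = 1e-3, span: float = 0.3,
                        cell_ids=None) -> PseudoventricleFit:
    """Hastie-Stuetzle principal curve on a cells x 2 embedding."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    pts = np.asarray(embedding, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("embedding must be cells x 2")
    if pts.shape[0] < 20:
        raise ValueError("need >= 20 cells")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical; cannot fit a curve")

    center = pts.mean(axis=0)
    Y = pts - center
    _, _, Vt = np.linalg.svd(Y, full_matrices=False)
    lam = Y @ Vt[0]
    curve = np.empty((0, 2))
    prev_d2 = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        lam_sorted = lam[order]
        smoothed = np.empty_like(pts)
        for d in range(2):
            fitted = lowess(
                pts[order, d], lam_sorted, frac=span, it=0, return_sorted=False
            )
            smoothed[:, d] = fitted
        # polyline over unique lambda positions, in lambda order
        curve = smoothed
        # collapse duplicate lambda positions to single curve points
        uniq_mask = np.concatenate([[True], np.diff(lam_sorted) > 0])
        curve = curve[uniq_mask]
        lam, d2 = _project_to_polyline(pts, curve)
        total = float(d2.sum())
        if prev_d2 < np.inf and abs(prev_d2 - total) <= tol * max(prev_d2, 1e-12):
            prev_d2 = total
            break
        prev_d2 = total
    return PseudoventricleFit(
        curve=curve,
        lam=lam,
        cell_ids=None if cell_ids is None else np.asarray(cell_ids, dtype=object),
        n_iter=n_iter,
        mean_sq_dist=prev_d2 / pts.shape[0],
    )


def orient_and_scale(fit: PseudoventricleFit, anchor_expression: np.ndarray,
                     n_bins: int = 30) -> PseudoventricleFit:
    """Orient lambda so the anchor-high (ventral) end maps to 0, then
    rescale linearly to [0, n_bins]."""
    anchor = np.asarray(anchor_expression, float)
    ok = np.isfinite(anchor)
    if ok.sum() < 10:
        raise ValueError("anchor expression available for <10 cells")
    lam = fit.lam.copy()
    r = np.corrcoef(anchor[ok], lam[ok])[0, 1]
    if abs(r) < 0.1:
        warnings.warn("anchor barely correlates with lambda; keeping orientation")
    elif r > 0:
        lam = lam.max() - lam
    span = np.ptp(lam)
    if span == 0:
        raise ValueError("lambda has zero range")
    lam = (lam - lam.min()) / span * n_bins
    return PseudoventricleFit(
        curve=fit.curve.copy(),
        lam=lam,
        cell_ids=fit.cell_ids,
        n_iter=fit.n_iter,
        mean_sq_dist=fit.mean_sq_dist,
        oriented=True,
        n_bins=n_bins,
    )


# ----------------------------------------------------------------------
def score_module_per_cell(norm_expr: np.ndarray, gene_ids, module_genes) -> np.ndarray:
    """Scaled module expression: mean over module genes of the z-scored
    normalized expression.  Zero-variance genes contribute 0."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = [pos[g] for g in module_genes if g in pos]
    if len(idx) < 2:
        raise ValueError("fewer than 2 module genes present in the matrix")
    sub = np.asarray(norm_expr, float)[idx]  # genes x cells
    sd = sub.std(axis=1)
    mean = sub.mean(axis=1)
    z = np.where(sd[:, None] > 0, (sub - mean[:, None]) / np.where(sd == 0, 1, sd)[:, None], 0.0)
    return z.mean(axis=0)


def binned_group_test(lam: np.ndarray, score: np.ndarray, group: np.ndarray,
                      sample: np.ndarray, bin_width: float = 1.0,
                      min_cells: int = 3, alpha: float = 0.05,
                      run_k: int = 5) -> BinnedTestResult:
    """Treatment effect on module score within width-1 lambda bins.

    Each bin with >=``min_cells`` cells and >=2 samples per group is tested
    with the random-intercept mixed model (falling back to a two-sample t
    test when an arm retains a single sample); Bonferroni adjustment spans
    the tested bins only.
    """
    from .wgcna import module_trait_lmm

    lam = np.asarray(lam, float)
    score = np.asarray(score, float)
    group = np.asarray(group, dtype=object)
    sample = np.asarray(sample, dtype=object)
    arms = pd.unique(group)
    if len(arms) != 2:
        raise ValueError(f"expected two groups, got {list(arms)}")
    treated_arm = "treated" if "treated" in arms else arms[0]
    n_bins = int(np.ceil(lam.max() / bin_width)) if lam.max() > 0 else 1
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        m = (lam >= lo) & (lam < hi) if b < n_bins - 1 else (lam >= lo) & (lam <= hi)
        row = {"bin": b, "lo": lo, "hi": hi, "tested": False, "p": np.nan,
               "method": None}
        for arm in arms:
            s = score[m & (group == arm)]
            key = "treated" if arm == treated_arm else "control"
            row[f"n_{key}"] = int(s.size)
            row[f"mean_{key}"] = float(s.mean()) if s.size else np.nan
            row[f"sem_{key}"] = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else np.nan
        ok = all(
            (m & (group == arm)).sum() >= min_cells for arm in arms
        )
        n_samples_per_arm = {
            arm: len(set(sample[m & (group == arm)])) for arm in arms
        }
        if ok and all(v >= 2 for v in n_samples_per_arm.values()):
            beta, se, p = module_trait_lmm(score[m], group[m] == treated_arm,
                                           sample[m])
            row.update(tested=True, p=p, beta=beta, method="lmm")
        elif ok and all(v >= 1 for v in n_samples_per_arm.values()):
            a = score[m & (group == treated_arm)]
            bscore = score[m & (group != treated_arm)]
            t_stat, p = stats.ttest_ind(a, bscore, equal_var=False)
            row.update(tested=True, p=float(p), beta=float(a.mean() - bscore.mean()),
                       method="ttest")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("bin")
    tested = table["tested"]
    if not tested.any():
        raise ValueError("no testable bins")
    n_tested = int(tested.sum())
    table["p_adj"] = np.nan
    table.loc[tested, "p_adj"] = np.minimum(table.loc[tested, "p"] * n_tested, 1.0)
    run, flag = consecutive_significant_run(
        table["p_adj"].to_numpy(), alpha=alpha, k=run_k
    )
    return BinnedTestResult(table=table, longest_run=run, flag=flag,
                            alpha=alpha, run_k=run_k)


def consecutive_significant_run(adjusted_p: np.ndarray, alpha: float = 0.05,
                                k: int = 5):
    """Longest run of consecutive tested bins with adjusted p < alpha;
    untested (NaN) bins break runs.  Returns (longest run, run >= k)."""
    p = np.asarray(adjusted_p, float)
    best = cur = 0
    for v in p:
        if np.isfinite(v) and v < alpha:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best, best >= k
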