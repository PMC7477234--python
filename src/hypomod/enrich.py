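"""Enrichment statistics: hypergeometric over-representation with the
direction z-score, preranked GSEA with a permutation NES, rank-rank
hypergeometric overlap (RRHO) maps, and construction of astrocyte
reactivity genesets from external DE tables.

All hypergeometric tails go through one kernel (scipy's hypergeometric
survival function), so the over-representation and RRHO paths agree
exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection

__all__ = [
    "hypergeom_enrich",
    "direction_zscore",
    "preranked_gsea",
    "rrho_map",
    "build_reactivity_genesets",
]


def _hyper_tail(overlap: int, universe: int, set_a: int, set_b: int) -> float:
    """Upper-tail P(X >= overlap) for overlap of two sets in a universe."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_a, set_b))


# ----------------------------------------------------------------------
def hypergeom_enrich(query, collection: GeneSetCollection, background,
                     min_size: int = 10, max_size: int = 300,
                     min_intersect: int = 3,
                     up: set | None = None, down: set | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Terms are intersected with the background; terms outside
    [``min_size``, ``max_size``] or overlapping the query in fewer than
    ``min_intersect`` genes are excluded before Bonferroni correction.
    When ``up``/``down`` sets are given, each tested term also gets the
    direction z-score.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for term, (name, genes) in collection.items():
        term_genes = set(genes) & background
        if not (min_size <= len(term_genes) <= max_size):
            continue
        overlap = query & term_genes
        if len(overlap) < min_intersect:
            continue
        p = _hyper_tail(len(overlap), len(background), len(term_genes), len(query))
        z = (
            direction_zscore(overlap, up, down)
            if up is not None and down is not None
            else np.nan
        )
        rows.append(
            {
                "term_id": term,
                "name": name,
                "term_size": len(term_genes),
                "overlap": len(overlap),
                "genes": ",".join(sorted(overlap)),
                "p": p,
                "direction_z": z,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "name", "term_size", "overlap", "genes", "p", "direction_z"],
    )
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    return out


def direction_zscore(overlap, up, down) -> float:
    """(n_up - n_down) / sqrt(n_overlap) over a term's query overlap.

    Genes in neither direction set count only in the denominator.  An empty
    overlap has no defined direction (NaN).
    """
    overlap = set(overlap)
    if not overlap:
        return float("nan")
    n_up = len(overlap & set(up))
    n_down = len(overlap & set(down))
    return (n_up - n_down) / np.sqrt(len(overlap))


# ----------------------------------------------------------------------
def _es_running(stat_sorted: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Enrichment score: max-deviation of the weighted KS running sum over a
    ranking (genes sorted by decreasing statistic; ``hit`` marks members)."""
    w = np.abs(stat_sorted) ** weight
    hit_w = np.where(hit, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        return 0.0
    n_miss = (~hit).sum()
    steps = hit_w / total_hit - np.where(hit, 0.0, 1.0 / max(n_miss, 1))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(ranking: pd.Series, term_genes, n_perm: int = 1000,
                   weight: float = 1.0, seed: int = 0) -> dict:
    """Preranked GSEA for one term against a gene -> statistic ranking.

    The null permutes gene labels (random member sets of equal size); the
    normalized enrichment score divides ES by the mean magnitude of
    same-sign null scores, and the empirical two-sided p uses the add-one
    correction (so p >= 1/(n_perm + 1)).  Leading-edge genes are the
    members at or before the ES extremum.
    """
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = np.asarray(ranking.index, dtype=object)
    stat = ranking.to_numpy(float)
    members = set(term_genes) & set(genes)
    if len(members) == 0:
        raise ValueError("term has no genes in the ranked universe")
    if len(members) < 3:
        raise ValueError("term needs >=3 genes in the ranked universe")
    hit = np.array([g in members for g in genes])
    es = _es_running(stat, hit, weight)

    rng = np.random.default_rng(seed)
    n = len(genes)
    m = int(hit.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=m, replace=False)] = True
        null[i] = _es_running(stat, perm_hit, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    p = (1.0 + (np.abs(null) >= abs(es)).sum()) / (n_perm + 1.0)

    # leading edge
    w = np.abs(stat) ** weight
    hit_w = np.where(hit, w, 0.0)
    steps = hit_w / max(hit_w.sum(), 1e-300) - np.where(hit, 0.0, 1.0 / max((~hit).sum(), 1))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        lead = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        lead = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
    return {
        "es": es,
        "nes": float(nes),
        "p": float(p),
        "leading_edge": lead,
        "n_perm": n_perm,
        "seed": seed,
    }


# ----------------------------------------------------------------------
def rrho_map(list_a, list_b, step: int | None = None,
             by_adjust: bool = False) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap map.

    For each threshold pair (i*step, j*step) the overlap of the top-i*step
    genes of A with the top-j*step genes of B is scored with the upper-tail
    hypergeometric -log10 p (one-sided over-enrichment).  Returns a
    DataFrame indexed/columned by the thresholds; with ``by_adjust`` the
    Benjamini-Yekutieli-adjusted grid is returned instead.
    """
    list_a = list(list_a)
    list_b = list(list_b)
    if set(list_a) != set(list_b):
        diff = set(list_a) ^ set(list_b)
        raise ValueError(
            f"rankings cover different universes; symmetric difference: {sorted(diff)[:10]}"
        )
    n = len(list_a)
    if step is None:
        step = max(1, n // 100)
    rank_b = {g: i for i, g in enumerate(list_b)}
    pos_b = np.array([rank_b[g] for g in list_a])
    thresholds = np.arange(step, n + 1, step)
    # cumulative 2-D overlap counts via a histogram of (rank_a, rank_b)
    H, _, _ = np.histogram2d(
        np.arange(n), pos_b, bins=[np.r_[0, thresholds], np.r_[0, thresholds]]
    )
    O = H.cumsum(axis=0).cumsum(axis=1)
    grid = np.empty_like(O)
    for i, ta in enumerate(thresholds):
        for j, tb in enumerate(thresholds):
            grid[i, j] = -np.log10(
                max(_hyper_tail(int(O[i, j]), n, int(ta), int(tb)), 1e-320)
            )
    if by_adjust:
        from statsmodels.stats.multitest import multipletests

        p = np.power(10.0, -grid).ravel()
        adj = multipletests(np.clip(p, 0, 1), method="fdr_by")[1]
        grid = -np.log10(np.clip(adj, 1e-320, 1.0)).reshape(grid.shape)
    return pd.DataFrame(grid, index=pd.Index(thresholds, name="top_a"),
                        columns=pd.Index(thresholds, name="top_b"))


# ----------------------------------------------------------------------
def build_reactivity_genesets(de_tables: dict, pan_pair=("LPS", "MCAO"),
                              lfc_min: float = 2.0, fdr_max: float = 0.05,
                              skip_fdr: set | None = None) -> GeneSetCollection:
    """Condition-specific reactivity genesets from named DE tables.

    Per condition, genes with log2fc > ``lfc_min`` and FDR < ``fdr_max``
    (the FDR clause is dropped for conditions in ``skip_fdr``) form the
    candidate set.  Genes present in both ``pan_pair`` conditions move to a
    PAN-reactive set; any remaining overlap between the pair is removed
    from both, so condition-specific sets are pairwise disjoint.
    """
    skip_fdr = skip_fdr or set()
    for cond in pan_pair:
        if cond not in de_tables:
            raise ValueError(f"missing required condition {cond!r}")
    raw = {}
    for cond, table in de_tables.items():
        t = table.table if hasattr(table, "table") else table
        m = t["log2fc"] > lfc_min
        if cond not in skip_fdr:
            m &= t["fdr"] < fdr_max
        raw[cond] = set(t.index[m])
    a, b = pan_pair
    pan = raw[a] & raw[b]
    sets = {"PAN": ("pan-reactive", frozenset(pan))} if pan else {}
    for cond, genes in raw.items():
        specific = genes - pan
        if cond in pan_pair:
            other = raw[b] if cond == a else raw[a]
            specific -= other
        if specific:
            sets[cond] = (f"{cond}-specific", frozenset(specific))
    return GeneSetCollection(sets=sets)
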