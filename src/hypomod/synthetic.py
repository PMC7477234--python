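"""Seeded synthetic count data with known ground truth.

The generator emulates the data structures the analysis pipeline assumes:

* multi-sample two-group (treated vs control) UMI count matrices with
  distinct cell types, marker genes, batch structure, and planted
  differential expression;
* correlated gene modules driven by a per-cell latent Gaussian factor whose
  mean is shifted by treatment (so eigengene recovery and the module-trait
  mixed model have a known beta);
* a gradient cell type whose zone markers vary smoothly along a latent
  position ``t`` in [0, 1] (a tanycyte-like dorsoventral continuum);
* labeled reference datasets for projection testing, and paired ranked gene
  lists with controlled rank concordance.

Counts are negative binomial with the mean-dispersion parameterization
``var = mu + alpha * mu**2``; ``alpha`` is drawn per gene from a gamma
prior, matching the model assumed by the differential-expression engine.
Per-cell sequencing depth is log-normal; gene means are converted to
per-cell proportions so a cell's expected total equals its drawn depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix

__all__ = [
    "CellTypeSpec",
    "SampleSpec",
    "DESpec",
    "ModuleSpec",
    "GradientSpec",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_reference",
    "simulate_ranked_pair",
    "default_config",
]


@dataclass
class CellTypeSpec:
    name: str
    n_cells_per_sample: int
    marker_genes: Sequence[str] = ()
    marker_log2fc: float = 2.0


@dataclass
class SampleSpec:
    sample_id: str
    group: str  # "treated" | "control"
    batch_id: str = "b0"


@dataclass
class DESpec:
    """Planted treatment effect: a fraction of eligible genes shift by a
    random log2 fold change (sign chosen at random) in treated cells of the
    affected cell types (all types when ``affected_cell_types`` is None)."""

    fraction_de: float = 0.0
    log2fc_mean: float = 1.0
    log2fc_sd: float = 0.25
    affected_cell_types: Sequence[str] | None = None


@dataclass
class ModuleSpec:
    """Co-expression module: member genes share a per-cell latent Gaussian
    factor added (times ``loading``) to their log2 mean; treatment shifts
    the factor mean by ``treatment_effect``."""

    genes: Sequence[str]
    loading: float = 1.0
    treatment_effect: float = 0.0


@dataclass
class GradientSpec:
    """1-D latent gradient within one cell type.  ``zone_markers`` maps a
    gene to a smooth function of t in [0, 1] returning a log2 modulation of
    that gene's mean."""

    cell_type: str
    zone_markers: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)


@dataclass
class SimConfig:
    n_genes: int
    cell_types: list[CellTypeSpec]
    samples: list[SampleSpec]
    library_meanlog: float = 8.0   # exp(8) ~ 3000 UMIs/cell
    library_sdlog: float = 0.3
    dispersion_shape: float = 2.0  # gamma prior on per-gene alpha
    dispersion_scale: float = 0.15
    de_spec: DESpec = field(default_factory=DESpec)
    modules: list[ModuleSpec] = field(default_factory=list)
    gradient: GradientSpec | None = None
    mito_fraction: float = 0.05
    ribo_fraction: float = 0.05
    n_mito_genes: int = 13
    n_ribo_genes: int = 20
    seed: int = 0

    # ------------------------------------------------------------------
    def gene_ids(self) -> np.ndarray:
        return np.array([f"g{i:05d}" for i in range(self.n_genes)], dtype=object)

    def validate(self) -> None:
        universe = set(self.gene_ids())
        claimed: dict[str, str] = {}
        for ct in self.cell_types:
            for g in ct.marker_genes:
                if g not in universe:
                    raise ValueError(f"marker gene {g!r} outside gene universe")
                if g in claimed:
                    raise ValueError(
                        f"gene {g!r} assigned to both {claimed[g]} and marker:{ct.name}"
                    )
                claimed[g] = f"marker:{ct.name}"
        for i, m in enumerate(self.modules):
            for g in m.genes:
                if g not in universe:
                    raise ValueError(f"module gene {g!r} outside gene universe")
                if g in claimed:
                    raise ValueError(
                        f"gene {g!r} assigned to both {claimed[g]} and module:{i}"
                    )
                claimed[g] = f"module:{i}"
        if self.gradient is not None:
            names = {ct.name for ct in self.cell_types}
            if self.gradient.cell_type not in names:
                raise ValueError(f"gradient cell type {self.gradient.cell_type!r} unknown")
            for g in self.gradient.zone_markers:
                if g not in universe:
                    raise ValueError(f"zone marker {g!r} outside gene universe")
        if not 0 <= self.de_spec.fraction_de <= 1:
            raise ValueError("fraction_de must be in [0, 1]")
        if self.mito_fraction < 0 or self.ribo_fraction < 0 or (
            self.mito_fraction + self.ribo_fraction >= 1
        ):
            raise ValueError("mito/ribo fractions must be non-negative and sum below 1")
        if self.de_spec.fraction_de > 0:
            for arm in ("treated", "control"):
                if sum(s.group == arm for s in self.samples) < 2:
                    raise ValueError(
                        f"de_spec requires >=2 samples in the {arm} arm"
                    )
        for s in self.samples:
            if s.group not in ("treated", "control"):
                raise ValueError(f"unknown group {s.group!r}")


@dataclass
class SimTruth:
    """Ground truth for every simulated cell and gene."""

    cells: pd.DataFrame  # index cell_id: type, sample_id, group, batch, lambda_true (NaN if absent)
    genes: pd.DataFrame  # index gene_id: is_de, true_log2fc, module_id, marker_of


# ----------------------------------------------------------------------
def _base_abundance(config: SimConfig, rng: np.random.Generator):
    """Per-gene relative abundance with mito/ribo genes flagged and scaled so
    their expected UMI share matches the configured fractions."""
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_ribo = np.zeros(config.n_genes, dtype=bool)
    # flag the trailing genes, keeping the front of the universe free for
    # markers/modules declared by index
    n_m, n_r = config.n_mito_genes, config.n_ribo_genes
    if n_m:
        is_mito[-n_m:] = True
    if n_r:
        is_ribo[-(n_m + n_r):-n_m if n_m else None] = True
    other = ~(is_mito | is_ribo)
    rest = base[other].sum()
    denom = 1.0 - config.mito_fraction - config.ribo_fraction
    if n_m:
        base[is_mito] *= (config.mito_fraction / denom) * rest / base[is_mito].sum()
    if n_r:
        base[is_ribo] *= (config.ribo_fraction / denom) * rest / base[is_ribo].sum()
    return base, is_mito, is_ribo


def simulate_dataset(config: SimConfig, seed: int | None = None):
    """Draw a (CountMatrix, SimTruth) pair from the configured generative model.

    Identical ``(config, seed)`` gives bit-identical output.  When ``seed``
    is None the config's own seed is used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # gene-level parameters are a property of the configured universe: they
    # depend only on the config seed, so independently seeded draws (e.g. a
    # reference and a query dataset) describe the same genes
    rng_genes = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids = config.gene_ids()
    base, is_mito, is_ribo = _base_abundance(config, rng_genes)
    alpha = np.maximum(rng_genes.gamma(config.dispersion_shape, config.dispersion_scale,
                                       size=config.n_genes), 1e-8)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # cell bookkeeping
    cell_type, cell_sample, cell_group, cell_batch = [], [], [], []
    for s in config.samples:
        for ct in config.cell_types:
            cell_type += [ct.name] * ct.n_cells_per_sample
            cell_sample += [s.sample_id] * ct.n_cells_per_sample
            cell_group += [s.group] * ct.n_cells_per_sample
            cell_batch += [s.batch_id] * ct.n_cells_per_sample
    n_cells = len(cell_type)
    cell_type = np.array(cell_type, dtype=object)
    cell_sample = np.array(cell_sample, dtype=object)
    cell_group = np.array(cell_group, dtype=object)
    cell_batch = np.array(cell_batch, dtype=object)
    treated = cell_group == "treated"

    # log2 effect matrix (genes x cells), assembled sparsely by blocks
    log2eff = np.zeros((config.n_genes, n_cells))

    marker_of = np.array([None] * config.n_genes, dtype=object)
    for ct in config.cell_types:
        idx = [gene_pos[g] for g in ct.marker_genes]
        if idx:
            marker_of[idx] = ct.name
            in_type = cell_type == ct.name
            log2eff[np.ix_(idx, np.flatnonzero(in_type))] += ct.marker_log2fc

    # planted DE
    is_de = np.zeros(config.n_genes, dtype=bool)
    true_log2fc = np.zeros(config.n_genes)
    if config.de_spec.fraction_de > 0:
        eligible = np.flatnonzero(
            (marker_of == None) & ~is_mito & ~is_ribo  # noqa: E711
        )
        module_genes = {g for m in config.modules for g in m.genes}
        eligible = np.array([i for i in eligible if gene_ids[i] not in module_genes])
        n_de = int(round(config.de_spec.fraction_de * config.n_genes))
        n_de = min(n_de, eligible.size)
        de_idx = rng.choice(eligible, size=n_de, replace=False)
        is_de[de_idx] = True
        mag = rng.normal(config.de_spec.log2fc_mean, config.de_spec.log2fc_sd, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        true_log2fc[de_idx] = sign * np.abs(mag)
        affected = config.de_spec.affected_cell_types
        cell_affected = treated if affected is None else (
            treated & np.isin(cell_type, list(affected))
        )
        log2eff[np.ix_(de_idx, np.flatnonzero(cell_affected))] += true_log2fc[de_idx, None]

    # latent-factor modules
    module_id = np.array([None] * config.n_genes, dtype=object)
    factors = np.zeros((len(config.modules), n_cells))
    for mi, m in enumerate(config.modules):
        idx = [gene_pos[g] for g in m.genes]
        module_id[idx] = mi
        f = rng.normal(0.0, 1.0, size=n_cells)
        f[treated] += m.treatment_effect
        factors[mi] = f
        log2eff[idx, :] += m.loading * f[None, :]

    # gradient
    lambda_true = np.full(n_cells, np.nan)
    if config.gradient is not None:
        gcells = np.flatnonzero(cell_type == config.gradient.cell_type)
        t = rng.uniform(0.0, 1.0, size=gcells.size)
        lambda_true[gcells] = t
        for g, fn in config.gradient.zone_markers.items():
            log2eff[gene_pos[g], gcells] += np.asarray(fn(t), dtype=float)

    # means and NB draws
    mu = base[:, None] * np.exp2(log2eff)
    mu /= mu.sum(axis=0, keepdims=True)
    lib = rng.lognormal(config.library_meanlog, config.library_sdlog, size=n_cells)
    mu *= lib[None, :]
    n_param = 1.0 / alpha
    p_param = n_param[:, None] / (n_param[:, None] + mu)
    counts = rng.negative_binomial(n_param[:, None], p_param)

    cell_ids = np.array([f"c{i:06d}" for i in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {
            "sample_id": cell_sample,
            "group": cell_group,
            "batch": cell_batch,
            "cell_type": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    gene_meta = pd.DataFrame(
        {
            "symbol": [("mt-" if m else ("Rp-" if r else "")) + g
                       for g, m, r in zip(gene_ids, is_mito, is_ribo)],
            "is_mito": is_mito,
            "is_ribo": is_ribo,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cm = CountMatrix(
        X=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "cell_type": cell_type,
                "sample_id": cell_sample,
                "group": cell_group,
                "batch": cell_batch,
                "lambda_true": lambda_true,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        ),
        genes=pd.DataFrame(
            {
                "is_de": is_de,
                "true_log2fc": true_log2fc,
                "module_id": module_id,
                "marker_of": marker_of,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
    )
    return cm, truth


def simulate_reference(config: SimConfig, seed: int):
    """A labeled dataset from the same generative families, for use as a
    projection reference.  Planted DE and module treatment effects are
    stripped so labels are driven by marker structure alone."""
    if len(config.cell_types) < 2:
        raise ValueError("a projection reference needs >=2 cell types")
    import copy

    ref_cfg = copy.deepcopy(config)
    ref_cfg.de_spec = DESpec(fraction_de=0.0)
    ref_cfg.modules = [ModuleSpec(m.genes, m.loading, 0.0) for m in config.modules]
    cm, truth = simulate_dataset(ref_cfg, seed=seed)
    labels = truth.cells["cell_type"].copy()
    labels.name = "label"
    return cm, labels


def simulate_ranked_pair(n_genes: int, concordance: float, seed: int):
    """Two full rankings of one gene universe with Spearman correlation
    approximately ``concordance`` (exact copies at +/-1)."""
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not -1.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    x = rng.normal(size=n_genes)
    if concordance == 1.0:
        y = x.copy()
    elif concordance == -1.0:
        y = -x
    else:
        # Pearson rho of latent normals giving target Spearman concordance
        rho = 2.0 * np.sin(np.pi * concordance / 6.0)
        y = rho * x + np.sqrt(1.0 - rho ** 2) * rng.normal(size=n_genes)
    rank_a = genes[np.argsort(-x, kind="stable")]
    rank_b = genes[np.argsort(-y, kind="stable")]
    return list(rank_a), list(rank_b)


# ----------------------------------------------------------------------
def default_config(seed: int = 0) -> SimConfig:
    """The default two-arm design: 3 treated + 3 control samples (one batch
    per arm pair), three cell types with 10 markers each, ~3000 UMIs/cell."""
    n_genes = 400
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cell_types = [
        CellTypeSpec("astro", 60, gene_ids[0:10], 2.0),
        CellTypeSpec("tany", 60, gene_ids[10:20], 2.0),
        CellTypeSpec("neuron", 60, gene_ids[20:30], 2.0),
    ]
    samples = [
        SampleSpec("s1", "treated", "b0"),
        SampleSpec("s2", "treated", "b0"),
        SampleSpec("s3", "treated", "b1"),
        SampleSpec("s4", "control", "b0"),
        SampleSpec("s5", "control", "b1"),
        SampleSpec("s6", "control", "b1"),
    ]
    return SimConfig(n_genes=n_genes, cell_types=cell_types, samples=samples, seed=seed)


def write_truth(truth: SimTruth, path) -> None:
    """Serialize SimTruth as two TSVs (cells.tsv, genes.tsv) under ``path``."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.cells.add_prefix("truth_").to_csv(path / "truth_cells.tsv", sep="\t")
    truth.genes.add_prefix("truth_").to_csv(path / "truth_genes.tsv", sep="\t")
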