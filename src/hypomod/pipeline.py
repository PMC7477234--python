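"""Config-driven orchestration of the analysis stages with a manifest.

A pipeline config (YAML) declares an ordered stage list; each stage writes
its TSV outputs under the output directory and appends a manifest entry
(parameters, derived seed, input hashes, output shapes).  One global seed
is fanned out deterministically: stage i uses
``numpy.random.SeedSequence([global_seed, i])``, so re-running a single
stage never depends on random draws made by earlier stages.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import io as io_mod
from . import qc as qc_mod
from . import synthetic, wgcna

log = logging.getLogger("hypomod")

KNOWN_STAGES = ("simulate", "qc", "de", "modules")

_STAGE_DEFAULTS = {
    "simulate": {"n_genes": 400, "n_cells_per_type": 60, "fraction_de": 0.0},
    "qc": {"mode": "sc", "min_genes": 400, "max_genes": 4000, "resolution": 0.1,
           "n_pcs": 30, "k_neighbors": 20, "n_variable_genes": 2000},
    "de": {"lfc": 0.25, "fdr": 0.05},
    "modules": {"deep_split": 2, "min_size": 15, "merge_height": 0.2,
                "n_variable_genes": 5000},
}


@dataclass
class PipelineConfig:
    stages: list               # list of {"name": ..., params...}
    out_dir: Path
    seed: int = 0
    mode: str = "single_cell"
    input_dir: Path | None = None
    source: Path | None = None

    def stage_seed(self, index: int) -> int:
        return int(np.random.SeedSequence([self.seed, index]).generate_state(1)[0] % (2 ** 31))


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; defaults are injected and
    unknown keys rejected with a suggestion."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known_top = {"stages", "out_dir", "seed", "mode", "input_dir"}
    for key in raw:
        if key not in known_top:
            hint = difflib.get_close_matches(key, known_top, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{extra}")
    if "stages" not in raw or not raw["stages"]:
        raise ValueError("config must declare a non-empty stage list")
    if "out_dir" not in raw:
        raise ValueError("config must declare out_dir")
    mode = raw.get("mode", "single_cell")
    if mode not in ("single_cell", "single_nucleus", "bulk"):
        raise ValueError(f"unknown mode {mode!r}")
    stages = []
    for entry in raw["stages"]:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry.get("name")
        if name not in KNOWN_STAGES:
            hint = difflib.get_close_matches(str(name), KNOWN_STAGES, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown stage {name!r}{extra}")
        params = dict(_STAGE_DEFAULTS[name])
        for k, v in entry.items():
            if k == "name":
                continue
            if k not in params:
                hint = difflib.get_close_matches(k, params, n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"stage {name}: unknown parameter {k!r}{extra}")
            params[k] = v
        _check_ranges(name, params)
        stages.append({"name": name, **params})
    input_dir = raw.get("input_dir")
    if input_dir is not None:
        input_dir = Path(input_dir)
        if not input_dir.exists():
            raise ValueError(f"input_dir does not exist: {input_dir}")
    return PipelineConfig(
        stages=stages,
        out_dir=Path(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        mode=mode,
        input_dir=input_dir,
        source=path,
    )


def _check_ranges(name: str, params: dict) -> None:
    positive = {"n_genes", "n_cells_per_type", "min_genes", "max_genes", "n_pcs",
                "k_neighbors", "min_size", "n_variable_genes"}
    for k in positive & set(params):
        if not (isinstance(params[k], int) and params[k] > 0):
            raise ValueError(f"stage {name}: {k} must be a positive integer")
    unit = {"fraction_de", "fdr", "merge_height"}
    for k in unit & set(params):
        if not 0 <= float(params[k]) <= 1:
            raise ValueError(f"stage {name}: {k} must lie in [0, 1]")


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the declared stages in order; returns the manifest dict.

    Any stage failure raises with the stage named; outputs from completed
    stages remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "mode": config.mode, "stages": []}
    state: dict = {}
    for i, stage in enumerate(config.stages):
        name = stage["name"]
        seed = config.stage_seed(i)
        log.info("stage %s (seed %d)", name, seed)
        try:
            entry = _RUNNERS[name](stage, state, out_dir, seed, config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        entry.update({"stage": name, "seed": seed,
                      "params": {k: v for k, v in stage.items() if k != "name"}})
        manifest["stages"].append(entry)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _run_simulate(stage, state, out_dir, seed, config):
    cfg = synthetic.default_config(seed=seed)
    cfg.n_genes = stage["n_genes"]
    for ct in cfg.cell_types:
        ct.n_cells_per_sample = stage["n_cells_per_type"]
    cfg.de_spec = synthetic.DESpec(fraction_de=stage["fraction_de"])
    cm, truth = synthetic.simulate_dataset(cfg, seed=seed)
    state["counts"], state["truth"] = cm, truth
    sim_dir = out_dir / "simulated"
    io_mod.write_counts_10x(cm, sim_dir)
    synthetic.write_truth(truth, sim_dir)
    return {"n_genes": cm.n_genes, "n_cells": cm.n_cells,
            "outputs": {"matrix": _hash_file(sim_dir / "matrix.mtx")}}


def _run_qc(stage, state, out_dir, seed, config):
    if "counts" not in state:
        if config.input_dir is None:
            raise ValueError("qc stage needs a simulate stage or input_dir")
        state["counts"] = io_mod.read_counts_10x(config.input_dir)
    cm = state["counts"]
    thresholds = qc_mod.QCThresholds.for_mode(
        "sn" if config.mode == "single_nucleus" else "sc",
        min_genes=stage["min_genes"], max_genes=stage["max_genes"],
    )
    report = qc_mod.qc_report(cm, thresholds)
    io_mod.write_results(report, out_dir / "qc_report.tsv")
    filtered = qc_mod.filter_cells_genes(cm, thresholds)
    log.info("QC kept %d/%d cells, %d/%d genes", filtered.n_cells, cm.n_cells,
             filtered.n_genes, cm.n_genes)
    norm = qc_mod.normalize_log(filtered)
    var_genes = qc_mod.select_variable_genes(
        norm, filtered.gene_ids, n_top=min(stage["n_variable_genes"], filtered.n_genes)
    )
    gidx = filtered.gene_index(var_genes)
    totals = np.asarray(filtered.X.sum(axis=0)).ravel()
    mr = np.asarray(
        filtered.X[(filtered.gene_meta["is_mito"] | filtered.gene_meta["is_ribo"]).to_numpy()]
        .sum(axis=0)
    ).ravel() / totals
    covs = pd.DataFrame({"total_umis": totals, "mito_ribo_fraction": mr})
    scaled = qc_mod.regress_and_scale(norm[gidx], covs)
    emb = qc_mod.run_pca(scaled, cell_ids=filtered.cell_ids,
                         gene_ids=np.asarray(var_genes),
                         n_pcs=min(stage["n_pcs"], len(var_genes), filtered.n_cells))
    labels = qc_mod.cluster_cells(emb, k_neighbors=min(stage["k_neighbors"],
                                                       filtered.n_cells - 1),
                                  resolution=stage["resolution"], seed=seed)
    state.update(filtered=filtered, norm=norm, embedding=emb, clusters=labels)
    io_mod.write_results(labels.as_series().to_frame(), out_dir / "clusters.tsv")
    return {"n_cells": filtered.n_cells, "n_genes": filtered.n_genes,
            "n_clusters": int(labels.labels.max()) + 1,
            "outputs": {"clusters": _hash_file(out_dir / "clusters.tsv")}}


def _run_de(stage, state, out_dir, seed, config):
    cm = state.get("filtered", state.get("counts"))
    if cm is None:
        raise ValueError("de stage needs counts (run simulate/qc first)")
    pb = de_mod.aggregate_pseudobulk(
        cm, np.ones(cm.n_cells, dtype=bool), cm.cell_meta["sample_id"]
    )
    res = de_mod.nb_wald_test(pb)
    res = de_mod.classify_degs(res, lfc=stage["lfc"], fdr=stage["fdr"])
    io_mod.write_results(res.table, out_dir / "pseudobulk_de.tsv")
    state["de"] = res
    n_deg = int(res.table["category"].isin(["up", "down"]).sum())
    return {"n_degs": n_deg,
            "outputs": {"de": _hash_file(out_dir / "pseudobulk_de.tsv")}}


def _run_modules(stage, state, out_dir, seed, config):
    cm = state.get("filtered", state.get("counts"))
    if cm is None:
        raise ValueError("modules stage needs counts")
    norm = state.get("norm")
    if norm is None:
        norm = qc_mod.normalize_log(cm)
    var_genes = qc_mod.select_variable_genes(
        norm, cm.gene_ids, n_top=min(stage["n_variable_genes"], cm.n_genes)
    )
    gidx = cm.gene_index(var_genes)
    expr = norm[gidx].T  # cells x genes
    report = wgcna.pick_soft_threshold(expr)
    adj = wgcna.signed_adjacency(expr, report.chosen)
    _, dissim = wgcna.topological_overlap(adj)
    assign = wgcna.cut_modules(dissim, var_genes, deep_split=stage["deep_split"],
                               min_size=stage["min_size"])
    if (assign != wgcna.GREY).any():
        assign, eig, _ = wgcna.merge_modules(expr, assign,
                                             cut_height=stage["merge_height"],
                                             cell_ids=cm.cell_ids)
        kme = wgcna.compute_kme(expr, eig, var_genes)
        trait = wgcna.module_trait_table(
            eig,
            cm.cell_meta["group"].to_numpy(),
            cm.cell_meta["sample_id"].to_numpy(),
            cm.cell_meta["batch"].to_numpy() if "batch" in cm.cell_meta else None,
        )
        io_mod.write_results(eig, out_dir / "eigengenes.tsv")
        io_mod.write_results(kme, out_dir / "kme.tsv")
        io_mod.write_results(trait, out_dir / "module_trait.tsv")
    io_mod.write_results(assign.to_frame(), out_dir / "modules.tsv")
    n_mod = int((pd.unique(assign) != wgcna.GREY).sum())
    return {"power": report.chosen, "n_modules": n_mod,
            "outputs": {"modules": _hash_file(out_dir / "modules.tsv")}}


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "de": _run_de,
    "modules": _run_modules,
}
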