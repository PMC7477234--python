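import numpy as np
import pytest

import hypomod.synthetic as syn


@pytest.fixture(scope="session")
def small_sim():
    """Default two-arm design (3 treated + 3 control samples, three cell
    types) with no planted DE."""
    cfg = syn.default_config(seed=0)
    cm, truth = syn.simulate_dataset(cfg)
    return cfg, cm, truth


def block_expression(seed, n_cells, sizes, n_noise, within=0.8):
    """Cells x genes matrix with planted correlated blocks (shared factor,
    within-block correlation ``within``) plus independent noise genes."""
    rng = np.random.default_rng(seed)
    cols = []
    for s in sizes:
        f = rng.normal(size=n_cells)
        cols.append(
            np.sqrt(within) * f[:, None]
            + np.sqrt(1 - within) * rng.normal(size=(n_cells, s))
        )
    if n_noise:
        cols.append(rng.normal(size=(n_cells, n_noise)))
    return np.concatenate(cols, axis=1)


def modular_expression(seed, n_cells=300, sizes=(60, 50, 40, 30, 20),
                       n_noise=200, lo=0.3, hi=0.95):
    """Blocks with heterogeneous per-gene factor loadings, giving a spread
    of intramodular connectivity (closer to real co-expression data)."""
    rng = np.random.default_rng(seed)
    cols = []
    for s in sizes:
        f = rng.normal(size=n_cells)
        lam = rng.uniform(lo, hi, size=s)
        cols.append(
            lam[None, :] * f[:, None]
            + np.sqrt(1 - lam ** 2)[None, :] * rng.normal(size=(n_cells, s))
        )
    if n_noise:
        cols.append(rng.normal(size=(n_cells, n_noise)))
    return np.concatenate(cols, axis=1)


def module_chain_config(seed, loading=1.0, treatment_effect=1.0):
    """Three planted 30-gene co-expression modules in one glial population,
    the first treatment-responsive; 3 samples per arm."""
    n_genes = 300
    gids = [f"g{i:05d}" for i in range(n_genes)]
    return syn.SimConfig(
        n_genes=n_genes,
        cell_types=[syn.CellTypeSpec("glia", 80)],
        samples=[
            syn.SampleSpec(f"s{i}", "treated" if i < 3 else "control", "b0")
            for i in range(6)
        ],
        modules=[
            syn.ModuleSpec(gids[30:60], loading=loading,
                           treatment_effect=treatment_effect),
            syn.ModuleSpec(gids[60:90], loading=loading, treatment_effect=0.0),
            syn.ModuleSpec(gids[90:120], loading=loading, treatment_effect=0.0),
        ],
        seed=seed,
    )
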