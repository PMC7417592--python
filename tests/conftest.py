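import numpy as np
import pandas as pd
import pytest

import ascpath as ap


@pytest.fixture(scope="session")
def small_config():
    return ap.SimulationConfig(n_cells=300, n_genes=400, n_spikes=10, seed=1)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    adata, spikes = ap.simulate_experiment(small_config)
    return adata, spikes


@pytest.fixture(scope="session")
def small_panel(small_config, small_experiment):
    adata, _ = small_experiment
    return ap.simulate_bulk_reference(small_config, adata)


@pytest.fixture(scope="session")
def default_experiment():
    """Full-size simulation used by trajectory/annotation recovery tests."""
    cfg = ap.SimulationConfig(seed=1)
    adata, spikes = ap.simulate_experiment(cfg)
    return cfg, adata, spikes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_bulk(rng, n_genes=30, groups=("g1", "g2"), reps=3, spikes=0):
    """Random RPM-scale bulk matrix with a group map (test helper)."""
    names = [f"G{i}" for i in range(n_genes)] + [
        f"ERCC-{i:05d}" for i in range(spikes)
    ]
    cols, gmap = [], {}
    for g in groups:
        for r in range(reps):
            cols.append(f"{g}_r{r}")
            gmap[f"{g}_r{r}"] = g
    values = pd.DataFrame(
        rng.exponential(5.0, size=(len(names), len(cols))),
        index=pd.Index(names, name="gene"),
        columns=cols,
    )
    return ap.BulkMatrix(
        values=values, unit="RPM", groups=pd.Series(gmap), cells_per_sample=1000
    )
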