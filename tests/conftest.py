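import numpy as np
import pandas as pd
import pytest

from livpm import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        n_liv_individuals=20,
        n_pm_individuals=20,
        bilateral_fraction=0.5,
        n_genes=300,
        n_proteins=120,
        n_multiplexes=4,
        n_clusters=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.simulate_bundle(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_meta(n_liv, n_pm, seed=0):
    """Metadata table with one sample per individual, no covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_liv):
        rows.append((f"L{i:03d}", f"iL{i:03d}", "LIV"))
    for i in range(n_pm):
        rows.append((f"P{i:03d}", f"iP{i:03d}", "PM"))
    meta = pd.DataFrame(rows, columns=["sample_id", "individual_id", "liv_pm_status"])
    meta["age"] = rng.normal(60, 10, len(meta))
    return meta
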