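import numpy as np
import pandas as pd
import pytest

from igf1score.de import build_signature, wald_de
from igf1score.preprocess import estimate_size_factors, filter_genes
from igf1score.simulate import SimulationConfig, simulate_cohort, simulate_reference


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def reference_sim(default_config):
    """Default simulated stimulation experiment (counts, groups, truth)."""
    return simulate_reference(default_config)


@pytest.fixture(scope="session")
def fitted_signature(reference_sim):
    """Signed gene set learned from the default reference simulation."""
    counts, groups, _ = reference_sim
    filtered = filter_genes(counts)
    s = estimate_size_factors(filtered)
    res = wald_de(filtered, groups, s)
    return build_signature(res)


@pytest.fixture(scope="session")
def cohort_sim(default_config, reference_sim):
    """Default simulated cohort (counts, metadata, truth)."""
    _, _, truth = reference_sim
    return simulate_cohort(default_config, truth)


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """A tiny hand-checkable count matrix, all entries positive."""
    rng = np.random.default_rng(7)
    mat = rng.integers(1, 200, size=(30, 6))
    return pd.DataFrame(
        mat,
        index=pd.Index([f"g{i}" for i in range(30)], name="gene"),
        columns=pd.Index([f"s{j}" for j in range(6)], name="sample"),
    )
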