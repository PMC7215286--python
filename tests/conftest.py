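import numpy as np
import pytest

from tractrisk.model_core import ModelData, ModelSpec
from tractrisk.preprocess import expected_counts, score_covariates
from tractrisk.sampler import run_chain
from tractrisk.synthetic import SimulationConfig, simulate_counts, simulate_geography


@pytest.fixture(scope="session")
def grid3():
    """3x3 unit-square lattice: polygons and queen graph."""
    return simulate_geography(3, 3)


@pytest.fixture(scope="session")
def small_truth():
    """10x10 synthetic dataset, unstructured-effect truth."""
    return simulate_counts(SimulationConfig(rows=10, cols=10, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """A completed short fit of the unstructured variant on the 10x10
    dataset (shared across diagnostics tests)."""
    table = small_truth.table
    deciles = score_covariates(table)
    ec = expected_counts(table.counts, table.households)
    data = ModelData(y=table.counts, E=ec.expected, q=deciles.q,
                     graph=small_truth.graph)
    spec = ModelSpec(variant=1, n_covariates=12, iterations=2500, burn_in=800,
                     seed=7)
    return data, run_chain(data, spec)
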