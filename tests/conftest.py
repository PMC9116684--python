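import numpy as np
import pytest

from xprediction.core_io import (
    DependencyScreenMatrix,
    DrugSensitivityTable,
    GeneExpressionMatrix,
)
from xprediction.feature_builder import FeatureMatrix, SensitivityLabels
from xprediction.network_profiler import NetworkStack
from xprediction.synthetic_data import SimulationConfig, simulate_dataset, simulate_feature_matrix


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(0)
    return GeneExpressionMatrix(rng.standard_normal((4, 6)),
                                ["g1", "g2", "g3", "g4"],
                                [f"s{i}" for i in range(6)])


@pytest.fixture
def small_sens():
    rng = np.random.default_rng(1)
    return DrugSensitivityTable(rng.standard_normal((6, 2)),
                                [f"s{i}" for i in range(6)], ["dA", "dB"])


@pytest.fixture
def small_dep():
    rng = np.random.default_rng(2)
    return DependencyScreenMatrix(rng.standard_normal((4, 6)),
                                  ["g1", "g2", "g3", "g4"],
                                  [f"s{i}" for i in range(6)])


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset with ground truth (n=50, J=6, L=2)."""
    cfg = SimulationConfig(n_samples=50, n_regulators=6, n_targets=2,
                           edge_density=0.25, noise_sd=0.3,
                           coefficient_profile="increasing", seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_features():
    """Balanced features with 2 informative of 8 columns, n=60."""
    return simulate_feature_matrix(60, 8, 2, effect=2.0, seed=3)


def random_stack(rng, n=4, L=3, J=5, density=0.4) -> NetworkStack:
    coef = rng.standard_normal((n, L, J))
    coef[rng.random((n, L, J)) > density] = 0.0
    return NetworkStack(coef,
                        [f"s{i}" for i in range(n)],
                        [f"t{l}" for l in range(L)],
                        [f"r{j}" for j in range(J)])


def labels_for(sample_ids, pattern) -> SensitivityLabels:
    return SensitivityLabels(list(pattern), list(sample_ids), -1.0, 1.0, "dX")


def feature_matrix_from(values, labels) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    cols = [(f"t{i}", f"r{i}") for i in range(values.shape[1])]
    ids = [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values, ids, cols, np.asarray(labels, dtype=int))
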