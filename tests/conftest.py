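import numpy as np
import pytest

from latentdag import synthetic_data as sd
from latentdag.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def chain_truth():
    """Two-gene chain g1 -> g2 with weight 0.8 and unit noise."""
    W = np.array([[0.0, 0.8], [0.0, 0.0]])
    return sd.GroundTruth(weights=W, gene_ids=("g1", "g2"), noise_sd=np.ones(2))


@pytest.fixture(scope="session")
def chain_expression(chain_truth):
    return sd.simulate_expression(chain_truth, n=10000, seed=7)


@pytest.fixture(scope="session")
def er_truth():
    """20-gene, 20-edge random DAG with weights in ±[0.5, 2]."""
    gt = sd.simulate_dag(20, 20, "erdos_renyi", seed=3)
    return sd.assign_weights(gt, (0.5, 2.0), seed=4)


@pytest.fixture(scope="session")
def er_expression(er_truth):
    return sd.simulate_expression(er_truth, n=1000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or tuple(f"g{i}" for i in range(values.shape[1]))
    return ExpressionMatrix(values=values, gene_ids=genes)
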