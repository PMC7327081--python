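import numpy as np
import pytest

from coexstage.io import ExpressionMatrix
from coexstage.simulate import SimulationConfig, simulate_staged_expression


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition synthetic dataset shared across tests."""
    cfg = SimulationConfig(seed=42)
    return cfg, *simulate_staged_expression(cfg)


@pytest.fixture(scope="session")
def tiny_sim():
    """A fast, smaller dataset for pipeline smoke tests."""
    cfg = SimulationConfig(n_genes=80, samples_per_group=24, modules_per_stage=1,
                           module_size=8, seed=7)
    return cfg, *simulate_staged_expression(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_expr(rng):
    """Unstructured expression matrix on log scale."""
    genes = [f"G{i}" for i in range(20)]
    samples = [f"S{j}" for j in range(15)]
    return ExpressionMatrix(genes, samples, 5 + rng.standard_normal((20, 15)))
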