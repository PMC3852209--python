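import numpy as np
import pytest

from bcmnet import BCMParams, WeightedBipartiteGraph


@pytest.fixture
def toy_graph() -> WeightedBipartiteGraph:
    """3x3 graph whose BCM run is verified by a step-by-step manual trace."""
    return WeightedBipartiteGraph.from_edges(
        ["x1", "x2", "x3"],
        ["y1", "y2", "y3"],
        [
            ("x1", "y1", 1.0),
            ("x2", "y1", 0.95),
            ("x1", "y2", 0.9),
            ("x2", "y2", 0.9),
            ("x3", "y3", 0.85),
            ("x1", "y3", 0.1),
            ("x2", "y3", 0.1),
            ("x3", "y1", 0.1),
            ("x3", "y2", 0.1),
        ],
    )


@pytest.fixture
def default_params() -> BCMParams:
    return BCMParams(C=36, tau=2, beta=0.7)


def random_graph(seed: int, n_x: int = 6, n_y: int = 6, p: float = 0.7):
    """Small random graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n_x, n_y)) < p
    w = np.where(mask, rng.uniform(0.1, 1.0, (n_x, n_y)), 0.0)
    return WeightedBipartiteGraph(
        [f"x{i}" for i in range(n_x)], [f"y{j}" for j in range(n_y)], w
    )
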