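import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from conngraph import CohortSpec, WeightedGraph


def random_weighted_graph(
    rng: np.random.Generator,
    n: int,
    p: float = 0.6,
    connected: bool = False,
) -> WeightedGraph:
    """Random undirected graph with uniform weights in (0.2, 1]."""
    for _ in range(200):
        mask = np.triu(rng.random((n, n)) < p, k=1)
        w = np.zeros((n, n))
        w[mask] = rng.uniform(0.2, 1.0, mask.sum())
        w = w + w.T
        g = WeightedGraph(w)
        if not connected:
            return g
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(csr_matrix(w > 0), directed=False)
        if n_comp == 1:
            return g
    raise RuntimeError("failed to sample a connected graph")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160315)


@pytest.fixture
def tiny_spec() -> CohortSpec:
    """Small cohort: full 90-ROI structure but few subjects, short series."""
    return CohortSpec(group_sizes=(3, 3, 3), n_volumes=120, seed=42)
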