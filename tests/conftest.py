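"""Shared fixtures and helpers for the mrgraph test suite."""

import numpy as np
import pytest

from mrgraph.simulate import ACYCLIC_G, CYCLIC_G


@pytest.fixture
def acyclic_graph():
    """Three-trait acyclic design graph: Y3 -> Y1 (0.2), Y3 -> Y2 (0.1)."""
    return ACYCLIC_G.copy()


@pytest.fixture
def cyclic_graph():
    """Three-trait cyclic design graph: Y3 -> Y1 (0.5), Y1 -> Y2 (0.05),
    Y2 -> Y3 (0.5)."""
    return CYCLIC_G.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_admissible_graph(rng, T=4, density=0.4, radius=0.9):
    """Random sparse direct-effect graph rescaled to spectral radius <= radius."""
    G = rng.uniform(-1.0, 1.0, (T, T)) * (rng.random((T, T)) < density)
    np.fill_diagonal(G, 0.0)
    rho = np.max(np.abs(np.linalg.eigvals(G)))
    if rho > 0:
        G *= radius * rng.uniform(0.3, 1.0) / rho
    return G
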