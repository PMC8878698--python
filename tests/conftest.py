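import numpy as np
import pytest

from poretrans import MoveConfig, PoreGeometry, build_pore_region


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def wide_region():
    """A short, wide pore in which almost any small chain is valid."""
    return build_pore_region(PoreGeometry(12, 12, 5))


@pytest.fixture
def small_config():
    return MoveConfig(n_segments=10, max_moves=100_000)


def brute_force_chain_valid(segments, region, delta_min=2, delta_max=4):
    """Independent validity oracle: O(N^2) pairwise scan + per-node status scan."""
    from poretrans import NodeStatus, node_status

    pts = np.asarray(segments, dtype=float)
    n = len(segments)
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(pts[i], pts[j]):
                return False
    for i in range(n - 1):
        d = float(np.hypot(*(pts[i + 1] - pts[i])))
        if not (delta_min - 1e-12 <= d <= delta_max + 1e-12):
            return False
    return all(node_status(tuple(map(int, p)), region) is not NodeStatus.WALL for p in segments)
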