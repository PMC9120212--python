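import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import barcodelim as b

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_community():
    """A gapped 5-species community with no discordance events."""
    return b.simulate_community(b.CommunityConfig(seed=1))


@pytest.fixture(scope="session")
def clean_distances(clean_community):
    return b.distance_matrix(clean_community.alignment)


def random_distance_matrix(seed: int, n: int = 8) -> b.DistanceMatrix:
    """A random symmetric matrix with zero diagonal (not necessarily metric)."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.0, 0.3, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return b.DistanceMatrix([f"s{i}" for i in range(n)], vals)


def brute_force_components(dm: b.DistanceMatrix, threshold: float) -> frozenset:
    """Independent oracle: BFS components of the strict-threshold graph."""
    ids = dm.ids
    unvisited = set(range(len(ids)))
    blocks = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = set(stack)
        while stack:
            i = stack.pop()
            for j in list(unvisited):
                if dm.values[i, j] < threshold:
                    unvisited.discard(j)
                    comp.add(j)
                    stack.append(j)
        blocks.append(frozenset(ids[i] for i in comp))
    return frozenset(blocks)
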