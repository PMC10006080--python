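import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def partition(labels):
    """Cluster assignment -> set of frozensets of member indices."""
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


def brute_force_components(snapshots, threshold=0.5):
    """Independent O(n^2) oracle: threshold graph + networkx components."""
    import networkx as nx

    from mef2dyn.ensemble import contact_similarity

    g = nx.Graph()
    g.add_nodes_from(range(len(snapshots)))
    for i in range(len(snapshots)):
        for j in range(i + 1, len(snapshots)):
            if contact_similarity(snapshots[i], snapshots[j]) > threshold:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
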