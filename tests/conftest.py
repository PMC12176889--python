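"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netflex import FunctionalNetwork, Partition, modularity_q

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_net(n, edges):
    return FunctionalNetwork(n_nodes=n, edges=frozenset(tuple(sorted(e)) for e in edges))


def ring(n):
    return make_net(n, [(i, (i + 1) % n) for i in range(n)])


def path(n):
    return make_net(n, [(i, i + 1) for i in range(n - 1)])


def star(n):
    return make_net(n, [(0, i) for i in range(1, n)])


def clique_edges(nodes):
    nodes = list(nodes)
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]


def two_triangles_bridge():
    return make_net(6, clique_edges(range(3)) + clique_edges(range(3, 6)) + [(2, 3)])


def two_cliques_bridge():
    return make_net(8, clique_edges(range(4)) + clique_edges(range(4, 8)) + [(3, 4)])


def set_partitions(items):
    """All set partitions of `items` (Bell-number enumeration)."""
    items = list(items)
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_best_q(net):
    """Exhaustive maximum-modularity search; the independent optimum oracle."""
    best_q, best_p = -2.0, None
    for parts in set_partitions(range(net.n_nodes)):
        labels = [0] * net.n_nodes
        for mod, part in enumerate(parts, start=1):
            for node in part:
                labels[node] = mod
        p = Partition.from_labels(labels)
        q = modularity_q(net, p)
        if q > best_q + 1e-12:
            best_q, best_p = q, p
    return best_q, best_p


@pytest.fixture(scope="session")
def fixture_battery():
    """Small named graphs for exhaustive-optimum comparisons."""
    return {
        "ring6": ring(6),
        "path7": path(7),
        "star8": star(8),
        "two_triangles_bridge": two_triangles_bridge(),
        "two_4cliques_bridge": two_cliques_bridge(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
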