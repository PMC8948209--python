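"""Shared fixtures: canonical tiny graphs and test-only delay generators."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from epiloc.netmodel import Graph


def graph_from_nx(h: nx.Graph) -> Graph:
    """Wrap a networkx graph whose nodes are already 0..N-1."""
    return Graph(g=h.copy())


@pytest.fixture
def path5() -> Graph:
    """Path 0-1-2-3-4 (A-B-C-D-E)."""
    return graph_from_nx(nx.path_graph(5))


@pytest.fixture
def star5() -> Graph:
    """Star: centre 0 with leaves 1..4."""
    return graph_from_nx(nx.star_graph(4))


@pytest.fixture
def triangle() -> Graph:
    return graph_from_nx(nx.cycle_graph(3))


@pytest.fixture
def cycle4() -> Graph:
    return graph_from_nx(nx.cycle_graph(4))


@pytest.fixture
def k23() -> Graph:
    """Complete bipartite K_{2,3}: side {0,1} vs side {2,3,4}."""
    return graph_from_nx(nx.complete_bipartite_graph(2, 3))


def random_connected(n: int, p: float, seed: int) -> Graph:
    """Small connected Erdos-Renyi sample (retries until connected)."""
    for attempt in range(200):
        h = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if nx.is_connected(h):
            return graph_from_nx(h)
    raise RuntimeError("could not draw a connected graph")


def random_tree(n: int, seed: int) -> Graph:
    return graph_from_nx(nx.random_labeled_tree(n, seed=seed))


def gaussian_tree_times(
    tree: Graph, source: int, mu: float, sigma: float, rng: np.random.Generator
) -> dict[int, float]:
    """Test-only spread generator matching the estimators' own assumptions:
    independent Gaussian per-edge delays on a tree, arrival time = sum of
    delays along the unique source-node path."""
    delay = {
        tuple(sorted(e)): rng.normal(mu, sigma) for e in tree.g.edges()
    }
    times = {source: 0.0}
    for parent, child in nx.bfs_edges(tree.g, source):
        times[child] = times[parent] + delay[tuple(sorted((parent, child)))]
    return times
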