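"""Network construction and preprocessing.

Arenas for the spreading and localisation experiments: synthetic
Barabasi-Albert and Erdos-Renyi graphs, plus a plain edge-list reader for
empirical contact/communication networks. All graphs are undirected and
simple, with nodes reindexed to a dense ``0..N-1`` range; the original
labels are retained in a side map for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx

__all__ = [
    "Graph",
    "GraphStats",
    "generate_ba",
    "generate_er",
    "read_edge_list",
    "write_edge_list",
    "prune_low_degree",
    "graph_stats",
]


@dataclass
class Graph:
    """An undirected simple graph with dense integer node ids.

    Parameters
    ----------
    g
        The underlying :class:`networkx.Graph`; nodes are ``0..N-1``,
        no self-loops, no parallel edges.
    labels
        ``labels[i]`` is the original label of node ``i`` (equal to ``i``
        for generated graphs).
    """

    g: nx.Graph
    labels: list[Hashable] = field(default_factory=list)
    # per-root BFS results, filled lazily by the locate module; safe because
    # a Graph is never mutated after construction
    _bfs_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(range(self.g.number_of_nodes()))

    @property
    def node_count(self) -> int:
        return self.g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.g.number_of_edges()

    @property
    def nodes(self) -> range:
        return range(self.node_count)

    def neighbors(self, v: int) -> list[int]:
        return list(self.g[v])

    def degree(self, v: int) -> int:
        return self.g.degree[v]

    @property
    def adjacency(self) -> dict[int, set[int]]:
        return {v: set(self.g[v]) for v in self.g}


@dataclass(frozen=True)
class GraphStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    connected: bool


def _from_nx(h: nx.Graph) -> Graph:
    """Relabel ``h`` to 0..N-1 (sorted original order) and wrap it."""
    order = sorted(h.nodes())
    mapping = {old: i for i, old in enumerate(order)}
    g = nx.relabel_nodes(h, mapping, copy=True)
    return Graph(g=g, labels=list(order))


def generate_ba(n_nodes: int, mean_degree: int, seed: int) -> Graph:
    """Barabasi-Albert preferential-attachment graph with target mean degree.

    The attachment parameter is ``m = mean_degree / 2`` and growth starts
    from a complete seed graph on ``m + 1`` nodes, so the realised mean
    degree is close to ``mean_degree`` for large graphs. The result is
    always connected.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    if mean_degree <= 0 or mean_degree % 2 != 0:
        raise ValueError("mean_degree must be a positive even integer")
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be smaller than n_nodes")
    m = mean_degree // 2
    h = nx.barabasi_albert_graph(
        n_nodes, m, seed=seed, initial_graph=nx.complete_graph(m + 1)
    )
    return Graph(g=h)


def generate_er(n_nodes: int, mean_degree: float, seed: int) -> Graph:
    """Erdos-Renyi ``G(N, p)`` graph with ``p = mean_degree / (N - 1)``.

    If the sample is disconnected the largest connected component is kept
    and reindexed: the SI process cannot leave the source's component and
    the distance-based scorers need finite distances.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    if not 0 < mean_degree <= n_nodes - 1:
        raise ValueError("mean_degree must lie in (0, n_nodes - 1]")
    p = mean_degree / (n_nodes - 1)
    h = nx.gnp_random_graph(n_nodes, p, seed=seed)
    if not nx.is_connected(h):
        giant = max(nx.connected_components(h), key=len)
        h = h.subgraph(giant).copy()
    return _from_nx(h)


def read_edge_list(path) -> Graph:
    """Read an undirected simple graph from a plain-text edge list.

    One edge per line, two whitespace-separated node labels; lines starting
    with ``#`` or ``%`` are ignored (covers konect-style headers). Duplicate
    and reversed edges are collapsed and self-loops dropped (the node is
    still registered, possibly with degree 0). Labels are mapped to
    ``0..N-1`` in sorted order; the original labels are kept in
    :attr:`Graph.labels`.
    """
    h: nx.Graph = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "%")):
                continue
            n_lines += 1
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: malformed edge on line {lineno}: {line!r} "
                    "(expected two whitespace-separated labels)"
                )
            u, v = parts
            if u == v:
                h.add_node(u)  # self-loop dropped, node retained
            else:
                h.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    return _from_nx(h)


def write_edge_list(g: Graph, path) -> None:
    """Write the graph in the same plain edge-list format, original labels."""
    with open(path, "w") as fh:
        for u, v in sorted(g.g.edges()):
            fh.write(f"{g.labels[u]} {g.labels[v]}\n")


def prune_low_degree(g: Graph, min_degree: int) -> Graph:
    """Iteratively remove nodes of degree below ``min_degree``.

    Removal can lower the degree of the neighbours, so the filter cascades
    until no node falls below the threshold (the standard core-style
    reduction). Nodes are reindexed; the label map follows.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    h = g.g.copy()
    while True:
        low = [v for v, d in h.degree() if d < min_degree]
        if not low:
            break
        h.remove_nodes_from(low)
    if h.number_of_nodes() == 0:
        raise ValueError("graph eliminated by pruning")
    keep = sorted(h.nodes())
    out = _from_nx(h)
    out.labels = [g.labels[v] for v in keep]
    return out


def graph_stats(g: Graph) -> GraphStats:
    """Summary record: N, E, mean degree ``2E/N`` and connectedness."""
    n = g.node_count
    e = g.edge_count
    return GraphStats(
        n_nodes=n,
        n_edges=e,
        mean_degree=2.0 * e / n if n else 0.0,
        connected=n > 0 and nx.is_connected(g.g),
    )
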