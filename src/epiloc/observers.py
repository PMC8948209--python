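"""Observer placement strategies.

A budget of ``K`` nodes is instrumented as observers before the spread
starts; only their infection arrival times are available to the
localisers. Four strategies are provided:

- **BC** — the ``K`` nodes of highest betweenness centrality;
- **HCR** (high coverage rate) — greedy maximisation of the fraction of
  nodes adjacent to at least one observer, escalating to double-, triple-
  coverage once every node is covered;
- **HVO** (high variance observers) — greedy maximisation of the number of
  nodes lying on shortest paths (of length at most ``L``) between observer
  pairs, with the same multiplicity escalation;
- **RND** — uniform random placement (the null model).

All deterministic strategies break ties by ascending node index, so a
placement is reproducible for a fixed preprocessed graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netmodel import Graph

__all__ = [
    "PlacementConfig",
    "place",
    "place_bc",
    "place_hcr",
    "place_hvo",
    "place_rnd",
    "coverage_rate",
]

STRATEGIES = ("BC", "HCR", "HVO", "RND")


@dataclass(frozen=True)
class PlacementConfig:
    """Observer budget and strategy.

    Either ``budget`` (K) or ``density`` (d = K/N, resolved per graph as
    ``K = max(1, round(d*N))``) must be given. ``hvo_max_len`` is the HVO
    path-length cap L (None = unlimited); ``seed`` is used by RND only.
    """

    strategy: str
    budget: int | None = None
    density: float | None = None
    hvo_max_len: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if (self.budget is None) == (self.density is None):
            raise ValueError("exactly one of budget / density must be set")
        if self.density is not None and not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")

    def resolve_budget(self, n_nodes: int) -> int:
        if self.budget is not None:
            k = self.budget
        else:
            k = max(1, round(self.density * n_nodes))
        if not 1 <= k < n_nodes:
            raise ValueError(f"budget {k} out of range for N={n_nodes}")
        return k


def place(g: Graph, cfg: PlacementConfig) -> list[int]:
    """Dispatch to the configured placement strategy."""
    k = cfg.resolve_budget(g.node_count)
    if cfg.strategy == "BC":
        return place_bc(g, k)
    if cfg.strategy == "HCR":
        return place_hcr(g, k)
    if cfg.strategy == "HVO":
        return place_hvo(g, k, max_len=cfg.hvo_max_len)
    return place_rnd(g, k, seed=cfg.seed)


def _check_k(g: Graph, k: int, k_min: int = 1) -> None:
    if not k_min <= k < g.node_count:
        raise ValueError(f"k must lie in [{k_min}, N-1], got {k}")


def place_bc(g: Graph, k: int) -> list[int]:
    """The ``k`` nodes of largest betweenness centrality.

    Betweenness is a per-node sum of shortest-path fractions, so the
    set-level argmax separates into the top-``k`` ranking. Ties broken by
    ascending node index.
    """
    _check_k(g, k)
    bc = nx.betweenness_centrality(g.g, normalized=False)
    order = sorted(g.nodes, key=lambda v: (-bc[v], v))
    return order[:k]


def coverage_rate(g: Graph, observers: list[int]) -> float:
    """Fraction of nodes adjacent to at least one observer.

    Open neighbourhoods: an observer does not cover itself unless it is
    the neighbour of another observer.
    """
    if len(set(observers)) != len(observers):
        raise ValueError("observers must be distinct")
    covered: set[int] = set()
    for o in observers:
        covered.update(g.neighbors(o))
    return len(covered) / g.node_count


def place_hcr(g: Graph, k: int) -> list[int]:
    """Greedy high-coverage-rate placement with multiplicity escalation.

    Each pick maximises the number of newly m-covered nodes (nodes with at
    least ``m`` observer neighbours), starting at m=1; once every node is
    m-covered the objective escalates to m+1. Ties by ascending index.
    """
    _check_k(g, k)
    n = g.node_count
    cover = np.zeros(n, dtype=np.int64)  # observer-neighbour count per node
    chosen: list[int] = []
    in_set = np.zeros(n, dtype=bool)
    tier = 1
    for _ in range(k):
        while np.all(cover >= tier):
            tier += 1
        best, best_gain = -1, -1
        for c in range(n):
            if in_set[c]:
                continue
            gain = sum(1 for w in g.neighbors(c) if cover[w] == tier - 1)
            if gain > best_gain:
                best, best_gain = c, gain
        chosen.append(best)
        in_set[best] = True
        for w in g.neighbors(best):
            cover[w] += 1
    return chosen


def _pair_path_counts(
    dist: np.ndarray, sigma: np.ndarray, u: int, v: int, max_len: int | None
) -> np.ndarray:
    """Per-node count of shortest u-v paths (length <= max_len) through it.

    A node ``w`` lies on a shortest path iff d(u,w)+d(w,v) = d(u,v); the
    number of such paths through ``w`` is sigma(u,w)*sigma(w,v). Endpoints
    themselves lie on every path.
    """
    d_uv = dist[u, v]
    if d_uv < 0 or (max_len is not None and d_uv > max_len):
        return np.zeros(dist.shape[0])
    on = (dist[u] >= 0) & (dist[v] >= 0) & (dist[u] + dist[v] == d_uv)
    return np.where(on, sigma[u] * sigma[v], 0.0)


def _distance_and_count_matrices(g: Graph) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts (float to avoid
    overflow); unreachable pairs get distance -1 and count 0."""
    n = g.node_count
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in g.nodes:
        dist[s, s] = 0
        sigma[s, s] = 1.0
        queue = [s]
        while queue:
            nxt: list[int] = []
            for u in queue:
                for w in g.neighbors(u):
                    if dist[s, w] < 0:
                        dist[s, w] = dist[s, u] + 1
                        nxt.append(w)
                    if dist[s, w] == dist[s, u] + 1:
                        sigma[s, w] += sigma[s, u]
            queue = nxt
    return dist, sigma


def place_hvo(g: Graph, k: int, max_len: int | None = None) -> list[int]:
    """Greedy path-covering placement (high variance observers).

    The objective is the number of m-path-covered nodes: nodes lying on at
    least ``m`` shortest paths of length at most ``L`` between observer
    pairs. The initial pair is chosen exhaustively as the pair covering
    the most nodes; each later addition maximises the current-tier gain,
    escalating the multiplicity m once every node is m-path-covered.
    """
    _check_k(g, k, k_min=2)
    n = g.node_count
    dist, sigma = _distance_and_count_matrices(g)

    best_pair, best_cov = None, -1
    for u in range(n):
        for v in range(u + 1, n):
            cov = int(np.count_nonzero(_pair_path_counts(dist, sigma, u, v, max_len)))
            if cov > best_cov:
                best_pair, best_cov = (u, v), cov
    assert best_pair is not None
    chosen = list(best_pair)
    counts = _pair_path_counts(dist, sigma, best_pair[0], best_pair[1], max_len)

    in_set = np.zeros(n, dtype=bool)
    in_set[chosen] = True
    tier = 1
    for _ in range(k - 2):
        while np.all(counts >= tier):
            tier += 1
        best, best_gain = -1, -1
        best_new = None
        for c in range(n):
            if in_set[c]:
                continue
            new = np.zeros(n)
            for o in chosen:
                new += _pair_path_counts(dist, sigma, c, o, max_len)
            gain = int(np.count_nonzero((counts < tier) & (counts + new >= tier)))
            if gain > best_gain:
                best, best_gain, best_new = c, gain, new
        chosen.append(best)
        in_set[best] = True
        counts += best_new
    return chosen


def place_rnd(g: Graph, k: int, seed: int = 0) -> list[int]:
    """Uniform placement without replacement (the null model)."""
    _check_k(g, k)
    rng = np.random.default_rng(seed)
    return [int(v) for v in rng.choice(g.node_count, size=k, replace=False)]
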