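"""Source localisation from observer arrival times.

Every method scores each candidate node ``s`` with a function ``F(s)``;
the estimated source is the argmax. Five estimators are provided:

- **LPTV** — Gaussian maximum-likelihood on a breadth-first-search tree
  approximation, using delay differences relative to a reference observer
  ``o_0`` (the limited-information variant: only arrival times are used,
  not the direction of arrival).
- **TRBS** — backwards spreading: the candidate minimising the variance of
  ``t_k - mu * d(s, o_k)`` across observers.
- **PC** — Pearson correlation between the hop distances from the
  candidate to the observers and the observed arrival times.
- **GMLA** — a gradient-like LPTV: only the ``K_0`` earliest observers are
  used and candidates are explored by hill-climbing from the first
  observer's neighbourhood, so only a subset of nodes is ever scored.
- **EPL** — an LPTV refinement for loopy graphs: parallel shortest paths
  are treated as correlated Gaussian delays and collapsed through the
  moments of the minimum of two Gaussians; observer-pair covariance is
  weighted by the Jaccard index of their path-ensemble edge sets.

The per-link delay model (mean ``mu``, variance ``sigma2``) defaults to
the geometric moments implied by the SI infection rate beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve as _sym_solve

from .netmodel import Graph
from .sisim import ObserverSet

__all__ = [
    "DelayModel",
    "GMLAConfig",
    "PathEnsemble",
    "MinGaussianMoments",
    "ScoreTable",
    "bfs_distances",
    "bfs_tree",
    "enumerate_shortest_paths",
    "min_gaussian_moments",
    "path_correlation",
    "jaccard_edges",
    "score_lptv",
    "score_trbs",
    "score_pc",
    "score_gmla",
    "score_epl",
    "rank_of",
]

PC_SENTINEL = -2.0  # below any valid correlation; marks degenerate candidates


@dataclass(frozen=True)
class DelayModel:
    """Per-link delay moments plugged into the estimators."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @classmethod
    def from_beta(cls, beta: float) -> "DelayModel":
        """Geometric first-passage moments of an SI link: mean 1/beta,
        variance (1-beta)/beta^2."""
        if not 0 < beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        return cls(mu=1.0 / beta, sigma2=(1.0 - beta) / beta**2)


@dataclass(frozen=True)
class GMLAConfig:
    """Number of earliest observers retained by GMLA."""

    k0: int

    def __post_init__(self) -> None:
        if self.k0 < 2:
            raise ValueError("k0 must be >= 2")

    @classmethod
    def default_for(cls, n_nodes: int) -> "GMLAConfig":
        """ceil(sqrt(N)), bounded below by 5."""
        return cls(k0=max(5, math.isqrt(n_nodes - 1) + 1))


@dataclass
class ScoreTable:
    """Per-candidate scores with ranking semantics.

    ``evaluated_set`` is the set of nodes actually scored (GMLA explores
    only part of the graph); unevaluated nodes receive the pessimistic
    rank ``N``.
    """

    scores: dict[int, float]
    method: str
    n_nodes: int
    flags: dict = field(default_factory=dict)

    @property
    def evaluated_set(self) -> set[int]:
        return set(self.scores)

    @property
    def argmax_set(self) -> set[int]:
        if not self.scores:
            return set()
        best = max(self.scores.values())
        return {v for v, f in self.scores.items() if f == best}

    def to_table(self, **metadata) -> str:
        lines = []
        if metadata:
            lines.append("# " + " ".join(f"{k}={v}" for k, v in metadata.items()))
        lines.append(f"# method={self.method}")
        lines.append("node\tscore\trank")
        for v in sorted(self.scores):
            lines.append(f"{v}\t{self.scores[v]!r}\t{rank_of(self, v)}")
        return "\n".join(lines) + "\n"


def rank_of(st: ScoreTable, node: int) -> int:
    """Pessimistic competition rank of ``node`` in the score table.

    1 + number of strictly better nodes + number of ties (the queried node
    placed last among its ties); a node the method never evaluated gets
    the maximum rank ``N``.
    """
    if node not in st.scores:
        return st.n_nodes
    f = st.scores[node]
    better = sum(1 for v in st.scores.values() if v > f)
    ties = sum(1 for v in st.scores.values() if v == f)
    return better + ties


# ---------------------------------------------------------------------------
# path machinery


def bfs_distances(g: Graph, root: int) -> np.ndarray:
    """Hop distances from ``root`` to every node (-1 if unreachable)."""
    cached = g._bfs_cache.get(("dist", root))
    if cached is not None:
        return cached
    n = g.node_count
    dist = np.full(n, -1, dtype=np.int64)
    dist[root] = 0
    queue = [root]
    while queue:
        nxt: list[int] = []
        for u in queue:
            for w in g.neighbors(u):
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        queue = nxt
    dist.setflags(write=False)
    g._bfs_cache[("dist", root)] = dist
    return dist


def bfs_tree(g: Graph, root: int) -> np.ndarray:
    """Shortest-path spanning tree as a parent array (root's parent = -1).

    Among multiple shortest predecessors the lowest-index one is chosen,
    making the tree deterministic.
    """
    cached = g._bfs_cache.get(("tree", root))
    if cached is not None:
        return cached
    dist = bfs_distances(g, root)
    n = g.node_count
    parent = np.full(n, -1, dtype=np.int64)
    for v in range(n):
        if v == root or dist[v] < 0:
            continue
        parent[v] = min(w for w in g.neighbors(v) if dist[w] == dist[v] - 1)
    parent.setflags(write=False)
    g._bfs_cache[("tree", root)] = parent
    return parent


def _shortest_path_counts(g: Graph, root: int) -> tuple[np.ndarray, list[int]]:
    """BFS distances plus exact shortest-path counts (Python ints)."""
    cached = g._bfs_cache.get(("counts", root))
    if cached is not None:
        return cached
    n = g.node_count
    dist = np.full(n, -1, dtype=np.int64)
    count = [0] * n
    dist[root] = 0
    count[root] = 1
    queue = [root]
    while queue:
        nxt: list[int] = []
        for u in queue:
            for w in g.neighbors(u):
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    count[w] += count[u]
        queue = nxt
    g._bfs_cache[("counts", root)] = (dist, count)
    return dist, count


@dataclass
class PathEnsemble:
    """All shortest paths between two nodes (list possibly capped).

    ``count`` is the exact number of shortest paths; ``paths`` holds at
    most ``cap`` of them in lexicographic node order; ``edge_union`` is
    the exact union of edges over *all* shortest paths (independent of the
    cap, accumulated from the predecessor DAG).
    """

    endpoints: tuple[int, int]
    paths: list[tuple[int, ...]]
    edge_union: frozenset[tuple[int, int]]
    count: int

    @property
    def length(self) -> int:
        return len(self.paths[0]) - 1 if self.paths else 0


def _edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def _k_shortest_paths(
    g: Graph,
    dist_u: np.ndarray,
    dist_v: np.ndarray,
    u: int,
    v: int,
    k: int,
) -> list[tuple[int, ...]]:
    """Up to ``k`` shortest u-v paths in lexicographic node order, given the
    BFS distance arrays from both endpoints."""
    d = int(dist_u[v])
    paths: list[tuple[int, ...]] = []
    stack: list[int] = [u]

    def _dfs(w: int) -> None:
        if len(paths) >= k:
            return
        if w == v:
            paths.append(tuple(stack))
            return
        for x in sorted(g.neighbors(w)):
            if dist_u[x] == dist_u[w] + 1 and dist_u[w] + 1 + dist_v[x] == d:
                stack.append(x)
                _dfs(x)
                stack.pop()

    _dfs(u)
    return paths


def enumerate_shortest_paths(g: Graph, u: int, v: int, cap: int = 64) -> PathEnsemble:
    """Enumerate the shortest u-v paths via the BFS predecessor DAG.

    Enumeration order is lexicographic by node index; the path list is
    truncated at ``cap`` while ``count`` and ``edge_union`` stay exact.
    """
    dist_u, count_u = _shortest_path_counts(g, u)
    if dist_u[v] < 0:
        raise ValueError(f"nodes {u} and {v} are not connected")
    dist_v = bfs_distances(g, v)
    d = int(dist_u[v])

    # an edge (a,b), dist_u[b]=dist_u[a]+1, is on a shortest path iff
    # dist_u[a] + 1 + dist_v[b] == d
    edges: set[tuple[int, int]] = set()
    for a in range(g.node_count):
        if dist_u[a] < 0 or dist_u[a] >= d:
            continue
        for b in g.neighbors(a):
            if dist_u[b] == dist_u[a] + 1 and dist_u[a] + 1 + dist_v[b] == d:
                edges.add(_edge(a, b))

    paths = _k_shortest_paths(g, dist_u, dist_v, u, v, cap)
    return PathEnsemble(
        endpoints=(u, v),
        paths=paths,
        edge_union=frozenset(edges),
        count=int(count_u[v]),
    )


def path_correlation(p1: tuple[int, ...], p2: tuple[int, ...]) -> float:
    """Correlation of two equal-length shortest paths: shared edges / L."""
    if len(p1) != len(p2):
        raise ValueError("paths must have equal length")
    length = len(p1) - 1
    if length == 0:
        return 1.0
    e1 = {_edge(a, b) for a, b in zip(p1, p1[1:])}
    e2 = {_edge(a, b) for a, b in zip(p2, p2[1:])}
    return len(e1 & e2) / length


def jaccard_edges(e1: frozenset | set, e2: frozenset | set) -> float:
    """Jaccard index of two edge sets; both empty -> 0 by convention."""
    union = len(e1 | e2)
    if union == 0:
        return 0.0
    return len(e1 & e2) / union


# ---------------------------------------------------------------------------
# minimum of two correlated Gaussians


@dataclass(frozen=True)
class MinGaussianMoments:
    """First two moments of Y = min(X1, X2) for correlated Gaussians."""

    ey: float
    ey2: float

    @property
    def variance(self) -> float:
        return max(self.ey2 - self.ey**2, 0.0)  # clamp round-off


def min_gaussian_moments(
    mu1: float, mu2: float, s1: float, s2: float, rho: float
) -> MinGaussianMoments:
    """Closed-form moments of the minimum of two correlated Gaussians.

    ``s1``, ``s2`` are standard deviations; ``rho`` their correlation.
    With ``theta = sqrt(s1^2 + s2^2 - 2 rho s1 s2)`` the mean is
    ``mu1 Phi((mu2-mu1)/theta) + mu2 Phi((mu1-mu2)/theta)
    - theta phi((mu2-mu1)/theta)`` and the second moment follows the
    analogous weighted form. ``theta = 0`` degenerates to the pointwise
    minimum of the two (then perfectly coupled) variables.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    theta2 = s1**2 + s2**2 - 2.0 * rho * s1 * s2
    theta = math.sqrt(max(theta2, 0.0))
    if theta == 0.0:
        # X2 - X1 is a deterministic shift mu2 - mu1
        if mu1 <= mu2:
            return MinGaussianMoments(ey=mu1, ey2=s1**2 + mu1**2)
        return MinGaussianMoments(ey=mu2, ey2=s2**2 + mu2**2)
    a = (mu2 - mu1) / theta
    # scalar standard-normal cdf/pdf (erf form); the scorers call this in
    # tight per-candidate loops
    cdf_a = 0.5 * (1.0 + math.erf(a / math.sqrt(2.0)))
    cdf_ma = 1.0 - cdf_a
    pdf_a = math.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    ey = mu1 * cdf_a + mu2 * cdf_ma - theta * pdf_a
    ey2 = (
        (s1**2 + mu1**2) * cdf_a
        + (s2**2 + mu2**2) * cdf_ma
        - (mu1 + mu2) * theta * pdf_a
    )
    return MinGaussianMoments(ey=float(ey), ey2=float(ey2))


# ---------------------------------------------------------------------------
# scorers


def _require_times(obs: ObserverSet) -> np.ndarray:
    if obs.arrival_times is None:
        raise ValueError("observer set has no recorded arrival times")
    return np.asarray(obs.arrival_times, dtype=np.float64)


def _ridge_solve(lam: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric solve with a tiny ridge; never an explicit inverse."""
    eps = 1e-9 * max(float(lam.diagonal().max(initial=0.0)), 1.0)
    a = lam + eps * np.eye(lam.shape[0])
    return _sym_solve(a, rhs, assume_a="sym")


def _observer_distance_matrix(g: Graph, nodes: list[int]) -> np.ndarray:
    return np.vstack([bfs_distances(g, o) for o in nodes]).astype(np.float64)


def _lptv_candidate_score(
    g: Graph,
    nodes: list[int],
    d: np.ndarray,
    ref: int,
    dm: DelayModel,
    s: int,
) -> float:
    """LPTV score of one candidate on the BFS tree rooted at it.

    ``nodes`` are the observers, ``d`` the delay differences relative to
    the reference observer ``nodes[ref]`` (length K-1, reference removed).
    """
    parent = bfs_tree(g, s)

    def root_path_edges(v: int) -> frozenset[tuple[int, int]]:
        out = set()
        while parent[v] >= 0:
            out.add(_edge(v, parent[v]))
            v = int(parent[v])
        return frozenset(out)

    dist = bfs_distances(g, s)
    o0 = nodes[ref]
    others = [o for i, o in enumerate(nodes) if i != ref]
    mu_s = dm.mu * np.array([dist[o] - dist[o0] for o in others], dtype=np.float64)

    e0 = root_path_edges(o0)
    # tree path o_0 -> o_k = symmetric difference of the two root paths
    tree_paths = [e0 ^ root_path_edges(o) for o in others]
    m = len(others)
    lam = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            shared = len(tree_paths[i] & tree_paths[j])
            lam[i, j] = lam[j, i] = dm.sigma2 * shared
    z = _ridge_solve(lam, d - 0.5 * mu_s)
    return float(mu_s @ z)


def _split_reference(obs: ObserverSet) -> tuple[int, np.ndarray]:
    """Reference observer index and the delay-difference vector t_k - t_0
    over the remaining observers (input order preserved)."""
    t = _require_times(obs)
    ref = obs.reference_index
    d = np.array([t[i] - t[ref] for i in range(len(obs)) if i != ref])
    return ref, d


def score_lptv(g: Graph, obs: ObserverSet, dm: DelayModel) -> ScoreTable:
    """Gaussian ML source score on a per-candidate BFS-tree approximation.

    For each candidate ``s`` the deterministic delay vector is
    ``mu * (d(s,o_k) - d(s,o_0))`` and the covariance entry for observers
    ``k, i`` is ``sigma2`` times the number of edges shared by the tree
    paths ``o_0 -> o_k`` and ``o_0 -> o_i``; the score is
    ``mu_s' Lambda^-1 (d - mu_s / 2)``.
    """
    if len(obs) < 2:
        raise ValueError("LPTV needs at least two observers")
    ref, d = _split_reference(obs)
    scores = {
        s: _lptv_candidate_score(g, obs.nodes, d, ref, dm, s) for s in g.nodes
    }
    return ScoreTable(scores=scores, method="LPTV", n_nodes=g.node_count)


def score_trbs(g: Graph, obs: ObserverSet, dm: DelayModel) -> ScoreTable:
    """Backwards-spreading score: minus the variance of the residuals
    ``t_k - mu * d(s, o_k)`` over observers (absolute times, no reference
    observer)."""
    if len(obs) < 2:
        raise ValueError("TRBS needs at least two observers")
    t = _require_times(obs)
    dmat = _observer_distance_matrix(g, obs.nodes)  # K x N
    resid = t[:, None] - dm.mu * dmat
    scores_arr = -np.var(resid, axis=0)
    scores = {s: float(scores_arr[s]) for s in g.nodes}
    return ScoreTable(scores=scores, method="TRBS", n_nodes=g.node_count)


def score_pc(g: Graph, obs: ObserverSet) -> ScoreTable:
    """Pearson correlation between candidate-observer hop distances and the
    observed arrival times.

    Scale-invariance of the correlation makes the per-link mean delay
    irrelevant, so raw hop counts are used. A candidate equidistant from
    all observers carries no information and receives the sentinel score
    -2; if the arrival times themselves have zero variance every candidate
    is undefined and all scores are set to the sentinel (flagged).
    """
    if len(obs) < 2:
        raise ValueError("PC needs at least two observers")
    t = _require_times(obs)
    dmat = _observer_distance_matrix(g, obs.nodes)  # K x N
    ty = t - t.mean()
    sy = float(ty @ ty)
    flags = {}
    if sy == 0.0:
        flags["degenerate_times"] = True
        scores = {s: PC_SENTINEL for s in g.nodes}
        return ScoreTable(scores=scores, method="PC", n_nodes=g.node_count, flags=flags)
    x = dmat - dmat.mean(axis=0)
    sx = np.einsum("ij,ij->j", x, x)
    num = ty @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(sx * sy)
    r = np.clip(r, -1.0, 1.0)  # guard round-off
    r[sx == 0.0] = PC_SENTINEL
    scores = {s: float(r[s]) for s in g.nodes}
    return ScoreTable(scores=scores, method="PC", n_nodes=g.node_count, flags=flags)


def score_gmla(
    g: Graph, obs: ObserverSet, dm: DelayModel, cfg: GMLAConfig | None = None
) -> ScoreTable:
    """Gradient-like LPTV restricted to the K_0 earliest observers.

    Candidates are explored by hill-climbing: starting from the earliest
    observer ("observer one") and its neighbours, the search moves to any
    neighbouring candidate whose score is at least the current maximum,
    and stops when no unvisited neighbour qualifies. Only visited nodes
    appear in the score table; the true source may therefore be missed
    entirely, in which case its rank is N.
    """
    if len(obs) < 2:
        raise ValueError("GMLA needs at least two observers")
    if cfg is None:
        cfg = GMLAConfig.default_for(g.node_count)
    t = _require_times(obs)
    order = sorted(range(len(obs)), key=lambda i: (t[i], obs.nodes[i]))
    keep = sorted(order[: max(2, min(cfg.k0, len(obs)))])
    sub = ObserverSet(
        nodes=[obs.nodes[i] for i in keep], arrival_times=t[keep]
    )
    ref, d = _split_reference(sub)
    o1 = sub.nodes[ref]

    scores: dict[int, float] = {}

    def sc(v: int) -> float:
        if v not in scores:
            scores[v] = _lptv_candidate_score(g, sub.nodes, d, ref, dm, v)
        return scores[v]

    sc(o1)
    for w in g.neighbors(o1):
        sc(w)
    current = max(scores, key=lambda v: (scores[v], -v))
    best = scores[current]
    moved = {o1, current}
    while True:
        neigh = [w for w in sorted(g.neighbors(current))]
        for w in neigh:
            sc(w)
        eligible = [w for w in neigh if w not in moved and scores[w] >= best]
        if not eligible:
            break
        current = max(eligible, key=lambda v: (scores[v], -v))
        best = max(best, scores[current])
        moved.add(current)
    return ScoreTable(scores=scores, method="GMLA", n_nodes=g.node_count)


def _ensemble_moments(
    length: int, n_paths: int, rho2: float | None, dm: DelayModel
) -> tuple[float, float]:
    """Mean and variance of the first arrival over a shortest-path ensemble.

    One path: (L mu, L sigma2). Two paths: min of two Gaussians with the
    measured path correlation. More than two: the two-path approximation
    with rho = 0.
    """
    mean1 = length * dm.mu
    var1 = length * dm.sigma2
    if n_paths <= 1:
        return mean1, var1
    rho = rho2 if (n_paths == 2 and rho2 is not None) else 0.0
    s = math.sqrt(var1)
    mom = min_gaussian_moments(mean1, mean1, s, s, rho)
    return mom.ey, mom.variance


def score_epl(
    g: Graph, obs: ObserverSet, dm: DelayModel, cap: int = 64
) -> ScoreTable:
    """Equiprobable-links score: LPTV generalised to loopy graphs.

    Every candidate-observer connection is the full ensemble of shortest
    paths; its expected arrival delay is the mean of the minimum over the
    (correlated Gaussian) path delays under the two-path approximation.
    The observer covariance is built once per observer set from the
    ensembles to the reference observer: Jaccard index of the edge unions
    times the geometric mean of the min-distribution variances.
    """
    if len(obs) < 2:
        raise ValueError("EPL needs at least two observers")
    ref, d = _split_reference(obs)
    o0 = obs.nodes[ref]
    others = [o for i, o in enumerate(obs.nodes) if i != ref]

    def pair_stats(u: int, v: int) -> tuple[int, int, float | None]:
        """(length, path count, two-path correlation) for a node pair;
        memoised on the graph since paths never change."""
        key = ("epl_pair", _edge(u, v))
        hit = g._bfs_cache.get(key)
        if hit is not None:
            return hit
        dist_u, count_u = _shortest_path_counts(g, u)
        length, n_paths = int(dist_u[v]), count_u[v]
        rho = None
        if n_paths == 2:
            dist_v = bfs_distances(g, v)
            p1, p2 = _k_shortest_paths(g, dist_u, dist_v, u, v, 2)
            rho = path_correlation(p1, p2)
        g._bfs_cache[key] = (length, n_paths, rho)
        return length, n_paths, rho

    # observer-side covariance: ensembles o_0 -> o_i, computed once per
    # observer set (source-independent)
    minvar = []
    unions = []
    for o in others:
        key = ("epl_union", _edge(o0, o))
        union = g._bfs_cache.get(key)
        if union is None:
            union = enumerate_shortest_paths(g, o0, o, cap=1).edge_union
            g._bfs_cache[key] = union
        unions.append(union)
        length, n_paths, rho = pair_stats(o0, o)
        _, var = _ensemble_moments(length, n_paths, rho, dm)
        minvar.append(var)
    m = len(others)
    lam = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            jac = 1.0 if i == j else jaccard_edges(unions[i], unions[j])
            lam[i, j] = lam[j, i] = jac * math.sqrt(minvar[i] * minvar[j])

    obs_nodes = [o0, *others]
    scores: dict[int, float] = {}
    for s in g.nodes:
        means = {}
        for o in obs_nodes:
            length, n_paths, rho = pair_stats(s, o) if s != o else (0, 1, None)
            mean, _ = _ensemble_moments(length, n_paths, rho, dm)
            means[o] = mean
        mu_s = np.array([means[o] - means[o0] for o in others])
        z = _ridge_solve(lam, d - 0.5 * mu_s)
        scores[s] = float(mu_s @ z)
    return ScoreTable(scores=scores, method="EPL", n_nodes=g.node_count)
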