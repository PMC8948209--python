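"""Path machinery, min-of-Gaussians moments and the five source scorers."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import multivariate_normal

from epiloc.locate import (
    DelayModel,
    GMLAConfig,
    PC_SENTINEL,
    bfs_distances,
    bfs_tree,
    enumerate_shortest_paths,
    jaccard_edges,
    min_gaussian_moments,
    path_correlation,
    rank_of,
    score_epl,
    score_gmla,
    score_lptv,
    score_pc,
    score_trbs,
    ScoreTable,
)
from epiloc.sisim import ObserverSet, SpreadConfig, observe, run_si

from conftest import (
    gaussian_tree_times,
    graph_from_nx,
    random_connected,
    random_tree,
)


class TestBFS:
    def test_path_distances(self, path5):
        assert list(bfs_distances(path5, 0))[:3] == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_matches_networkx(self, seed):
        g = random_connected(15, 0.25, seed)
        for root in (0, 7):
            ref = nx.single_source_shortest_path_length(g.g, root)
            d = bfs_distances(g, root)
            assert all(d[v] == ref[v] for v in g.nodes)
        assert bfs_distances(g, 3)[9] == bfs_distances(g, 9)[3]

    def test_tree_input_reproduced(self):
        t = random_tree(10, seed=2)
        parent = bfs_tree(t, 0)
        tree_edges = {frozenset((v, int(parent[v]))) for v in t.nodes if parent[v] >= 0}
        assert tree_edges == {frozenset(e) for e in t.g.edges()}

    def test_cycle_lowest_index_parent(self, cycle4):
        parent = bfs_tree(cycle4, 0)
        assert parent[2] == 1  # antipodal node: neighbours 1 and 3, pick 1

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_paths_are_shortest(self, seed):
        g = random_connected(15, 0.25, seed)
        root = 2
        parent = bfs_tree(g, root)
        dist = bfs_distances(g, root)
        for v in g.nodes:
            hops, u = 0, v
            while parent[u] >= 0:
                u = int(parent[u])
                hops += 1
            assert hops == dist[v]


class TestEnumerateShortestPaths:
    def test_path_graph_single(self, path5):
        pe = enumerate_shortest_paths(path5, 0, 4)
        assert pe.count == 1 and pe.paths == [(0, 1, 2, 3, 4)]

    def test_cycle_antipodal_two(self, cycle4):
        pe = enumerate_shortest_paths(cycle4, 0, 2)
        assert pe.count == 2
        assert pe.paths == [(0, 1, 2), (0, 3, 2)]

    def test_k23_three_paths(self, k23):
        pe = enumerate_shortest_paths(k23, 0, 1)
        assert pe.count == 3 and pe.length == 2

    def test_cap_truncates_list_not_count(self, k23):
        pe = enumerate_shortest_paths(k23, 0, 1, cap=2)
        assert len(pe.paths) == 2 and pe.count == 3
        # edge union stays exact regardless of the cap
        assert len(pe.edge_union) == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dfs_oracle(self, seed):
        g = random_connected(12, 0.3, seed)
        for u, v in [(0, 5), (1, 9)]:
            oracle = [tuple(p) for p in nx.all_shortest_paths(g.g, u, v)]
            pe = enumerate_shortest_paths(g, u, v, cap=1000)
            assert pe.count == len(oracle)
            assert sorted(pe.paths) == sorted(oracle)
            union = {frozenset(e) for p in oracle for e in zip(p, p[1:])}
            assert {frozenset(e) for e in pe.edge_union} == union


class TestMinGaussianMoments:
    def test_standard_symmetric_case(self):
        """E[min of two iid N(0,1)] = -theta*phi(0) with theta=sqrt(2)."""
        m = min_gaussian_moments(0, 0, 1, 1, 0)
        assert m.ey == pytest.approx(-0.5641895835, abs=1e-9)

    def test_perfectly_coupled_degenerate(self):
        m = min_gaussian_moments(3.0, 3.0, 2.0, 2.0, 1.0)
        assert m.ey == 3.0 and m.variance == pytest.approx(4.0)

    def test_separation_limit(self):
        m = min_gaussian_moments(-5, 5, 1, 1, 0)
        assert m.ey == pytest.approx(-5, abs=1e-4)
        assert m.variance == pytest.approx(1.0, abs=1e-3)

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            min_gaussian_moments(0, 0, 1, 1, 1.5)

    @pytest.mark.parametrize(
        "mu2,s2,rho",
        list(itertools.product([0.0, 1.0, 3.0], [0.5, 1.0, 2.0], [-0.5, 0.0, 0.7])),
    )
    def test_monte_carlo_oracle(self, mu2, s2, rho):
        """Closed form vs 10^6-sample simulation; the grid makes 54
        simultaneous comparisons so the z bound carries a Bonferroni
        adjustment (family confidence of a single 3-sigma check)."""
        z_star = 4.03
        mu1, s1 = 0.0, 1.0
        rng = np.random.default_rng(hash((mu2, s2, rho)) % 2**31)
        cov = [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
        x = rng.multivariate_normal([mu1, mu2], cov, size=1_000_000)
        y = x.min(axis=1)
        m = min_gaussian_moments(mu1, mu2, s1, s2, rho)
        n = len(y)
        assert abs(m.ey - y.mean()) < z_star * y.std() / np.sqrt(n)
        y2 = y**2
        assert abs(m.ey2 - y2.mean()) < z_star * y2.std() / np.sqrt(n)


class TestPathOverlap:
    def test_identical(self):
        assert path_correlation((0, 1, 2), (0, 1, 2)) == 1.0

    def test_disjoint(self, cycle4):
        assert path_correlation((0, 1, 2), (0, 3, 2)) == 0.0

    def test_partial(self):
        assert path_correlation((0, 1, 2, 3), (0, 1, 4, 3)) == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            path_correlation((0, 1), (0, 1, 2))

    def test_jaccard(self):
        ab, bc, cd = frozenset({(0, 1)}), frozenset({(1, 2)}), frozenset({(2, 3)})
        assert jaccard_edges(ab | bc, bc | cd) == pytest.approx(1 / 3)
        assert jaccard_edges(ab, ab) == 1.0
        assert jaccard_edges(ab, cd) == 0.0
        assert jaccard_edges(frozenset(), frozenset()) == 0.0


def _full_obs(g, realisation):
    return observe(realisation, list(g.nodes))


class TestLPTV:
    def test_star_centre_recovered(self, star5):
        r = run_si(star5, SpreadConfig(beta=1.0, seed=0), source=0)
        obs = observe(r, [1, 2, 3, 4])
        st = score_lptv(star5, obs, DelayModel.from_beta(1.0))
        assert 0 in st.argmax_set

    def test_path_midpoint_recovered(self, path5):
        r = run_si(path5, SpreadConfig(beta=1.0, seed=0), source=2)
        obs = observe(r, [0, 4])
        st = score_lptv(path5, obs, DelayModel.from_beta(1.0))
        assert st.argmax_set == {2}

    def test_single_observer_rejected(self, path5):
        r = run_si(path5, SpreadConfig(beta=1.0, seed=0), source=2)
        with pytest.raises(ValueError):
            score_lptv(path5, observe(r, [0]), DelayModel.from_beta(1.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_ml_oracle_on_trees(self, seed):
        """With Gaussian per-edge delays on a tree the LPTV score is the
        exact log-likelihood up to a candidate-independent constant, so its
        argmax must equal the exhaustive ML argmax."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        t = random_tree(n, seed=seed)
        src = int(rng.integers(n))
        mu, sig = 1.0, 0.1
        times = gaussian_tree_times(t, src, mu, sig, rng)
        observers = sorted(rng.choice(n, size=max(2, n // 2), replace=False).tolist())
        obs = ObserverSet(
            nodes=observers,
            arrival_times=np.array([times[o] for o in observers]),
        )
        st = score_lptv(t, obs, DelayModel(mu=mu, sigma2=sig**2))

        ref = obs.reference_index
        o0 = observers[ref]
        others = [o for i, o in enumerate(observers) if i != ref]
        d = np.array([times[o] - times[o0] for o in others])
        paths = []
        for o in others:
            p = nx.shortest_path(t.g, o0, o)
            paths.append({frozenset(e) for e in zip(p, p[1:])})
        lam = np.array([[sig**2 * len(pi & pj) for pj in paths] for pi in paths])
        lls = {}
        for s in t.nodes:
            ds = nx.single_source_shortest_path_length(t.g, s)
            mus = mu * np.array([ds[o] - ds[o0] for o in others])
            lls[s] = multivariate_normal.logpdf(d, mean=mus, cov=lam,
                                                allow_singular=True)
        oracle = max(lls, key=lls.get)
        assert oracle in st.argmax_set


class TestTRBS:
    def test_deterministic_front_score_zero(self):
        g = random_connected(15, 0.25, seed=1)
        r = run_si(g, SpreadConfig(beta=1.0, seed=0), source=3)
        st = score_trbs(g, _full_obs(g, r), DelayModel.from_beta(1.0))
        assert st.scores[3] == 0.0
        assert 3 in st.argmax_set
        assert all(v <= 0 for v in st.scores.values())

    def test_hand_computed_path(self, path5):
        # observers A=0 (t=2) and C=2 (t=0): candidate 2 has residuals
        # (2-2, 0-0) -> var 0; candidates 0,1 are strictly worse
        obs = ObserverSet(nodes=[0, 2], arrival_times=np.array([2, 0]))
        st = score_trbs(path5, obs, DelayModel(mu=1.0, sigma2=0.0))
        assert st.scores[2] == 0.0
        assert 2 in st.argmax_set
        assert st.scores[1] == pytest.approx(-1.0)

    def test_shift_invariance(self):
        g = random_connected(15, 0.25, seed=2)
        r = run_si(g, SpreadConfig(beta=0.5, seed=5), source=0)
        obs = observe(r, [1, 4, 9])
        dm = DelayModel.from_beta(0.5)
        st = score_trbs(g, obs, dm)
        shifted = ObserverSet(nodes=obs.nodes, arrival_times=obs.arrival_times + 7)
        st2 = score_trbs(g, shifted, dm)
        for v in g.nodes:
            assert st.scores[v] == pytest.approx(st2.scores[v])


class TestPC:
    def test_perfect_proportionality(self, path5):
        # candidate 0 sees observers at distances (1,2,3) with times (2,4,6)
        obs = ObserverSet(nodes=[1, 2, 3], arrival_times=np.array([2, 4, 6]))
        st = score_pc(path5, obs)
        assert st.scores[0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, path5):
        obs = ObserverSet(nodes=[1, 2, 3], arrival_times=np.array([3, 2, 1]))
        st = score_pc(path5, obs)
        assert st.scores[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds(self, seed):
        g = random_connected(20, 0.2, seed)
        r = run_si(g, SpreadConfig(beta=0.4, seed=seed), source=0)
        st = score_pc(g, observe(r, [1, 5, 9, 12]))
        for v in g.nodes:
            assert -1.0 <= st.scores[v] <= 1.0 or st.scores[v] == PC_SENTINEL

    def test_degenerate_times_flagged(self, star5):
        obs = ObserverSet(nodes=[1, 2, 3], arrival_times=np.array([1, 1, 1]))
        st = score_pc(star5, obs)
        assert st.flags.get("degenerate_times")
        assert all(v == PC_SENTINEL for v in st.scores.values())


class TestGMLA:
    def test_scores_equal_lptv_on_restricted_set(self):
        g = random_connected(25, 0.15, seed=4)
        r = run_si(g, SpreadConfig(beta=0.5, seed=8), source=2)
        obs = observe(r, [0, 3, 6, 9, 12, 15, 18])
        dm = DelayModel.from_beta(0.5)
        cfg = GMLAConfig(k0=4)
        st = score_gmla(g, obs, dm, cfg)
        # restrict to the 4 earliest observers exactly as GMLA does
        t = obs.arrival_times
        keep = sorted(sorted(range(len(obs)), key=lambda i: (t[i], obs.nodes[i]))[:4])
        sub = ObserverSet(nodes=[obs.nodes[i] for i in keep], arrival_times=t[keep])
        full = score_lptv(g, sub, dm)
        for v, f in st.scores.items():
            assert f == pytest.approx(full.scores[v], rel=1e-9)

    def test_star_hand_trace(self, star5):
        r = run_si(star5, SpreadConfig(beta=1.0, seed=0), source=0)
        obs = observe(r, [1, 2, 3])
        st = score_gmla(star5, obs, DelayModel.from_beta(1.0), GMLAConfig(k0=3))
        # observer one is a leaf (time 1); the centre is its only neighbour,
        # scores maximal, and the climb stops there
        assert 0 in st.argmax_set
        assert {0, 1} <= st.evaluated_set

    def test_unevaluated_nodes_rank_n(self):
        g = random_connected(30, 0.12, seed=6)
        r = run_si(g, SpreadConfig(beta=0.8, seed=3), source=0)
        obs = observe(r, [5, 10, 15, 20])
        st = score_gmla(g, obs, DelayModel.from_beta(0.8), GMLAConfig(k0=3))
        unevaluated = set(g.nodes) - st.evaluated_set
        assert unevaluated, "hill climb should not visit the whole graph here"
        for v in unevaluated:
            assert rank_of(st, v) == g.node_count


class TestEPL:
    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_to_lptv_on_trees(self, seed):
        """Single-path limit: every ensemble has n=1, and the argmax must
        agree with LPTV under Gaussian test delays."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 16))
        t = random_tree(n, seed=300 + seed)
        src = int(rng.integers(n))
        times = gaussian_tree_times(t, src, 1.0, 0.1, rng)
        observers = sorted(rng.choice(n, size=max(2, n // 2), replace=False).tolist())
        obs = ObserverSet(
            nodes=observers,
            arrival_times=np.array([times[o] for o in observers]),
        )
        dm = DelayModel(mu=1.0, sigma2=0.01)
        assert score_epl(t, obs, dm).argmax_set == score_lptv(t, obs, dm).argmax_set

    def test_parallel_paths_shorten_expected_arrival(self, cycle4):
        """Two disjoint length-2 paths: the expected first arrival is
        E[min of two N(2mu, 2sigma^2)] < 2mu."""
        dm = DelayModel(mu=2.0, sigma2=1.0)
        m = min_gaussian_moments(4.0, 4.0, np.sqrt(2), np.sqrt(2), 0.0)
        assert m.ey < 4.0
        # and the EPL scorer indeed uses that mean: true source at 0,
        # observers at 1 (adjacent) and 2 (antipodal, two parallel paths)
        obs = ObserverSet(nodes=[1, 2], arrival_times=np.array([2.0, m.ey]))
        st = score_epl(cycle4, obs, dm)
        assert 0 in st.argmax_set

    def test_covariance_diagonal_is_min_variance(self, cycle4):
        """Lambda_ii = min-distribution variance of the ensemble (Jaccard
        of a set with itself is 1); exercised via the moments helper."""
        dm = DelayModel(mu=1.0, sigma2=0.5)
        m = min_gaussian_moments(2.0, 2.0, 1.0, 1.0, 0.0)
        assert m.variance > 0
        # score must be finite and defined for all candidates
        obs = ObserverSet(nodes=[0, 2], arrival_times=np.array([0, 2]))
        st = score_epl(cycle4, obs, dm)
        assert all(np.isfinite(list(st.scores.values())))


class TestRanking:
    def test_unique_max(self):
        st = ScoreTable(scores={0: 3.0, 1: 1.0, 2: 2.0}, method="x", n_nodes=3)
        assert rank_of(st, 0) == 1
        assert st.argmax_set == {0}

    def test_pessimistic_ties(self):
        st = ScoreTable(scores={0: 3.0, 1: 3.0, 2: 2.0}, method="x", n_nodes=3)
        assert rank_of(st, 0) == 2 and rank_of(st, 1) == 2

    def test_missing_node_gets_n(self):
        st = ScoreTable(scores={0: 3.0}, method="x", n_nodes=10)
        assert rank_of(st, 7) == 10


@pytest.mark.parametrize("seed", range(5))
def test_observer_order_invariance(seed):
    """Permuting the observer input order leaves the argmax set unchanged
    for every scorer (the reference observer is chosen by time, not order)."""
    rng = np.random.default_rng(seed)
    g = random_connected(20, 0.2, seed)
    r = run_si(g, SpreadConfig(beta=0.5, seed=seed), source=1)
    nodes = [0, 4, 8, 12, 16]
    obs = observe(r, nodes)
    perm = list(rng.permutation(len(nodes)))
    obs_p = ObserverSet(
        nodes=[nodes[i] for i in perm], arrival_times=obs.arrival_times[perm]
    )
    dm = DelayModel.from_beta(0.5)
    for fn in (
        lambda o: score_lptv(g, o, dm),
        lambda o: score_trbs(g, o, dm),
        lambda o: score_pc(g, o),
        lambda o: score_epl(g, o, dm),
    ):
        assert fn(obs).argmax_set == fn(obs_p).argmax_set
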