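import itertools

import networkx as nx
import numpy as np
import pytest

from ecmap.centrality import (ConvergenceError, ReducibleMatrixError,
                              betweenness_centrality, degree_centrality,
                              eigenvector_centrality, factored_matvec,
                              power_iteration)
from ecmap.similarity import SimilarityMatrix, correlation_similarity

from conftest import make_series


def dense(a, tag=""):
    a = np.asarray(a, float)
    return SimilarityMatrix(n=a.shape[0], form="dense", dense_values=a,
                            metric_tag=tag)


def dominant_eigenvector_oracle(a):
    """Full dense eigendecomposition; sign fixed positive."""
    w, v = np.linalg.eigh(np.asarray(a, float))
    vec = v[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return vec, w[-1]


def random_similarity(n, seed):
    g = np.random.default_rng(seed)
    u = g.uniform(0, 1, (n, n))
    return (u + u.T) / 2


def betweenness_oracle(adj):
    """Exhaustive shortest-path enumeration over all simple paths (n<=8).

    ``adj[i][j]`` is the edge length (np.inf if absent).
    """
    n = adj.shape[0]
    nodes = range(n)
    cb = np.zeros(n)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        inner = [v for v in nodes if v not in (s, t)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (s,) + mid + (t,)
                length = sum(adj[a][b] for a, b in zip(path, path[1:]))
                if np.isfinite(length):
                    paths.append((length, path))
        if not paths:
            continue  # disconnected pair contributes nothing
        best = min(p[0] for p in paths)
        shortest = [p[1] for p in paths if p[0] == best]
        for v in inner:
            through = sum(1 for p in shortest if v in p)
            cb[v] += through / len(shortest)
    return cb / ((n - 1) * (n - 2) / 2)


class TestDegreeCentrality:
    def test_all_ones(self):
        cm = degree_centrality(dense(np.ones((4, 4))))
        np.testing.assert_allclose(cm.values, 3.0)

    def test_direct_sums(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.5
        np.testing.assert_allclose(degree_centrality(dense(a)).values,
                                   [1.0, 0.5, 0.5])

    def test_linearity(self, rng):
        a = random_similarity(10, 3)
        base = degree_centrality(dense(a)).values
        a2 = a.copy()
        off = ~np.eye(10, dtype=bool)
        a2[off] *= 2
        np.testing.assert_allclose(degree_centrality(dense(a2)).values,
                                   2 * base)

    def test_factored_matches_dense(self):
        series = make_series(n_voxels=25, n_timepoints=40)
        d = correlation_similarity(series, form="dense")
        f = correlation_similarity(series, form="factored")
        np.testing.assert_allclose(degree_centrality(f).values,
                                   degree_centrality(d).values, atol=1e-10)


class TestPowerIteration:
    def test_dominant_axis(self):
        a = np.diag([2.0, 1.0])
        v, lam, _ = power_iteration(lambda x: a @ x, 2, tol=1e-12)
        np.testing.assert_allclose(v, [1, 0], atol=1e-9)
        assert lam == pytest.approx(2.0)

    def test_rank_one_two_iterations(self):
        a = np.ones((5, 5))
        v, lam, iters = power_iteration(lambda x: a @ x, 5)
        np.testing.assert_allclose(v, 1 / np.sqrt(5))
        assert lam == pytest.approx(5.0)
        assert iters <= 2

    def test_matches_dense_eigensolver(self):
        a = random_similarity(200, 7)
        v, lam, _ = power_iteration(lambda x: a @ x, 200, tol=1e-11)
        ov, ol = dominant_eigenvector_oracle(a)
        assert np.abs(v - ov).max() < 1e-8
        assert lam == pytest.approx(ol, rel=1e-10)

    def test_nonconvergence_error_carries_residual(self):
        # nearly-degenerate spectrum converges far too slowly for max_iter
        a = np.diag([1.0, 1.0 - 1e-9])
        with pytest.raises(ConvergenceError) as exc:
            power_iteration(lambda x: a @ x, 2, tol=1e-15, max_iter=5)
        assert exc.value.residual > 0
        assert exc.value.iterations == 5


class TestEigenvectorCentrality:
    @pytest.mark.parametrize("a_off", [0.1, 0.5, 1.0])
    def test_two_node_symmetry(self, a_off):
        a = np.array([[1.0, a_off], [a_off, 1.0]])
        cm = eigenvector_centrality(dense(a))
        np.testing.assert_allclose(cm.values, 1 / np.sqrt(2), atol=1e-9)
        assert cm.eigenvalue == pytest.approx(1 + a_off)

    def test_star_node_has_largest_centrality(self):
        a = np.full((5, 5), 0.1)
        np.fill_diagonal(a, 1.0)
        a[0, 1:] = a[1:, 0] = 0.9
        cm = eigenvector_centrality(dense(a))
        assert cm.values[0] > cm.values[1:].max()
        ov, _ = dominant_eigenvector_oracle(a)
        np.testing.assert_allclose(cm.values, ov, atol=1e-8)

    def test_scaling_invariance(self):
        a = random_similarity(30, 11)
        c1 = eigenvector_centrality(dense(a)).values
        c2 = eigenvector_centrality(dense(2.0 * a)).values
        np.testing.assert_array_equal(c1, c2)

    def test_diagonal_shift_invariance(self):
        a = random_similarity(40, 5)
        c1 = eigenvector_centrality(dense(a), tol=1e-12).values
        c2 = eigenvector_centrality(dense(a + 3.0 * np.eye(40)),
                                    tol=1e-12).values
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_perron_positivity(self):
        for seed in range(5):
            a = random_similarity(25, seed) + 0.01
            np.fill_diagonal(a, 1.0)
            cm = eigenvector_centrality(dense(a))
            assert (cm.values > 0).all()

    def test_permutation_equivariance(self, rng):
        a = random_similarity(12, 21)
        perm = rng.permutation(12)
        c = eigenvector_centrality(dense(a), tol=1e-12).values
        cp = eigenvector_centrality(dense(a[np.ix_(perm, perm)]),
                                    tol=1e-12).values
        np.testing.assert_allclose(cp, c[perm], atol=1e-9)

    def test_reducible_matrix_rejected(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.5  # nodes 2,3 isolated
        with pytest.raises(ReducibleMatrixError, match="mask"):
            eigenvector_centrality(dense(a))

    def test_unit_norm_and_provenance(self):
        series = make_series(n_voxels=20)
        cm = eigenvector_centrality(correlation_similarity(series))
        assert np.linalg.norm(cm.values) == pytest.approx(1.0)
        assert cm.method == "eigenvector"
        assert cm.metric_tag == "scaled-corr"
        assert cm.iterations >= 1 and cm.eigenvalue > 0

    def test_residual_satisfies_eigen_equation(self):
        a = random_similarity(60, 2)
        cm = eigenvector_centrality(dense(a), tol=1e-11)
        resid = np.abs(a @ cm.values - cm.eigenvalue * cm.values).max()
        assert resid < 1e-9 * cm.eigenvalue

    def test_factored_and_dense_paths_agree(self):
        series = make_series(n_voxels=80, n_timepoints=60)
        cd = eigenvector_centrality(correlation_similarity(series,
                                                           form="dense"))
        cf = eigenvector_centrality(correlation_similarity(series,
                                                           form="factored"))
        assert np.abs(cd.values - cf.values).max() < 1e-8


class TestFactoredMatvec:
    def test_zero_vector(self, rng):
        z = rng.standard_normal((10, 4))
        np.testing.assert_array_equal(factored_matvec(z, np.zeros(10)),
                                      np.zeros(10))

    def test_agreement_with_dense_product(self, rng):
        z = rng.standard_normal((50, 20))
        a = (z @ z.T + 1.0) / 2.0
        x = rng.standard_normal(50)
        assert np.abs(factored_matvec(z, x) - a @ x).max() < 1e-12

    def test_indicator_recovers_column(self, rng):
        z = rng.standard_normal((8, 3))
        a = (z @ z.T + 1.0) / 2.0
        for i in range(8):
            e = np.zeros(8)
            e[i] = 1.0
            np.testing.assert_allclose(factored_matvec(z, e), a[:, i],
                                       atol=1e-13)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            factored_matvec(rng.standard_normal((5, 2)), np.ones(6))


class TestBetweenness:
    def _graph_matrix(self, edges, n, weight=0.5):
        a = np.eye(n)
        for i, j in edges:
            a[i, j] = a[j, i] = weight
        return a

    def test_path_graph(self):
        a = self._graph_matrix([(0, 1), (1, 2)], 3)
        cm = betweenness_centrality(dense(a), edge_threshold=0.1)
        np.testing.assert_allclose(cm.values, [0, 1, 0])

    def test_star_graph(self):
        a = self._graph_matrix([(0, i) for i in range(1, 5)], 5)
        cm = betweenness_centrality(dense(a), edge_threshold=0.1)
        np.testing.assert_allclose(cm.values, [1, 0, 0, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("weighting", ["distance", "unweighted"])
    def test_random_graph_matches_bruteforce(self, seed, weighting):
        g = np.random.default_rng(seed)
        n = 8
        a = np.eye(n)
        # dyadic weights -> exact shortest-path length comparisons
        choices = np.array([0.0, 0.25, 0.5, 0.75])
        for i in range(n):
            for j in range(i + 1, n):
                a[i, j] = a[j, i] = g.choice(choices)
        thr = 0.1
        cm = betweenness_centrality(dense(a), edge_threshold=thr,
                                    weighting=weighting)
        adj = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(n):
                if i != j and a[i, j] > thr:
                    adj[i, j] = (1.0 - a[i, j] if weighting == "distance"
                                 else 1.0)
        np.testing.assert_allclose(cm.values, betweenness_oracle(adj),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_networkx(self, seed):
        g = np.random.default_rng(seed + 50)
        n = 12
        u = g.uniform(0, 1, (n, n))
        a = (u + u.T) / 2
        np.fill_diagonal(a, 1.0)
        thr = 0.5
        cm = betweenness_centrality(dense(a), edge_threshold=thr,
                                    weighting="distance")
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if a[i, j] > thr:
                    graph.add_edge(i, j, length=1.0 - a[i, j])
        expected = nx.betweenness_centrality(graph, weight="length",
                                             normalized=True)
        np.testing.assert_allclose(cm.values,
                                   [expected[i] for i in range(n)],
                                   atol=1e-10)

    def test_values_in_unit_interval(self):
        a = random_similarity(15, 9)
        np.fill_diagonal(a, 1.0)
        cm = betweenness_centrality(dense(a), edge_threshold=0.5)
        assert cm.values.min() >= 0 and cm.values.max() <= 1

    def test_node_limit_refusal(self):
        a = random_similarity(12, 0)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="force"):
            betweenness_centrality(dense(a), node_limit=10)
        cm = betweenness_centrality(dense(a), node_limit=10, force=True)
        assert cm.values.shape == (12,)

    def test_permutation_equivariance(self, rng):
        a = random_similarity(9, 33)
        np.fill_diagonal(a, 1.0)
        perm = rng.permutation(9)
        c = betweenness_centrality(dense(a), edge_threshold=0.6).values
        cp = betweenness_centrality(dense(a[np.ix_(perm, perm)]),
                                    edge_threshold=0.6).values
        np.testing.assert_allclose(cp, c[perm], atol=1e-12)
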