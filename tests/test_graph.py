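import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sfngrn.graph import (
    CellGraph,
    SFNGraph,
    alternative_graph,
    compute_factor_embedding,
    fuse_graphs,
    manhattan_distance,
    read_graph,
    sfn_graph,
    shared_factor_neighborhood,
    similarity_from_distance,
    spatial_adjacency,
    threshold_adjacency,
    write_graph,
)
from sfngrn.io import SpatialCoordinates


def brute_force_sfn(values, variance_target=0.90, k=10, threshold=0.5,
                    normalize_by_k=True):
    """Straight-line reference: materialises every pairwise distance and
    recomputes the whole pipeline with plain loops and a dense eigensolve."""
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / (len(values) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    frac = evals / evals.sum()
    cum = np.cumsum(frac)
    n_factors = int(np.flatnonzero(cum >= variance_target - 1e-9)[0]) + 1
    rank = int(np.sum(evals > 1e-12 * evals[0]))
    n_factors = max(1, min(n_factors, rank))
    H = np.zeros((len(values), n_factors))
    for j in range(n_factors):
        v = evecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        H[:, j] = centered @ v
    n = len(H)
    dominant = np.array([int(np.argmax(H[i])) for i in range(n)])
    fn = np.zeros((n, n_factors))
    for i in range(n):
        dists = [(np.linalg.norm(H[i] - H[j]), j) for j in range(n) if j != i]
        dists.sort()
        for _, j in dists[:k]:
            fn[i, dominant[j]] += 1
    fnp = fn / k if normalize_by_k else fn
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = np.sum(np.abs(fnp[i] - fnp[j]))
            if 1.0 / (1.0 + e) > threshold:
                A[i, j] = 1
    return H, fn, A


class TestFactorEmbedding:
    def test_rank_one_data_gives_single_factor(self):
        t = np.linspace(0, 1, 8)[:, None]
        values = t @ np.array([[1.0, 2.0, -0.5]]) + 3.0
        emb = compute_factor_embedding(values, variance_target=0.90)
        assert emb.n_factors == 1

    def test_variance_target_one_gives_rank(self, rng):
        low_rank = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 6))
        emb = compute_factor_embedding(low_rank, variance_target=1.0)
        assert emb.n_factors == 2

    def test_explained_fractions_match_dense_eigensolve(self, rng):
        values = rng.uniform(0, 5, size=(20, 5))
        emb = compute_factor_embedding(values, variance_target=0.99)
        centered = values - values.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(centered.T @ centered / 19))[::-1]
        np.testing.assert_allclose(
            emb.explained_fraction, (evals / evals.sum())[: emb.n_factors], atol=1e-10
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_factor_embedding(np.ones((5, 3)))

    def test_sign_convention_deterministic(self, rng):
        values = rng.uniform(0, 5, size=(15, 4))
        a = compute_factor_embedding(values)
        b = compute_factor_embedding(values)
        np.testing.assert_array_equal(a.H, b.H)


class TestSharedFactorNeighborhood:
    def test_identical_cells_single_dominant_bin(self):
        h = np.tile([2.0, 1.0], (6, 1))
        nb = shared_factor_neighborhood(h, k=3)
        np.testing.assert_array_equal(nb.fn[:, 0], np.full(6, 3))
        np.testing.assert_array_equal(nb.fn[:, 1], np.zeros(6))

    def test_hand_worked_five_cell_instance(self):
        h = np.array([[2, 0], [1.5, 0.1], [0, 3], [0.2, 2], [1, 1.1]], dtype=float)
        nb = shared_factor_neighborhood(h, k=2)
        np.testing.assert_array_equal(nb.dominant, [0, 0, 1, 1, 1])
        # exhaustive pairwise distances confirm these neighbour sets
        expected_neighbors = {0: {1, 4}, 1: {0, 4}, 2: {3, 4}, 3: {2, 4}, 4: {1, 3}}
        for i, nbrs in expected_neighbors.items():
            assert set(nb.neighbors[i]) == nbrs
        expected_fn = np.array([[1, 1], [1, 1], [0, 2], [0, 2], [1, 1]])
        np.testing.assert_array_equal(nb.fn, expected_fn)

    def test_fn_rows_sum_to_k(self, rng):
        h = rng.normal(size=(30, 4))
        nb = shared_factor_neighborhood(h, k=7)
        np.testing.assert_array_equal(nb.fn.sum(axis=1), np.full(30, 7))

    def test_self_never_a_neighbor(self, rng):
        h = rng.normal(size=(12, 3))
        h[5] = h[2]  # duplicate rows: self-exclusion must still hold
        nb = shared_factor_neighborhood(h, k=4)
        for i in range(12):
            assert i not in nb.neighbors[i]

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than"):
            shared_factor_neighborhood(rng.normal(size=(5, 2)), k=5)

    def test_permutation_equivariance(self, rng):
        h = rng.normal(size=(15, 3))  # distinct distances almost surely
        perm = rng.permutation(15)
        nb = shared_factor_neighborhood(h, k=4)
        nb_p = shared_factor_neighborhood(h[perm], k=4)
        np.testing.assert_array_equal(nb_p.fn, nb.fn[perm])


class TestDistanceAndSimilarity:
    def test_identical_rows_zero_distance(self):
        fn = np.array([[5, 5], [5, 5]])
        np.testing.assert_array_equal(manhattan_distance(fn, k=10), np.zeros((2, 2)))

    @pytest.mark.parametrize(
        "rows,expected",
        [
            (np.array([[10, 0], [0, 10]]), 2.0),
            (np.array([[7, 3], [5, 5]]), 0.4),
        ],
    )
    def test_normalized_manhattan_values(self, rows, expected):
        E = manhattan_distance(rows, k=10, normalize_by_k=True)
        assert E[0, 1] == pytest.approx(expected)

    def test_raw_counts_when_not_normalized(self):
        E = manhattan_distance(np.array([[7, 3], [5, 5]]), normalize_by_k=False)
        assert E[0, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("e,s", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_similarity_closed_forms(self, e, s):
        assert similarity_from_distance(np.array([[e]]))[0, 0] == pytest.approx(s)

    def test_threshold_is_strict(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        g = threshold_adjacency(S, threshold=0.5)
        assert g.n_edges == 0  # similarity exactly at the threshold: no edge

    def test_edge_iff_distance_below_one(self, rng):
        # algebra on the similarity transform: 1/(1+E) > 0.5  <=>  E < 1
        E = np.abs(rng.normal(0, 1, size=(8, 8)))
        E = (E + E.T) / 2
        np.fill_diagonal(E, 0)
        g = threshold_adjacency(similarity_from_distance(E), threshold=0.5)
        expected = (E < 1).astype(int)
        np.fill_diagonal(expected, 0)
        np.testing.assert_array_equal(g.a, expected)


class TestSpatialAdjacency:
    def test_coincident_cells_get_edge(self):
        coords = SpatialCoordinates(
            ["a", "b", "c"], np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        )
        g = spatial_adjacency(coords)
        assert g.a[0, 1] == 1

    def test_unscaled_distance_three_no_edge(self):
        g = spatial_adjacency(np.array([[0.0, 0.0], [3.0, 0.0]]), scale="none")
        assert g.n_edges == 0  # similarity 0.25 below threshold

    def test_grid_matches_brute_force(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(2.0))
        xy = np.column_stack([xs.ravel(), ys.ravel()])
        g = spatial_adjacency(xy, scale="median_knn")
        dist = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        nn = np.min(dist + np.diag(np.full(10, np.inf)), axis=1)
        scaled = dist / np.median(nn)
        expected = (1.0 / (1.0 + scaled) > 0.5).astype(int)
        np.fill_diagonal(expected, 0)
        np.testing.assert_array_equal(g.a, expected)


class TestFuseGraphs:
    def _graph(self, a):
        return CellGraph(np.array(a, dtype=int), source="expression")

    def test_or_truth_table(self):
        a = self._graph([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        b = self._graph([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        fused = fuse_graphs(a, b)
        np.testing.assert_array_equal(
            fused.a, [[0, 1, 1], [1, 0, 0], [1, 0, 0]]
        )
        assert fused.source == "fused"

    def test_idempotent_commutative_associative(self, rng):
        def random_graph():
            m = rng.integers(0, 2, size=(6, 6))
            m = np.triu(m, 1)
            return self._graph(m + m.T)

        a, b, c = random_graph(), random_graph(), random_graph()
        np.testing.assert_array_equal(fuse_graphs(a, a).a, a.a)
        np.testing.assert_array_equal(fuse_graphs(a, b).a, fuse_graphs(b, a).a)
        np.testing.assert_array_equal(
            fuse_graphs(fuse_graphs(a, b), c).a, fuse_graphs(a, fuse_graphs(b, c)).a
        )

    def test_monotone_edge_count(self, rng):
        m = rng.integers(0, 2, size=(8, 8))
        m = np.triu(m, 1)
        a, b = self._graph(m + m.T), self._graph(np.zeros((8, 8), int))
        fused = fuse_graphs(a, b)
        assert fused.n_edges >= max(a.n_edges, b.n_edges)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fuse"):
            fuse_graphs(self._graph(np.zeros((3, 3), int)),
                        self._graph(np.zeros((4, 4), int)))


class TestAlternativeStrategies:
    def test_identical_cells_pcc_edge(self, rng):
        values = rng.uniform(0, 4, size=(6, 5))
        values[3] = values[0]
        g = alternative_graph(values, "pcc")
        assert g.a[0, 3] == 1

    def test_manhattan_matches_brute_force(self, rng):
        values = rng.uniform(0, 4, size=(6, 4))
        g = alternative_graph(values, "manhattan", threshold=0.5)
        emb = compute_factor_embedding(values)
        E = np.abs(emb.H[:, None] - emb.H[None]).sum(-1)
        expected = (1.0 / (1.0 + E) > 0.5).astype(int)
        np.fill_diagonal(expected, 0)
        np.testing.assert_array_equal(g.a, expected)

    def test_unknown_strategy_rejected(self, rng):
        with pytest.raises(ValueError, match="strategy"):
            alternative_graph(rng.uniform(0, 1, (5, 3)), "chebyshev")


class TestSFNOracle:
    def test_pipeline_matches_brute_force_on_random_instances(self):
        """Full SFN pipeline vs an independent loop-based reimplementation."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n = int(rng.integers(8, 26))
            g = int(rng.integers(3, 7))
            k = int(rng.integers(2, min(6, n - 1) + 1))
            values = rng.uniform(0, 6, size=(n, g))
            graph, emb, nb = sfn_graph(values, k=k, threshold=0.5)
            H_ref, fn_ref, A_ref = brute_force_sfn(values, k=k)
            np.testing.assert_allclose(emb.H, H_ref, atol=1e-8,
                                       err_msg=f"trial {trial}")
            np.testing.assert_array_equal(nb.fn, fn_ref, err_msg=f"trial {trial}")
            np.testing.assert_array_equal(graph.a, A_ref, err_msg=f"trial {trial}")

    def test_graph_pipeline_permutation_equivariance(self, rng):
        values = rng.uniform(0, 6, size=(18, 5))
        perm = rng.permutation(18)
        g1, _, _ = sfn_graph(values, k=4)
        g2, _, _ = sfn_graph(values[perm], k=4)
        np.testing.assert_array_equal(g2.a, g1.a[np.ix_(perm, perm)])


class TestAlgebraicProperties:
    @given(
        arrays(
            float, st.tuples(st.integers(2, 8), st.integers(2, 8)),
            elements=st.floats(0, 50, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_similarity_bounded_and_antitone(self, E):
        """S = 1/(1+E) maps non-negative distances into (0, 1], decreasing."""
        S = similarity_from_distance(E)
        assert np.all((S > 0) & (S <= 1))
        assert np.all(S[E == 0] == 1)  # tiny E may round to S == 1 too
        shifted = similarity_from_distance(E + 1.0)
        assert np.all(shifted < S + 1e-15)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fusion_never_removes_edges(self, seed):
        rng = np.random.default_rng(seed)
        def g():
            m = np.triu(rng.integers(0, 2, size=(6, 6)), 1)
            return CellGraph(m + m.T, source="expression")
        a, b = g(), g()
        fused = fuse_graphs(a, b)
        assert np.all(fused.a >= a.a)
        assert np.all(fused.a >= b.a)
        np.testing.assert_array_equal(fused.a, np.maximum(a.a, b.a))


class TestEstimatorAndSerialization:
    def test_estimator_params_round_trip(self):
        est = SFNGraph(k=5, threshold=0.4)
        assert SFNGraph(**est.get_params()).get_params() == est.get_params()

    def test_fit_exposes_graph(self, tiny_bundle):
        X, _, _ = tiny_bundle
        est = SFNGraph(k=5).fit(X)
        assert est.graph_.n_cells == X.n_cells
        assert est.neighborhood_.fn.sum() == X.n_cells * 5

    def test_graph_mtx_round_trip(self, tmp_path, rng):
        m = rng.integers(0, 2, size=(7, 7))
        m = np.triu(m, 1)
        g = CellGraph(m + m.T, source="fused")
        write_graph(g, tmp_path / "g.mtx", params={"k": 10})
        back = read_graph(tmp_path / "g.mtx")
        np.testing.assert_array_equal(back.a, g.a)
        assert back.source == "fused"
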