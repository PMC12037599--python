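import numpy as np
import pytest

import oracles
from conftest import complete_graph, path_graph, random_graph, ring_lattice, star_graph
from covnet.exceptions import ValidationError
from covnet.metrics import (
    NullEnsemble,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    degree,
    global_efficiency,
    global_metric_values,
    local_clustering,
    local_efficiency,
    metrics_over_sparsities,
    modularity,
    nodal_efficiency,
    normalized_global_metrics,
    rewire_preserving_degree,
)
from covnet.networks import correlation_matrix, sparsity_grid
from covnet.simulate import SyntheticSpec, generate_cohort


def two_triangles():
    A = np.zeros((6, 6), dtype=bool)
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = True
    return A


class TestClosedFormCases:
    def test_complete_graph_k4(self):
        A = complete_graph(4)
        assert np.all(degree(A) == 3)
        assert clustering_coefficient(A) == pytest.approx(1.0)
        assert characteristic_path_length(A) == pytest.approx(1.0)
        assert global_efficiency(A) == pytest.approx(1.0)
        assert local_efficiency(A) == pytest.approx(1.0)
        assert np.allclose(nodal_efficiency(A), 1.0)

    def test_star_graph(self):
        A = star_graph(4)
        assert degree(A)[0] == 4 and np.all(degree(A)[1:] == 1)
        assert clustering_coefficient(A) == 0.0
        assert local_efficiency(A) == 0.0
        # every pair of leaves routes through the hub: C(4,2) = 6
        bc = betweenness(A)
        assert bc[0] == pytest.approx(6.0)
        assert np.allclose(bc[1:], 0.0)

    def test_path_graph_abc(self):
        A = path_graph(3)
        assert characteristic_path_length(A) == pytest.approx(4 / 3)
        assert global_efficiency(A) == pytest.approx(5 / 6)
        assert nodal_efficiency(A)[0] == pytest.approx(0.75)
        assert betweenness(A)[0] == 0.0 and betweenness(A)[2] == 0.0

    def test_triangle_clustering_is_one(self):
        A = complete_graph(3)
        assert clustering_coefficient(A) == pytest.approx(1.0)

    def test_two_disconnected_dyads_efficiency(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = True
        assert global_efficiency(A) == pytest.approx(1 / 3)

    def test_handshake_lemma_on_random_graphs(self):
        for seed in range(5):
            A = random_graph(9, 0.4, seed)
            assert degree(A).sum() == A.sum()

    def test_two_triangles_modularity_half(self):
        A = two_triangles()
        q = modularity(A, seed=1)
        assert q >= 0.5 - 1e-9
        assert q == pytest.approx(
            oracles.modularity_value(A, [[0, 1, 2], [3, 4, 5]]), abs=1e-9
        )

    def test_complete_graph_modularity_near_zero(self):
        assert abs(modularity(complete_graph(8), seed=2)) < 0.05

    def test_edgeless_graph_modularity_rejected(self):
        with pytest.raises(ValidationError):
            modularity(np.zeros((4, 4), dtype=bool))

    def test_fully_isolated_graph_has_no_path_length(self):
        with pytest.raises(ValidationError):
            characteristic_path_length(np.zeros((4, 4), dtype=bool))


class TestOracleBattery:
    """Every metric equals its brute-force oracle on 200 seeded random graphs."""

    @pytest.mark.parametrize("seed", range(200))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        p = float(rng.uniform(0.15, 0.8))
        A = random_graph(n, p, seed + 1000)
        assert np.array_equal(degree(A), A.sum(axis=1))
        assert np.allclose(local_clustering(A), oracles.clustering_oracle(A))
        assert global_efficiency(A) == pytest.approx(
            oracles.global_efficiency_oracle(A), abs=1e-12)
        assert np.allclose(nodal_efficiency(A), oracles.nodal_efficiency_oracle(A))
        assert local_efficiency(A) == pytest.approx(
            oracles.local_efficiency_oracle(A), abs=1e-12)
        assert np.allclose(betweenness(A), oracles.betweenness_oracle(A), atol=1e-9)
        if A.any():
            finite = np.isfinite(oracles.floyd_warshall(A)).sum() > n
            if finite:
                assert characteristic_path_length(A) == pytest.approx(
                    oracles.path_length_oracle(A), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_modularity_matches_exhaustive_partition_search(self, seed):
        A = random_graph(7, 0.45, seed + 3000)
        if not A.any():
            return
        q = modularity(A, seed=seed, n_restarts=10)
        assert q == pytest.approx(oracles.modularity_oracle(A), abs=1e-6)

    def test_two_cliques_with_bridge_matches_exhaustive_search(self):
        A = np.zeros((8, 8), dtype=bool)
        A[:4, :4] = complete_graph(4)
        A[4:, 4:] = complete_graph(4)
        A[3, 4] = A[4, 3] = True
        q = modularity(A, seed=0)
        assert q == pytest.approx(oracles.modularity_oracle(A), abs=1e-6)


class TestNodeRelabelingInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        A = random_graph(8, 0.5, seed + 500)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(8)
        B = A[np.ix_(perm, perm)]
        assert clustering_coefficient(A) == pytest.approx(clustering_coefficient(B))
        assert global_efficiency(A) == pytest.approx(global_efficiency(B))
        assert local_efficiency(A) == pytest.approx(local_efficiency(B))
        assert np.allclose(nodal_efficiency(A)[perm], nodal_efficiency(B))
        assert np.allclose(betweenness(A)[perm], betweenness(B), atol=1e-9)


class TestRewiring:
    def test_triangle_is_rigid(self):
        A = complete_graph(3)
        assert np.array_equal(rewire_preserving_degree(A, seed=4), A)

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_and_edge_count_preserved(self, seed):
        A = random_graph(15, 0.3, seed + 50)
        R = rewire_preserving_degree(A, seed=seed)
        assert np.array_equal(degree(R), degree(A))
        assert R.sum() == A.sum()
        assert not np.diag(R).any()

    def test_same_seed_reproduces_identical_graph(self):
        A = random_graph(15, 0.3, 7)
        r1 = rewire_preserving_degree(A, seed=123)
        r2 = rewire_preserving_degree(A, seed=123)
        assert np.array_equal(r1, r2)

    def test_rewiring_actually_changes_large_graphs(self):
        A = random_graph(30, 0.2, 9)
        R = rewire_preserving_degree(A, seed=5)
        assert not np.array_equal(R, A)


class TestNormalizedMetrics:
    def test_self_ensemble_normalizes_to_one(self):
        A = random_graph(12, 0.4, 2)
        gm = normalized_global_metrics(A, null_graphs=[A])
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lam == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)

    def test_sigma_equals_gamma_over_lambda(self):
        A = random_graph(20, 0.3, 3)
        gm = normalized_global_metrics(A, NullEnsemble(n_random=20, seed=1))
        assert gm.sigma == pytest.approx(gm.gamma / gm.lam, rel=1e-12)

    def test_dense_random_graph_is_not_small_world(self):
        A = random_graph(68, 0.3, 12)
        gm = normalized_global_metrics(A, NullEnsemble(n_random=100, seed=8))
        assert 0.8 <= gm.sigma <= 1.2

    def test_rewired_ring_lattice_is_small_world(self):
        A = ring_lattice(68, 8).copy()
        rng = np.random.default_rng(4)
        # rewire ~5% of edges to random targets (Watts-Strogatz construction)
        edges = np.array(np.nonzero(np.triu(A, 1))).T
        for i, j in edges[rng.random(len(edges)) < 0.05]:
            A[i, j] = A[j, i] = False
            while True:
                a, b = rng.integers(0, 68, 2)
                if a != b and not A[a, b]:
                    A[a, b] = A[b, a] = True
                    break
        gm = normalized_global_metrics(A, NullEnsemble(n_random=100, seed=9))
        assert gm.sigma > 1.0


class TestMetricCurves:
    def test_eglob_curve_monotone_under_nested_edges(self, regions6):
        cohort = generate_cohort(
            SyntheticSpec(n_per_group=(10, 9), regions=regions6, n_blocks=2, seed=6))
        net = correlation_matrix(cohort, "A")
        grid = sparsity_grid(0.2, 0.9, 0.1)
        vals = global_metric_values(net.matrix, grid, metrics=("Eglob",))["Eglob"]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_curves_match_per_sparsity_recomputation(self, regions6):
        from covnet.networks import binarize_at_sparsity

        cohort = generate_cohort(
            SyntheticSpec(n_per_group=(10, 9), regions=regions6, n_blocks=2, seed=6))
        net = correlation_matrix(cohort, "A")
        grid = np.array([0.3, 0.5, 0.7])
        curves, nodal = metrics_over_sparsities(
            net, grid, global_metrics=("Cp", "Eglob", "Eloc"),
            nodal_metrics=("degree",))
        for i, s in enumerate(grid):
            A = binarize_at_sparsity(net, float(s)).adjacency
            assert curves["Cp"].values[i] == pytest.approx(clustering_coefficient(A))
            assert curves["Eglob"].values[i] == pytest.approx(global_efficiency(A))
            assert curves["Eloc"].values[i] == pytest.approx(local_efficiency(A))
            assert np.array_equal(nodal["degree"].iloc[i].to_numpy(),
                                  degree(A).astype(float))

    def test_constant_curve_auc_is_rectangle(self):
        from covnet.inference import auc

        grid = sparsity_grid()
        assert auc(np.ones_like(grid), grid) == pytest.approx(0.30)
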