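import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmagc.evaluation import adjusted_rand_index
from mmagc.modified_wgcna import (
    ConnectivityProfile,
    adjacency,
    cluster,
    connectivity_profile,
    mean_connectivity,
    scale_free_fit,
    select_power_inflection,
    select_power_traditional,
    tom,
)


def random_similarity(n, rng):
    A = rng.uniform(0, 1, size=(n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return A


def uniform_similarity(n, r):
    M = np.full((n, n), float(r))
    np.fill_diagonal(M, 1.0)
    return M


class TestAdjacency:
    def test_power_one_is_identity_map(self, rng):
        C = random_similarity(6, rng)
        np.testing.assert_array_equal(adjacency(C, 1), C)

    def test_elementwise_power(self):
        C = uniform_similarity(4, 0.5)
        np.testing.assert_allclose(adjacency(C, 3)[0, 1], 0.125)

    def test_raising_power_never_increases_entries(self, rng):
        C = random_similarity(8, rng)
        prev = adjacency(C, 1)
        for m in range(2, 8):
            cur = adjacency(C, m)
            assert np.all(cur <= prev + 1e-15)
            prev = cur

    def test_invalid_power_rejected(self, rng):
        with pytest.raises(ValueError):
            adjacency(random_similarity(3, rng), 0)


class TestMeanConnectivity:
    def test_uniform_network(self):
        assert mean_connectivity(uniform_similarity(7, 0.4)) == \
            pytest.approx(6 * 0.4)

    def test_empty_network(self):
        assert mean_connectivity(np.eye(5)) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        A = random_similarity(6, rng)
        expected = np.mean([
            sum(A[i, j] for j in range(6) if j != i) for i in range(6)
        ])
        assert mean_connectivity(A) == pytest.approx(expected, abs=1e-12)


def scale_free_fit_oracle(adj, n_bins=10):
    """Independently coded binning + least squares (normal equations)."""
    k = adj.sum(axis=1) - np.diag(adj)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    xs, ys = [], []
    for i in range(n_bins):
        hi_inclusive = i == n_bins - 1
        mask = (k >= edges[i]) & ((k <= edges[i + 1]) if hi_inclusive
                                  else (k < edges[i + 1]))
        if mask.sum() and k[mask].mean() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum()))
    x, y = np.array(xs), np.array(ys)
    n = len(x)
    b = np.linalg.solve(
        np.array([[n, x.sum()], [x.sum(), (x * x).sum()]]),
        np.array([y.sum(), (x * y).sum()]),
    )
    resid = y - (b[0] + b[1] * x)
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    return 1 - (1 - r2) * (n - 1) / (n - 2)


class TestScaleFreeFit:
    def test_matches_independent_regression_oracle(self, rng):
        A = random_similarity(20, rng) * 0.6
        np.fill_diagonal(A, 1.0)
        assert scale_free_fit(A) == pytest.approx(scale_free_fit_oracle(A),
                                                  abs=1e-10)

    def test_constant_connectivity_not_assessable(self):
        assert np.isnan(scale_free_fit(uniform_similarity(25, 0.3)))

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            scale_free_fit(random_similarity(5, rng), n_bins=10)


class TestPowerSelection:
    def test_traditional_choice_is_smallest_qualifying_power(self, rng):
        # self-consistency against the stated criterion on simulated data
        from mmagc.simulation import SimulationConfig, simulate_study
        from mmagc.gene_correlation import correlation_matrix
        from mmagc.meta_combination import combine_diagonal, finalize_for_clustering

        study = simulate_study(SimulationConfig(sample_size=100), seed=3)
        corr = finalize_for_clustering(
            combine_diagonal([correlation_matrix(study.study, "MSOC")]))
        grid = tuple(range(1, 21))
        prof = connectivity_profile(corr, grid)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = select_power_traditional(corr, grid, profile=prof)
        i = grid.index(m)
        qualifying = [
            j for j in range(len(grid))
            if np.isfinite(prof.fit_r2[j]) and prof.fit_r2[j] >= 0.6
            and (j == 0 or prof.change_rate[j] <= 1 / 3)
        ]
        if qualifying:
            assert i == qualifying[0]
        else:  # fallback: best available fit
            assert prof.fit_r2[i] == np.nanmax(prof.fit_r2)

    def test_traditional_fallback_warns(self):
        corr = uniform_similarity(25, 0.5)  # single bin -> fit not assessable
        with pytest.warns(UserWarning, match="falling back"):
            select_power_traditional(corr)

    def test_inflection_uniform_matrix_uses_boundary(self):
        # geometric connectivity decay: the change rate has no interior
        # inflection, so the rule settles on the second grid power
        corr = uniform_similarity(30, 0.6)
        assert select_power_inflection(corr) == 2

    def test_inflection_detects_constructed_sign_change(self):
        # build k(m) whose change-rate's rate-of-change dips at a known spot
        grid = tuple(range(1, 11))
        rho = np.array([0.5, 0.45, 0.35, 0.32, 0.31, 0.305, 0.3025, 0.30125,
                        0.3006])  # delta dips at its second entry
        k = [10.0]
        for r in rho:
            k.append(k[-1] * (1 - r))
        prof = ConnectivityProfile(grid=grid, mean_k=np.array(k[:10]),
                                   fit_r2=np.full(10, 0.7))
        delta = np.diff(rho)
        j = next(i for i in range(1, len(delta) - 1)
                 if (delta[i] - delta[i - 1]) * (delta[i + 1] - delta[i]) < 0)
        got = select_power_inflection(np.eye(2), grid, profile=prof)
        assert got == grid[j + 1]

    def test_inflection_smaller_than_traditional_on_pooled_data(self):
        from mmagc.simulation import case_configs, simulate_meta
        from mmagc.gene_correlation import correlation_matrix
        from mmagc.meta_combination import combine_diagonal, finalize_for_clustering

        studies = simulate_meta(case_configs(1), master_seed=12345)
        corr = finalize_for_clustering(combine_diagonal(
            [correlation_matrix(s.study, "MSOC") for s in studies]))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_power_inflection(corr) < select_power_traditional(corr)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            select_power_inflection(np.eye(3), grid=(1, 2, 3))


class TestTOM:
    def test_two_nodes_single_edge(self):
        a = 0.4
        A = np.array([[1.0, a], [a, 1.0]])
        T = tom(A)
        assert T[0, 1] == pytest.approx(a)  # l=0, min k = a -> a/(a+1-a)
        assert T[0, 0] == 1.0

    def test_unweighted_triangle_fully_overlapping(self):
        A = np.ones((3, 3))
        np.testing.assert_allclose(tom(A), 1.0)

    def test_matches_triple_loop_reference(self, rng):
        A = random_similarity(5, rng)
        T = tom(A)
        G = 5
        for i in range(G):
            for j in range(G):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                l_ij = sum(A[i, g] * A[g, j] for g in range(G) if g not in (i, j))
                k_i = sum(A[i, g] for g in range(G) if g != i)
                k_j = sum(A[j, g] for g in range(G) if g != j)
                ref = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_range_and_symmetry_for_any_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        A = random_similarity(int(rng.integers(3, 12)), rng)
        T = tom(A)
        assert T.min() >= 0.0 and T.max() <= 1.0
        np.testing.assert_allclose(T, T.T, atol=1e-14)
        np.testing.assert_array_equal(np.diag(T), 1.0)

    @given(st.integers(0, 10_000))
    def test_connectivity_nonincreasing_in_power(self, seed):
        rng = np.random.default_rng(seed)
        C = random_similarity(10, rng)
        ks = [mean_connectivity(adjacency(C, m)) for m in range(1, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(ks, ks[1:]))


def block_tom(sizes, within=1.0, between=0.0):
    G = sum(sizes)
    T = np.full((G, G), between)
    start = 0
    for s in sizes:
        T[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(T, 1.0)
    return T


class TestCluster:
    def test_two_perfect_blocks_recovered(self):
        T = block_tom([4, 3])
        got = cluster(T, min_cluster_size=2)
        assert got.n_clusters == 2
        assert adjusted_rand_index(got.labels, [1] * 4 + [2] * 3) == 1.0

    def test_labels_ordered_by_decreasing_size(self):
        got = cluster(block_tom([3, 5]), min_cluster_size=2)
        assert list(got.labels) == [2] * 3 + [1] * 5

    def test_min_size_above_gene_count_leaves_all_unassigned(self):
        got = cluster(block_tom([3, 3]), min_cluster_size=10)
        assert np.all(got.labels == 0)

    def test_small_cluster_genes_reassigned_to_nearest(self):
        # the two-gene block dissolves and rejoins the closer big block
        T = block_tom([5, 4, 2], between=0.0)
        T[0:5, 5:9] = T[5:9, 0:5] = 0.5   # two big blocks moderately close
        T[9:11, 0:5] = T[0:5, 9:11] = 0.1  # the pair sits nearer block 1
        got = cluster(T, min_cluster_size=3)
        assert got.n_clusters == 2
        assert set(got.labels[9:11]) == {got.labels[0]}

    def test_permutation_invariance_up_to_relabeling(self, rng):
        T = block_tom([4, 4, 4], within=0.9, between=0.05)
        noise = rng.uniform(0, 0.02, size=T.shape)
        T = np.clip(0.5 * (noise + noise.T) + T, 0, 1)
        np.fill_diagonal(T, 1.0)
        perm = rng.permutation(12)
        a = cluster(T, 2).labels
        b = cluster(T[np.ix_(perm, perm)], 2).labels
        assert adjusted_rand_index(a[perm], b) == 1.0

    def test_deterministic(self, rng):
        T = np.clip(block_tom([5, 5]) + 0.01 * random_similarity(10, rng), 0, 1)
        np.fill_diagonal(T, 1.0)
        a = cluster(T, 3)
        b = cluster(T, 3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_quantile_and_absolute_cut_policies_run(self):
        T = block_tom([4, 4])
        for cut in ("quantile", 0.5):
            got = cluster(T, 2, cut=cut)
            assert len(got.labels) == 8
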