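"""Power adjacency, scale-free selection, TOM, and module extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from pleionet.ldsc import GeneticCorrelationMatrix
from pleionet.network import (
    AdjacencyMatrix,
    DegenerateFitError,
    ModuleDetector,
    NetworkConfig,
    detect_modules,
    fit_power_law,
    modules_from_adjacency,
    power_adjacency,
    scale_free_fit,
    select_network_config,
    tom_dissimilarity,
)

from conftest import block_rg_matrix


def rg_from_matrix(R, P=None, valid=None):
    K = len(R)
    R = np.asarray(R, dtype=float)
    if P is None:
        P = np.full((K, K), 1e-4)
        np.fill_diagonal(P, 0.0)
    if valid is None:
        valid = np.ones((K, K), dtype=bool)
    return GeneticCorrelationMatrix(
        traits=[f"t{i}" for i in range(K)], rg=R, se=np.full((K, K), 0.1),
        p=np.asarray(P, dtype=float), valid=np.asarray(valid, dtype=bool),
    )


def random_adjacency(K, seed, density=1.0):
    rng = np.random.default_rng(seed)
    A = rng.random((K, K))
    A = (A + A.T) / 2
    if density < 1.0:
        mask = rng.random((K, K)) < density
        mask = mask & mask.T
        A = np.where(mask, A, 0.0)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix([f"t{i}" for i in range(K)], A, NetworkConfig(1, 1.0))


class TestPowerAdjacency:
    def test_soft_threshold_value(self):
        rg = rg_from_matrix([[1, 0.5], [0.5, 1]])
        adj = power_adjacency(rg, 6, 0.2)
        assert adj.a[0, 1] == pytest.approx(0.015625)

    def test_sign_absorbed_by_absolute_value(self):
        pos = power_adjacency(rg_from_matrix([[1, 0.5], [0.5, 1]]), 6, 0.2)
        neg = power_adjacency(rg_from_matrix([[1, -0.5], [-0.5, 1]]), 6, 0.2)
        np.testing.assert_allclose(pos.a, neg.a)

    def test_p_threshold_zeroes_edge(self):
        P = [[0.0, 0.3], [0.3, 0.0]]
        adj = power_adjacency(rg_from_matrix([[1, 0.9], [0.9, 1]], P=P), 6, 0.2)
        assert adj.a[0, 1] == 0.0

    def test_invalid_pair_zeroed_and_diagonal_zero(self):
        valid = np.array([[True, False], [False, True]])
        adj = power_adjacency(rg_from_matrix([[1, np.nan], [np.nan, 1]], valid=valid), 2, 0.5)
        assert adj.a[0, 1] == 0.0 and adj.a[0, 0] == 0.0

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            power_adjacency(rg_from_matrix([[1, 0.5], [0.5, 1]]), 0.5, 0.2)

    @pytest.mark.parametrize("beta", [2, 4, 6, 8])
    def test_monotonicity_in_rg_and_beta(self, beta):
        lo = power_adjacency(rg_from_matrix([[1, 0.4], [0.4, 1]]), beta, 1.0).a[0, 1]
        hi = power_adjacency(rg_from_matrix([[1, 0.6], [0.6, 1]]), beta, 1.0).a[0, 1]
        one = power_adjacency(rg_from_matrix([[1, 1.0], [1.0, 1]]), beta, 1.0).a[0, 1]
        assert hi > lo
        assert one == pytest.approx(1.0)
        if beta > 2:
            weaker = power_adjacency(rg_from_matrix([[1, 0.6], [0.6, 1]]), 2, 1.0).a[0, 1]
            assert hi < weaker


class TestScaleFreeFit:
    def test_exact_inverse_power_law(self):
        # degrees 1..10 with counts proportional to 1/k: one degree per
        # equal-width bin, so the log-log points sit exactly on slope -1
        degrees = np.concatenate([np.repeat(k, 2520 // k) for k in range(1, 11)])
        fit = fit_power_law(degrees, n_bins=10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_complete_graph_degenerate(self):
        K = 8
        rg = rg_from_matrix(np.full((K, K), 0.8))
        with pytest.raises(DegenerateFitError):
            scale_free_fit(power_adjacency(rg, 2, 0.5))

    def test_zero_degree_nodes_counted_not_binned(self):
        degrees = np.array([0, 0, 1, 1, 2, 3, 3, 3])
        fit = fit_power_law(degrees, n_bins=3)
        assert fit.n_zero_degree == 2
        assert fit.bins["freq"].sum() == pytest.approx(1.0)

    def test_dense_random_graph_is_not_scale_free(self):
        hits = 0
        for seed in range(20):
            adj = random_adjacency(100, seed, density=0.5)
            try:
                fit = scale_free_fit(adj)
                hits += fit.r2 < 0.5
            except DegenerateFitError:
                hits += 1  # concentrated degrees: certainly not scale-free
        assert hits >= 18


def hub_rg_matrix(seed=0, K=40):
    """Hub-structured r_g: a few high-degree nodes, many leaves."""
    rng = np.random.default_rng(seed)
    R = np.zeros((K, K))
    P = np.full((K, K), 0.9)
    hubs = range(4)
    for h in hubs:
        for j in range(K):
            if j == h:
                continue
            if rng.random() < 0.6:
                R[h, j] = R[j, h] = rng.uniform(0.4, 0.9)
                P[h, j] = P[j, h] = rng.uniform(0.0, 0.4)
    for _ in range(K):
        i, j = rng.integers(0, K, 2)
        if i != j:
            R[i, j] = R[j, i] = rng.uniform(0.1, 0.7)
            P[i, j] = P[j, i] = rng.uniform(0.0, 0.4)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    return rg_from_matrix(R, P=P)


class TestSelectNetworkConfig:
    def test_matches_exhaustive_oracle(self):
        rg = hub_rg_matrix(seed=3)
        betas, thrs = (2, 4, 6, 8), (0.5, 0.3, 0.2, 0.1)
        config, table = select_network_config(rg, betas, thrs)
        best = None
        for b in betas:
            for t in thrs:
                try:
                    fit = scale_free_fit(power_adjacency(rg, b, t))
                except DegenerateFitError:
                    continue
                if fit.slope >= 0:
                    continue
                if best is None or fit.r2 > best[0] + 1e-12:
                    best = (fit.r2, b, t)
        assert (config.beta, config.p_threshold) == (best[1], best[2])
        assert len(table) == 16

    def test_tie_break_prefers_smaller_beta_then_larger_threshold(self):
        # count-based degrees do not depend on beta, so every beta ties and
        # the smallest must win
        rg = hub_rg_matrix(seed=5)
        config, table = select_network_config(rg, (4, 2, 8), (0.3,))
        assert config.beta == 2
        ok = table[table["status"] == "ok"]
        assert ok.groupby("threshold")["r2"].nunique().le(1).all()

    def test_single_usable_cell_selected(self):
        rg, _ = block_rg_matrix([3, 3], within=0.9)
        # uniform degrees -> degenerate everywhere; selection must refuse
        with pytest.raises(DegenerateFitError, match="manual"):
            select_network_config(rg, (2,), (0.2,))

    def test_empty_grid_rejected(self):
        rg = hub_rg_matrix(seed=6)
        with pytest.raises(ValueError, match="non-empty"):
            select_network_config(rg, (), (0.2,))


class TestTOM:
    def test_fully_connected_unit_adjacency(self):
        rg = rg_from_matrix(np.ones((3, 3)))
        tom = tom_dissimilarity(power_adjacency(rg, 1, 1.0))
        assert tom.w[0, 1] == pytest.approx(1.0)
        assert tom.d[0, 1] == pytest.approx(0.0)

    def test_single_edge_pair(self):
        rg = rg_from_matrix([[1, 0.5], [0.5, 1]])
        tom = tom_dissimilarity(power_adjacency(rg, 1, 1.0))
        # l=0, k=0.5 each: w = 0.5 / (0.5 + 1 - 0.5)
        assert tom.w[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        adj = random_adjacency(6, seed=7)
        tom = tom_dissimilarity(adj)
        A = adj.a
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom.w[i, j] == 1.0
                    continue
                lij = sum(A[i, u] * A[u, j] for u in range(6) if u not in (i, j))
                ki = sum(A[i, u] for u in range(6) if u != i)
                kj = sum(A[j, u] for u in range(6) if u != j)
                expected = (lij + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
                assert tom.w[i, j] == pytest.approx(expected, abs=1e-12)
                assert tom.d[i, j] == 1 - tom.w[i, j]

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000), st.floats(0.2, 1.0))
    def test_bounds_and_symmetry_property(self, K, seed, density):
        adj = random_adjacency(K, seed, density=density)
        tom = tom_dissimilarity(adj)
        assert np.all(tom.w >= -1e-12) and np.all(tom.w <= 1 + 1e-12)
        np.testing.assert_allclose(tom.w, tom.w.T, atol=1e-12)
        np.testing.assert_allclose(tom.d, 1.0 - tom.w, atol=0)


class TestModules:
    def test_three_perfect_blocks(self):
        rg, truth = block_rg_matrix([5, 4, 3], within=0.9)
        det = ModuleDetector(beta=6, p_threshold=0.2).fit(rg)
        assert det.partition_.n_modules == 3
        assert adjusted_rand_score(truth, det.labels_) == 1.0

    def test_uniform_network_single_module(self):
        rg = rg_from_matrix(np.full((6, 6), 0.8))
        part, _ = modules_from_adjacency(power_adjacency(rg, 6, 0.5))
        assert part.n_modules == 1
        assert set(part.labels) == {1}

    def test_isolated_nodes_get_label_zero(self):
        rg, truth = block_rg_matrix([5, 4], within=0.9)
        K = len(rg.traits)
        R2 = np.eye(K + 2)
        R2[:K, :K] = rg.rg
        P2 = np.full((K + 2, K + 2), 0.9)
        P2[:K, :K] = rg.p
        np.fill_diagonal(P2, 0.0)
        rg2 = rg_from_matrix(R2, P=P2)
        base = ModuleDetector(beta=6, p_threshold=0.2).fit(rg).labels_
        ext = ModuleDetector(beta=6, p_threshold=0.2).fit(rg2).labels_
        assert list(ext[K:]) == [0, 0]
        assert adjusted_rand_score(base, ext[:K]) == 1.0

    def test_noisy_planted_blocks_recovered(self):
        hits = 0
        for seed in range(20):
            rg, truth = block_rg_matrix([6, 5, 4], within=0.7, noise=0.1, seed=seed)
            det = ModuleDetector(beta=6, p_threshold=0.2).fit(rg)
            hits += adjusted_rand_score(truth, det.labels_) >= 0.9
        assert hits == 20

    def test_permutation_equivariance(self):
        rg, truth = block_rg_matrix([5, 4, 3], within=0.8, noise=0.05, seed=1)
        det = ModuleDetector(beta=6, p_threshold=0.2).fit(rg)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(rg.traits))
        rg_p = GeneticCorrelationMatrix(
            traits=[rg.traits[i] for i in perm],
            rg=rg.rg[np.ix_(perm, perm)],
            se=rg.se[np.ix_(perm, perm)],
            p=rg.p[np.ix_(perm, perm)],
            valid=rg.valid[np.ix_(perm, perm)],
        )
        det_p = ModuleDetector(beta=6, p_threshold=0.2).fit(rg_p)
        assert adjusted_rand_score(det.labels_[perm], det_p.labels_) == 1.0
        np.testing.assert_allclose(
            det_p.adjacency_.a, det.adjacency_.a[np.ix_(perm, perm)], atol=1e-15
        )

    def test_min_size_fallback_to_zero_label(self):
        rg, _ = block_rg_matrix([2, 5], within=0.9)
        det = ModuleDetector(beta=6, p_threshold=0.2, min_size=3).fit(rg)
        assert det.labels_[0] == 0 and det.labels_[1] == 0
        assert det.partition_.n_modules == 1

    def test_too_few_nodes_single_label_zero(self):
        rg, _ = block_rg_matrix([2], within=0.9)
        with pytest.warns(UserWarning, match="min_size"):
            part, _ = modules_from_adjacency(power_adjacency(rg, 6, 0.5), min_size=3)
        assert set(part.labels) == {0}
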