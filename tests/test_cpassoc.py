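"""S_Hom / S_Het combined statistics, R estimation and null calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pleionet import (
    SimulationTruth,
    calibrate_shet_null,
    estimate_R,
    gwas_scan,
    module_scan,
    s_het,
    s_hom,
    shet_pvalue,
    simulate_genotypes,
    simulate_phenotypes,
)
from pleionet.cpassoc import GENOME_WIDE_P, _SubsetCache, _shet_batch


def oracle_shet(T, R=None, weights=None):
    """Independent brute force: evaluate the truncated statistic on every
    magnitude-ordered prefix subset using plain matrix inverses."""
    T = np.asarray(T, dtype=float)
    k = len(T)
    R = np.eye(k) if R is None else np.asarray(R, dtype=float)
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(-np.abs(T), kind="stable")
    best = -np.inf
    for q in range(1, k + 1):
        idx = np.sort(order[:q])
        Rs = R[np.ix_(idx, idx)]
        Ws = np.diag(w[idx])
        e = np.ones(q)
        num = float(e @ np.linalg.inv(Rs @ Ws) @ T[idx]) ** 2
        den = float(e @ np.linalg.inv(Ws @ Rs @ Ws) @ e)
        best = max(best, num / den)
    return best


def random_correlation(k, rng):
    A = rng.standard_normal((k, k + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestSHom:
    def test_single_statistic_chi2_tail(self):
        S, p = s_hom([2.0])
        assert S == pytest.approx(4.0)
        assert p == pytest.approx(sps.chi2.sf(4.0, 1))

    def test_identity_r_equal_weights_reduces_to_sum(self):
        S, _ = s_hom([1.0, 1.0])
        assert S == pytest.approx(2.0)

    def test_opposite_effects_cancel(self):
        S, p = s_hom([1.0, -1.0])
        assert S == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            s_hom([1.0, 2.0], R=np.eye(3))
        with pytest.raises(ValueError):
            s_hom([1.0, 2.0], weights=[1.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        T = rng.standard_normal(5)
        R = random_correlation(5, rng)
        w = rng.uniform(10, 50, 5)
        perm = rng.permutation(5)
        a, _ = s_hom(T, R, w)
        b, _ = s_hom(T[perm], R[np.ix_(perm, perm)], w[perm])
        assert a == pytest.approx(b, abs=1e-10)

    def test_equal_weights_cancel(self):
        rng = np.random.default_rng(1)
        T = rng.standard_normal(4)
        R = random_correlation(4, rng)
        a, _ = s_hom(T, R, np.full(4, 37.0))
        b, _ = s_hom(T, R, None)
        assert a == pytest.approx(b, abs=1e-10)

    def test_weight_conventions_agree_for_equal_weights(self):
        rng = np.random.default_rng(2)
        T = rng.standard_normal(4)
        R = random_correlation(4, rng)
        a, _ = s_hom(T, R, np.full(4, 5.0), convention="printed")
        b, _ = s_hom(T, R, np.full(4, 5.0), convention="direct")
        assert a == pytest.approx(b, abs=1e-10)


class TestSHet:
    def test_singleton_is_t_squared(self):
        S, tau, idx = s_het([3.0])
        assert S == pytest.approx(9.0)
        assert tau == 0.0 and list(idx) == [0]

    def test_small_component_dropped(self):
        S, tau, idx = s_het([3.0, 0.1])
        assert S == pytest.approx(9.0)
        assert tau == pytest.approx(0.1)
        assert list(idx) == [0]

    def test_opposite_signs_recovered(self):
        S, _, idx = s_het([3.0, -3.0])
        assert S == pytest.approx(9.0)
        assert len(idx) == 1
        assert s_hom([3.0, -3.0])[0] == pytest.approx(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 4), st.integers(0, 100_000), st.booleans())
    def test_matches_bruteforce_oracle(self, k, seed, weighted):
        rng = np.random.default_rng(seed)
        T = rng.standard_normal(k) * 2
        R = random_correlation(k, rng)
        w = rng.uniform(5, 50, k) if weighted else None
        S, _, _ = s_het(T, R, w)
        assert S == pytest.approx(oracle_shet(T, R, w), abs=1e-10)

    def test_dominates_largest_single_component(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            T = rng.standard_normal(5) * 2
            R = random_correlation(5, rng)
            S, _, _ = s_het(T, R)
            assert S >= T.max() ** 2 - 1e-10 or S >= (T**2).max() - 1e-10

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(4)
        K = 5
        R = random_correlation(K, rng)
        w = rng.uniform(10, 40, K)
        Z = rng.standard_normal((200, K)) * 1.5
        cache = _SubsetCache(R, w, "printed")
        S_batch, q = _shet_batch(Z, cache)
        for i in range(0, 200, 17):
            S, _, idx = s_het(Z[i], R, w)
            assert S_batch[i] == pytest.approx(S, abs=1e-10)
            assert q[i] == len(idx)


class TestNullCalibration:
    def test_k1_reduces_to_chi2_and_uniform_beta(self):
        null = calibrate_shet_null(np.eye(1), B=100_000, seed=5)
        assert null.beta_a == pytest.approx(1.0, abs=0.05)
        assert null.beta_b == pytest.approx(1.0, abs=0.05)
        # S_Het == T^2 under K=1: empirical quantiles match chi2(1)
        q95 = np.quantile(null.draws_sorted, 0.95)
        assert q95 == pytest.approx(sps.chi2.ppf(0.95, 1), rel=0.05)

    def test_empirical_quantile_pvalue(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        null = calibrate_shet_null(R, B=20_000, seed=6)
        s95 = np.quantile(null.draws_sorted, 0.95)
        assert shet_pvalue(s95, null) == pytest.approx(0.05, abs=2 / np.sqrt(20_000))

    def test_determinism(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = calibrate_shet_null(R, B=10_000, seed=7)
        b = calibrate_shet_null(R, B=10_000, seed=7)
        np.testing.assert_array_equal(a.draws_sorted, b.draws_sorted)
        assert (a.beta_a, a.beta_b) == (b.beta_a, b.beta_b)

    def test_b_floor_enforced(self):
        with pytest.raises(ValueError, match="10,000"):
            calibrate_shet_null(np.eye(2), B=500, seed=0)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            calibrate_shet_null(R, B=10_000, seed=0)

    def test_pvalue_monotone_and_floor(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        null = calibrate_shet_null(R, B=10_000, seed=8)
        stats_grid = np.linspace(0, 40, 50)
        primary, emp, beta = null.pvalues(stats_grid)
        assert np.all(np.diff(primary) <= 1e-12)
        assert np.all(np.diff(beta) <= 1e-12)
        assert shet_pvalue(null.draws_sorted.min() - 1, null) == pytest.approx(
            1.0, abs=1 / 10_001 + 1e-9
        )
        assert shet_pvalue(null.draws_sorted[4999], null) == pytest.approx(0.5, abs=0.02)
        # beyond the empirical range the beta tail map takes over
        assert primary[-1] < 1 / 10_001


def simulate_module(seed, K=3, n=1500, m=2000, env_corr=0.5, fixed=None, h2=0.0):
    gt = simulate_genotypes(n, m, (0.1, 0.5), 0.0, seed=seed)
    truth = SimulationTruth.make(
        gt, h2=[h2] * K, rho_g=0.0, n_causal=50, seed=seed + 1,
        env_corr=env_corr, fixed_effects=fixed or {},
    )
    ph = simulate_phenotypes(gt, truth)
    return [gwas_scan(gt, ph, t) for t in ph.trait_names]


class TestEstimateR:
    def test_identical_inputs_give_unit_correlation(self):
        stats = simulate_module(10, K=1)
        from pleionet.datatypes import SummaryStats

        dup = [SummaryStats(f"c{i}", stats[0].table.copy()) for i in range(2)]
        R = estimate_R(dup)
        assert R.R[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_disjoint_sample_halves_give_near_zero(self):
        gt = simulate_genotypes(2000, 3000, (0.1, 0.5), 0.0, seed=11)
        truth = SimulationTruth.make(gt, h2=[0.0, 0.0], rho_g=0.0, n_causal=10,
                                     seed=12, env_corr=0.9)
        ph = simulate_phenotypes(gt, truth)
        half1 = gt.samples[:1000]
        half2 = gt.samples[1000:]
        s1 = gwas_scan(gt, ph, "T1", sample_subset=half1)
        s2 = gwas_scan(gt, ph, "T2", sample_subset=half2)
        R = estimate_R([s1, s2])
        assert abs(R.R[0, 1]) < 3 / np.sqrt(R.n_snps_used)

    def test_full_overlap_recovers_phenotypic_correlation(self):
        stats = simulate_module(13, K=2, n=2000, m=5000, env_corr=0.6, h2=0.0)
        R = estimate_R(stats)
        assert R.R[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_too_few_shared_snps(self):
        stats = simulate_module(14, K=2, m=300)
        with pytest.raises(ValueError, match="shared"):
            estimate_R(stats)

    def test_cutoff_too_strict_suggests_increase(self):
        stats = simulate_module(15, K=2, m=600)
        with pytest.raises(ValueError, match="cutoff"):
            estimate_R(stats, z_cutoff=0.05)


class TestModuleScan:
    def test_planted_aligned_and_opposite_snps(self):
        fixed = {
            "rs100": np.array([0.15, 0.15, 0.15]),
            "rs200": np.array([0.15, -0.15, 0.0]),
        }
        stats = simulate_module(16, K=3, n=2000, m=2000, env_corr=0.3, fixed=fixed)
        res = module_scan(stats, B=20_000, seed=17, threshold=1e-7)
        res = res.set_index("SNP")
        aligned = res.loc["rs100"]
        assert aligned["P_HOM"] == res["P_HOM"].min()
        opp = res.loc["rs200"]
        assert opp["P_HET"] < opp["P_HOM"]
        assert set(res.columns) >= {
            "S_HOM", "P_HOM", "S_HET", "TAU_STAR", "K_RETAINED",
            "P_HET_EMP", "P_HET_BETA", "SIGNIFICANT", "GENOME_WIDE",
        }

    def test_mismatched_null_model_rejected(self):
        stats = simulate_module(18, K=2, n=800, m=1200)
        wrong = calibrate_shet_null(np.eye(2), B=10_000, seed=19)
        with pytest.raises(ValueError, match="different R"):
            module_scan(stats, null=wrong)

    def test_significance_flag_inclusive_at_threshold(self):
        assert GENOME_WIDE_P == 5e-8
        stats = simulate_module(20, K=2, n=600, m=900)
        res = module_scan(stats, B=10_000, seed=21, threshold=1e-7)
        best = np.minimum(res["P_HOM"], res["P_HET"])
        np.testing.assert_array_equal(res["SIGNIFICANT"], best <= 1e-7)
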