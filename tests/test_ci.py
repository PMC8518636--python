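"""Eigenvalue mixture Q^2, adjusted vs chi-square intervals, and the
effective number of independent loci."""

import numpy as np
import pytest
from scipy import stats

from templink import (
    EigenSpectrum,
    build_R,
    chisq_ci,
    ci_for_f,
    ci_for_ne,
    effective_num_loci,
    eigen_spectrum,
    sample_q2,
    weighted_eigen_input,
)
from templink.ci import CorrelationModel, eigen_spectrum_blocks


class TestBuildR:
    def test_identity_for_uncorrelated_loci(self):
        k = 6
        c = np.full((k, k), 0.5)
        np.fill_diagonal(c, 0.0)
        r0 = np.eye(k)
        r = build_R(c, r0, 1000, 50, 50, 10)
        assert np.allclose(r, np.eye(k))

    def test_c_zero_passes_r0_through(self):
        c = np.zeros((2, 2))
        r0 = np.array([[1.0, 0.3], [0.3, 1.0]])
        r = build_R(c, r0, 1000, 50, 50, 10)
        assert r[0, 1] == pytest.approx(0.3)
        assert np.all(np.diag(r) == 1.0)

    def test_cross_chromosome_entries_negligible(self):
        """For unlinked pairs the correlation is linear in r0 with a factor
        below one-half (numerically ~0.43 in the first study regime); since
        the bias correction sends the r0 of truly unlinked pairs to ~0,
        cross-arm entries of R are effectively zero."""
        from templink import bias_correct_r0, delta_correlation

        factor = abs(delta_correlation(0.5, 1.0, 1238.0, 50, 50, 10))
        assert factor < 0.5
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        # an unlinked pair's raw |r| is below the sampling floor 1/sqrt(n)
        # in expectation, so its corrected r0 is exactly 0
        r0_corr = bias_correct_r0(0.08, 100)
        r0 = np.array([[1.0, r0_corr], [r0_corr, 1.0]])
        r = build_R(c, r0, 1238.0, 50, 50, 10)
        assert r[0, 1] == 0.0
        # and even a residual corrected r0 is damped by the unlinked factor
        r0 = np.array([[1.0, 0.1], [0.1, 1.0]])
        r = build_R(c, r0, 1238.0, 50, 50, 10)
        assert abs(r[0, 1]) == pytest.approx(0.1 * factor, rel=1e-9)

    def test_entry_above_one_rejected(self):
        c = np.zeros((2, 2))
        r0 = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            build_R(c, r0, 1000, 50, 50, 10)

    def test_correlation_model_validation(self):
        with pytest.raises(ValueError):
            CorrelationModel(np.array([[1.0, 0.2], [0.2, 0.9]]))
        m = CorrelationModel(np.eye(3))
        assert m.k == 3


class TestEigenSpectrum:
    def test_identity(self):
        spec = eigen_spectrum(np.eye(10))
        assert np.allclose(spec.lambdas, 1.0)
        assert spec.sum == pytest.approx(10.0)

    def test_two_by_two_closed_form(self):
        rho = 0.37
        spec = eigen_spectrum(np.array([[1.0, rho], [rho, 1.0]]))
        assert spec.lambdas == pytest.approx([1 + rho, 1 - rho])

    def test_block_diagonal_union(self):
        blocks = [np.array([[1.0, 0.5], [0.5, 1.0]]), np.eye(3)]
        full = np.zeros((5, 5))
        full[:2, :2] = blocks[0]
        full[2:, 2:] = blocks[1]
        a = eigen_spectrum(full).lambdas
        b = eigen_spectrum_blocks(blocks).lambdas
        assert np.allclose(a, b)

    def test_structurally_negative_rejected_strict(self):
        m = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        assert np.linalg.eigvalsh(m)[0] < -0.01
        with pytest.raises(ValueError):
            eigen_spectrum(m)

    def test_repair_restores_trace(self):
        m = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        spec = eigen_spectrum(m, repair=True)
        assert np.all(spec.lambdas >= 0)
        assert spec.sum == pytest.approx(3.0)


class TestWeightedPath:
    def test_equal_weights_recover_R(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        out = weighted_eigen_input(r, np.array([0.5, 0.5]))
        assert np.allclose(out, r)

    def test_identity_R_gives_K_w(self):
        w = np.array([0.1, 0.3, 0.6])
        out = weighted_eigen_input(np.eye(3), w)
        assert np.allclose(np.sort(np.diag(out)), np.sort(3 * w))

    def test_trace_conservation_both_paths(self, rng):
        """Sum of eigenvalues equals K for R and for K W^1/2 R W^1/2."""
        k = 40
        data = rng.standard_normal((200, k))
        data[:, 1] = 0.7 * data[:, 0] + 0.3 * data[:, 1]
        r = np.corrcoef(data, rowvar=False)
        spec_a = eigen_spectrum(r)
        assert spec_a.sum == pytest.approx(k, abs=1e-6 * k)
        w = rng.dirichlet(np.ones(k))
        spec_b = eigen_spectrum(weighted_eigen_input(r, w))
        assert spec_b.sum == pytest.approx(k, abs=1e-6 * k)

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_eigen_input(np.eye(3), np.array([0.5, 0.5]))


class TestQ2Sampling:
    def test_chisq_moments_when_identity(self):
        spec = EigenSpectrum(lambdas=np.ones(100))
        q2 = sample_q2(spec, 50_000, rng=7)
        # chi2_100: mean 100, var 200; 3 MC SEs
        se_mean = np.sqrt(200 / 50_000)
        assert abs(q2.draws.mean() - 100) < 3 * se_mean
        assert abs(q2.draws.var() - 200) / 200 < 0.05

    def test_rank_one_spectrum_is_scaled_chi1(self):
        k = 50
        spec = EigenSpectrum(lambdas=np.array([float(k)] + [0.0] * (k - 1)))
        q2 = sample_q2(spec, 100_000, rng=11)
        assert q2.quantile(0.975) == pytest.approx(k * 5.0239, rel=0.03)

    def test_zero_spectrum(self):
        spec = EigenSpectrum(lambdas=np.array([0.0]))
        q2 = sample_q2(spec, 1000, rng=1)
        assert np.all(q2.draws == 0.0)

    def test_reproducible_given_seed(self):
        spec = EigenSpectrum(lambdas=np.linspace(0.5, 1.5, 20))
        a = sample_q2(spec, 5000, rng=42).draws
        b = sample_q2(spec, 5000, rng=42).draws
        assert np.array_equal(a, b)


class TestIntervals:
    def test_adjusted_matches_chisq_for_identity_R(self):
        k, f_hat = 200, 0.02
        spec = EigenSpectrum(lambdas=np.ones(k))
        q2 = sample_q2(spec, 200_000, rng=3)
        lo_a, hi_a = ci_for_f(f_hat, q2, k)
        lo_c, hi_c = chisq_ci(f_hat, k)
        assert lo_a == pytest.approx(lo_c, rel=0.01)
        assert hi_a == pytest.approx(hi_c, rel=0.01)

    def test_zero_f_hat(self):
        spec = EigenSpectrum(lambdas=np.ones(5))
        q2 = sample_q2(spec, 2000, rng=1)
        assert ci_for_f(0.0, q2, 5) == (0.0, 0.0)

    def test_wider_spectrum_wider_interval(self):
        k, f_hat = 100, 0.02
        tight = EigenSpectrum(lambdas=np.ones(k))
        lam = np.ones(k)
        lam[:10] += 5.0
        lam *= k / lam.sum()
        wide = EigenSpectrum(lambdas=lam)
        q_t = sample_q2(tight, 100_000, rng=5)
        q_w = sample_q2(wide, 100_000, rng=5)
        lo_t, hi_t = ci_for_f(f_hat, q_t, k)
        lo_w, hi_w = ci_for_f(f_hat, q_w, k)
        assert lo_w < lo_t and hi_w > hi_t

    def test_chisq_k1_quantile_anchor(self):
        f_hat = 0.05
        lo, hi = chisq_ci(f_hat, 1)
        assert lo == pytest.approx(f_hat / 5.0239, rel=1e-4)
        assert hi == pytest.approx(f_hat / 0.000982069, rel=1e-3)

    def test_chisq_interval_shrinks_with_k(self):
        f_hat = 0.02
        w1 = np.diff(chisq_ci(f_hat, 100))[0]
        w2 = np.diff(chisq_ci(f_hat, 10_000))[0]
        assert w2 < w1 / 5

    def test_ne_bounds_anti_monotone(self):
        ne_lo, ne_hi = ci_for_ne(0.0171, 0.0196, 92, 45, 20)
        assert ne_lo == pytest.approx(3274, rel=0.01)
        assert ne_hi == pytest.approx(18047, rel=0.01)
        assert ne_lo < ne_hi

    def test_ne_upper_bound_infinite_below_floor(self):
        floor = 1 / 100 + 1 / 100
        ne_lo, ne_hi = ci_for_ne(floor - 1e-4, 0.025, 50, 50, 10)
        assert np.isinf(ne_hi)
        assert np.isfinite(ne_lo)

    def test_degenerate_f_interval(self):
        ne_lo, ne_hi = ci_for_ne(0.025, 0.025, 50, 50, 10)
        assert ne_lo == ne_hi


class TestEffectiveLoci:
    def test_identity_gives_k(self):
        assert effective_num_loci(EigenSpectrum(lambdas=np.ones(17))) == pytest.approx(17)

    def test_rank_one_gives_one(self):
        k = 20
        spec = EigenSpectrum(lambdas=np.array([float(k)] + [0.0] * (k - 1)))
        assert effective_num_loci(spec) == pytest.approx(1.0)

    def test_two_perfect_blocks_give_two(self):
        k = 10  # two blocks of 5 perfectly correlated loci
        lam = np.array([5.0, 5.0] + [0.0] * (k - 2))
        assert effective_num_loci(EigenSpectrum(lambdas=lam)) == pytest.approx(2.0)

    def test_bounds(self, rng):
        data = rng.standard_normal((100, 30))
        spec = eigen_spectrum(np.corrcoef(data, rowvar=False))
        kp = effective_num_loci(spec)
        assert 1.0 <= kp <= 30.0
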