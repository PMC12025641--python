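import numpy as np
import pytest

from lfpconn import core_io, kencoh, simulate, spectral, timedep
from lfpconn.exceptions import SingularityError


class TestKendallTau:
    def test_monotone_pair_is_maximal(self):
        x = np.arange(20.0)
        z = np.vstack([x, np.exp(x / 10)])  # strictly increasing map
        tau = kencoh.kendall_lag_tau(z, 0)
        assert tau[0, 1] == pytest.approx(1.0)

    def test_brute_equals_fast_on_random_arrays(self, rng):
        for _ in range(50):
            z = rng.standard_normal((2, 40))
            for h in (0, 2):
                tb = kencoh.kendall_lag_tau(z, h, method="brute")
                tf = kencoh.kendall_lag_tau(z, h, method="fast")
                np.testing.assert_allclose(tb, tf, atol=1e-12)

    def test_gaussian_arcsine_law(self):
        rng = np.random.default_rng(8)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000).T
        tau = kencoh.kendall_lag_tau(z, 0)
        assert abs(tau[0, 1] - 1 / 3) < 0.03

    def test_constant_channel_warns_and_zeroes(self):
        z = np.vstack([np.ones(30), np.arange(30.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            tau = kencoh.kendall_lag_tau(z, 0)
        assert tau[0, 1] == 0.0

    def test_lagged_tau_detects_shifted_dependence(self, rng):
        x = rng.standard_normal(500)
        z = np.vstack([x, np.roll(x, 2)])  # channel 2 is channel 1 delayed by 2
        tau0 = kencoh.kendall_lag_tau(z[:, 2:], 0)
        assert abs(tau0[0, 1]) < 0.2  # no same-time dependence
        tau2 = kencoh.kendall_lag_tau(z, 2)
        assert tau2[0, 1] == pytest.approx(1.0, abs=1e-12)  # Z1_{t-2} == Z2_t


class TestScaleMatrix:
    @pytest.mark.parametrize("tau,lam", [(1 / 3, 0.5), (0.0, 0.0), (1.0, 1.0), (-1.0, -1.0)])
    def test_sine_transform_values(self, tau, lam):
        assert np.sin(np.pi / 2 * tau) == pytest.approx(lam)

    def test_consistency_on_clean_gaussian(self):
        rng = np.random.default_rng(9)
        corr = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
        z = rng.multivariate_normal(np.zeros(3), corr, size=5000).T
        lam = kencoh.robust_scale_matrix(z, 0, "kendall_sine").values
        assert np.abs(lam - corr).max() < 0.05

    def test_sample_covariance_path_is_correlation(self, rng):
        z = rng.standard_normal((3, 400))
        lam = kencoh.robust_scale_matrix(z, 0, "sample_covariance").values
        expected = timedep.correlation_matrix(z).values
        np.testing.assert_allclose(lam, expected, atol=1e-10)


class TestCBC:
    def test_scalar_reduction(self, rng):
        # P=Q=1: phi equals the squared maximal lagged cross-correlation
        x = rng.standard_normal(500)
        y = 0.6 * np.roll(x, -1) + 0.8 * rng.standard_normal(500)
        z = np.vstack([x, y])
        res = kencoh.cbc_from_trial(z, 1, 1, h_max=3, estimator="sample_covariance")
        best = 0.0
        xm, ym = x - x.mean(), y - y.mean()
        for h in range(4):
            t = len(x)
            num = (xm[: t - h] * ym[h:]).sum() / t
            rho2 = num**2 / (xm.var() * ym.var())
            best = max(best, rho2)
        assert res.phi == pytest.approx(best, abs=1e-10)

    def test_grid_search_oracle_2x2(self, rng):
        z = rng.standard_normal((4, 600))
        z[2] = 0.6 * z[0] + 0.4 * rng.standard_normal(600)
        scales = {h: kencoh.robust_scale_matrix(z, h, "sample_covariance").values
                  for h in range(3)}
        res = kencoh.cbc_solve(scales, 2, 2)
        A, C = scales[0][:2, :2], scales[0][2:, 2:]
        angles = np.linspace(0, np.pi, 721)
        U = np.column_stack([np.cos(angles), np.sin(angles)])
        U = U / np.sqrt(np.einsum("ij,jk,ik->i", U, A, U))[:, None]
        V = np.column_stack([np.cos(angles), np.sin(angles)])
        V = V / np.sqrt(np.einsum("ij,jk,ik->i", V, C, V))[:, None]
        best = max(np.max((U @ scales[h][:2, 2:] @ V.T) ** 2) for h in range(3))
        assert abs(res.phi - best) < 1e-3

    def test_independent_groups_small_phi(self, rng):
        z = rng.standard_normal((4, 2000))
        res = kencoh.cbc_from_trial(z, 2, 2, h_max=0, estimator="sample_covariance")
        assert res.phi <= 0.05

    def test_direction_normalization(self, rng):
        z = rng.standard_normal((5, 400))
        scales = {0: kencoh.robust_scale_matrix(z, 0, "sample_covariance").values}
        res = kencoh.cbc_solve(scales, 3, 2)
        A, C = scales[0][:3, :3], scales[0][3:, 3:]
        assert res.u @ A @ res.u == pytest.approx(1.0, abs=1e-8)
        assert res.v @ C @ res.v == pytest.approx(1.0, abs=1e-8)
        assert res.u[np.argmax(np.abs(res.u))] > 0

    def test_rescaling_invariance_of_phi(self, rng):
        z = rng.standard_normal((4, 500))
        z[3] = 0.5 * z[1] + z[3]
        r1 = kencoh.cbc_from_trial(z, 2, 2, h_max=1)
        z2 = z * np.array([2.0, 0.1, 30.0, 5.0])[:, None]
        r2 = kencoh.cbc_from_trial(z2, 2, 2, h_max=1)
        assert r1.phi == pytest.approx(r2.phi, abs=1e-10)

    def test_singular_block_raises(self, rng):
        x = rng.standard_normal(200)
        z = np.vstack([x, x, rng.standard_normal(200), rng.standard_normal(200)])
        scales = {0: kencoh.robust_scale_matrix(z, 0, "sample_covariance").values}
        with pytest.raises(SingularityError):
            kencoh.cbc_solve(scales, 2, 2)


class TestCanonicalCoherenceAtFrequency:
    def test_scalar_reduction_equals_band_coherence(self):
        spec = simulate.VARSpec(
            P=2, order=1, coeffs=[np.array([[0.5, 0.0], [0.4, 0.2]])],
            innov_cov=np.eye(2))
        ts = simulate.simulate_var_trials(spec, R=60, T=128, fs=1.0, seed=12)
        S = spectral.spectral_matrix(ts)
        fi = 20
        phi, a, b = kencoh.canonical_coherence_at_frequency(S, S.freqs[fi], 1, 1)
        m = S.matrices[fi]
        coh = np.abs(m[0, 1]) ** 2 / (m[0, 0].real * m[1, 1].real)
        assert phi == pytest.approx(coh, rel=1e-8)

    def test_independent_groups_bias_scale(self):
        spec = simulate.VARSpec(P=4, order=1, coeffs=[np.zeros((4, 4))],
                                innov_cov=np.eye(4))
        K = 100
        ts = simulate.simulate_var_trials(spec, R=K, T=128, fs=1.0, seed=13)
        S = spectral.spectral_matrix(ts)
        phi, _, _ = kencoh.canonical_coherence_at_frequency(S, S.freqs[30], 2, 2)
        assert phi <= 10 / K  # small-sample bias scale


class TestDirectionSummary:
    def test_single_trial(self):
        d = np.array([[0.3, -0.7, 0.1]])
        s = kencoh.trial_directions_summary(d)
        np.testing.assert_allclose(s.values, np.abs(d[0]))

    def test_median_robust_to_outlier(self):
        base = np.tile([0.5, 0.2, 0.8], (5, 1))
        dirs = np.vstack([base, [100.0, -50.0, 7.0]])
        s = kencoh.trial_directions_summary(dirs)
        np.testing.assert_allclose(s.values, [0.5, 0.2, 0.8])

    def test_matches_objective_minimization(self, rng):
        dirs = np.abs(rng.standard_normal((7, 3)))
        med = kencoh.trial_directions_summary(dirs).values
        # direct minimization of sum_r ||dirs_r - mu||_L1 over a fine grid
        for coord in range(3):
            grid = np.linspace(0, dirs[:, coord].max() + 0.5, 2001)
            obj = np.abs(dirs[:, coord][:, None] - grid[None, :]).sum(axis=0)
            assert abs(med[coord] - grid[np.argmin(obj)]) < 2e-3


class TestDirectionTest:
    def test_identical_sets_give_zero_stat_p_one(self, rng):
        u = np.abs(rng.standard_normal((4, 3)))
        v = np.abs(rng.standard_normal((4, 2)))
        res = kencoh.direction_difference_test((u, v), (u.copy(), v.copy()),
                                               n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_statistic_uses_printed_normalization(self):
        # L2 norms divided by P and Q (not sqrt P, sqrt Q)
        u_g = np.tile([1.0, 0.0, 0.0, 0.0], (3, 1))
        u_k = np.tile([0.0, 1.0, 0.0, 0.0], (3, 1))
        v = np.tile([1.0, 1.0], (3, 1))
        stat = kencoh._direction_stat(u_g, v, u_k, v)
        assert stat == pytest.approx(np.sqrt(2.0) / 4)

    def test_smote_balances_minority(self, rng):
        x = np.abs(rng.standard_normal((4, 5)))
        out = kencoh.smote_augment(x, 6, rng=rng)
        assert out.shape == (10, 5)
        # synthetic points lie within the convex hull coordinate ranges
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    def test_bh_equal_pvalues_unchanged(self):
        adj = timedep.benjamini_hochberg([0.01] * 10)
        np.testing.assert_allclose(adj, 0.01)

    def test_detects_genuine_difference(self, rng):
        u_g = np.abs(0.1 * rng.standard_normal((8, 3))) + np.array([1.0, 0.0, 0.0])
        u_k = np.abs(0.1 * rng.standard_normal((8, 3))) + np.array([0.0, 1.0, 0.0])
        v = np.abs(0.1 * rng.standard_normal((16, 2))) + 0.5
        res = kencoh.direction_difference_test((u_g, v[:8]), (u_k, v[8:]),
                                               n_perm=199, seed=1)
        assert res.p_raw < 0.05


class TestKenCohEstimator:
    def test_fit_on_simulated_trials(self):
        spec = simulate.VARSpec(
            P=4, order=1,
            coeffs=[np.array([[0.3, 0, 0, 0], [0, 0.3, 0, 0],
                              [0.4, 0, 0.2, 0], [0, 0, 0, 0.2]])],
            innov_cov=np.eye(4))
        ts = simulate.simulate_var_trials(spec, R=4, T=600, fs=1000.0, seed=20)
        est = kencoh.KenCoh(band=spectral.BANDS["beta"], h_max=2).fit(ts)
        assert est.phi_.shape == (4,)
        assert np.all((est.phi_ >= 0) & (est.phi_ <= 1))
        assert est.u_.shape == (4, 2) and est.v_.shape == (4, 2)
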