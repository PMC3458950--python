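"""Yule-Walker VAR estimation, AIC order selection and parametric coherence."""

import warnings

import numpy as np
import pytest

from normcoh import (
    VARModel,
    coherence,
    default_grid,
    fit_var_yule_walker,
    sample_autocovariances,
    select_order_aic,
    simulate_var,
    spectral_matrix,
    welch_coherence_oracle,
)

B_CROSS = np.array([[[0.5, 0.3], [0.3, 0.5]]])  # coupled stable VAR(1)


def random_stable_var(rng, p=None):
    p = p or rng.integers(1, 4)
    while True:
        coefs = rng.uniform(-0.4, 0.4, size=(p, 2, 2)) / p
        m = VARModel(order=p, coefs=coefs, sigma=np.eye(2), dt=2.0)
        if m.companion_spectral_radius() < 0.95:
            return m


class TestAutocovariances:
    def test_white_noise_limits(self):
        z = np.random.default_rng(0).standard_normal((50_000, 2))
        g = sample_autocovariances(z[:, 0], z[:, 1], 1)
        assert np.abs(g[0] - np.eye(2)).max() < 0.05
        assert np.abs(g[1]).max() < 0.05

    def test_identical_channels(self, rng):
        x = rng.standard_normal(500)
        g = sample_autocovariances(x, x, 2)
        assert np.allclose(g[0], g[0][0, 0])

    def test_bilinearity_in_scale(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        g1 = sample_autocovariances(x, y, 3)
        g2 = sample_autocovariances(3.0 * x, 3.0 * y, 3)
        assert np.allclose(g2, 9.0 * g1)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="exceed"):
            sample_autocovariances(np.zeros(5), np.zeros(5), 5)


class TestYuleWalker:
    def test_parameter_recovery_long_series(self):
        B = np.array([[[0.5, 0.2], [0.1, 0.4]]])
        z = simulate_var(B, np.eye(2), 100_000, seed=1)
        m = fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0)
        assert np.abs(m.coefs - B).max() < 0.02
        assert np.abs(m.sigma - np.eye(2)).max() < 0.02

    def test_error_shrinks_with_sample_size(self):
        B = np.array([[[0.5, 0.2], [0.1, 0.4]]])
        errs = []
        for T in (500, 5_000, 50_000):
            z = simulate_var(B, np.eye(2), T, seed=7)
            m = fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0)
            errs.append(np.abs(m.coefs - B).max())
        assert errs[0] > errs[2]

    def test_white_noise_coefficients_near_zero(self):
        z = np.random.default_rng(3).standard_normal((20_000, 2))
        m = fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0)
        assert np.abs(m.coefs).max() < 5.0 / np.sqrt(20_000)

    def test_near_noiseless_recovery(self):
        """Vanishing innovation variance leaves only the O(1/T) bias of the
        1/T autocovariance divisor."""
        B = np.array([[[0.6, 0.1], [0.2, 0.3]]])
        z = simulate_var(B, 1e-10 * np.eye(2), 100_000, seed=4)
        m = fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0)
        assert np.abs(m.coefs - B).max() < 5e-3

    def test_agrees_with_statsmodels_ols(self):
        from statsmodels.tsa.api import VAR as SmVAR

        z = simulate_var(B_CROSS, np.eye(2), 20_000, seed=5)
        mine = fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0)
        sm_fit = SmVAR(z).fit(maxlags=1, trend="n")
        assert np.abs(mine.coefs[0] - sm_fit.coefs[0]).max() < 0.02

    def test_short_series_warns(self):
        z = simulate_var(B_CROSS, np.eye(2), 60, seed=6)
        with pytest.warns(UserWarning, match="short"):
            fit_var_yule_walker(z[:, 0], z[:, 1], 8, dt=1.0)


class TestOrderSelection:
    def test_forced_single_candidate(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        assert select_order_aic(x, y, [3]) == 3

    def test_recovers_var2_majority(self):
        B = np.stack(
            [
                np.array([[0.2, 0.1], [0.1, 0.2]]),
                np.array([[0.4, 0.15], [0.15, 0.4]]),
            ]
        )
        chosen = []
        for s in range(8):
            z = simulate_var(B, np.eye(2), 5_000, seed=s)
            chosen.append(select_order_aic(z[:, 0], z[:, 1], dt=1.0))
        assert np.bincount(chosen).argmax() == 2

    def test_white_noise_prefers_small_orders(self):
        from normcoh.var import aic

        wins = 0
        for s in range(10):
            z = np.random.default_rng(s).standard_normal((1_000, 2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a1 = aic(fit_var_yule_walker(z[:, 0], z[:, 1], 1), 1_000)
                a10 = aic(fit_var_yule_walker(z[:, 0], z[:, 1], 10), 1_000)
            wins += a1 <= a10
        assert wins > 5


class TestSpectralMatrix:
    def test_white_noise_flat_identity(self):
        m = VARModel(order=1, coefs=np.zeros((1, 2, 2)), sigma=np.eye(2), dt=2.0)
        for f in (0.0, 0.1, 0.25):
            assert np.allclose(spectral_matrix(m, f), np.eye(2))

    def test_diagonal_sigma_flat(self):
        m = VARModel(order=1, coefs=np.zeros((1, 2, 2)), sigma=np.diag([3.0, 7.0]), dt=2.0)
        assert np.allclose(spectral_matrix(m, 0.17), np.diag([3.0, 7.0]))

    def test_ar1_closed_form_at_zero(self):
        m = VARModel(order=1, coefs=0.5 * np.eye(2)[None], sigma=np.eye(2), dt=1.0)
        S = spectral_matrix(m, 0.0)
        # scalar AR(1): S(0) = sigma^2 / (1 - b)^2 = 1 / 0.25 = 4
        assert np.allclose(np.diag(S).real, 4.0)
        assert abs(S[0, 1]) < 1e-12

    def test_hermitian_positive_diagonal(self, rng):
        for _ in range(10):
            m = random_stable_var(rng)
            S = spectral_matrix(m, rng.uniform(0, m.nyquist))
            assert np.allclose(S, S.conj().T)
            assert (np.diag(S).real > 0).all()

    def test_out_of_range_frequency_raises(self):
        m = VARModel(order=1, coefs=np.zeros((1, 2, 2)), sigma=np.eye(2), dt=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_matrix(m, 0.3)


class TestCoherence:
    def test_independent_channels_zero(self):
        m = VARModel(
            order=1, coefs=np.diag([0.5, 0.3])[None], sigma=np.diag([1.0, 2.0]), dt=2.0
        )
        spec = coherence(m, default_grid(2.0, 20))
        assert np.abs(spec.values).max() < 1e-12

    def test_default_grid_shape_and_nyquist(self):
        g = default_grid(2.0, 125)
        assert g.size == 125
        assert np.isclose(g[-1], 0.25)
        assert np.allclose(np.diff(g), 0.002)
        assert np.allclose(default_grid(2.0, 2), [0.125, 0.25])
        for dt in (0.5, 1.0, 2.0, 3.0):
            assert np.isclose(default_grid(dt, 50)[-1], 1.0 / (2 * dt))

    def test_bounds_for_random_stable_models(self, rng):
        for _ in range(15):
            m = random_stable_var(rng)
            v = coherence(m, default_grid(2.0, 40)).values
            assert (v >= 0).all() and (v <= 1).all()

    def test_channel_swap_invariance(self):
        z = simulate_var(B_CROSS, np.eye(2), 5_000, seed=8)
        c1 = coherence(fit_var_yule_walker(z[:, 0], z[:, 1], 1), default_grid(2.0, 30))
        c2 = coherence(fit_var_yule_walker(z[:, 1], z[:, 0], 1), default_grid(2.0, 30))
        assert np.allclose(c1.values, c2.values, atol=1e-10)

    def test_channel_rescaling_invariance(self):
        z = simulate_var(B_CROSS, np.eye(2), 5_000, seed=9)
        c1 = coherence(fit_var_yule_walker(z[:, 0], z[:, 1], 2), default_grid(2.0, 30))
        c2 = coherence(
            fit_var_yule_walker(5.0 * z[:, 0], 0.2 * z[:, 1], 2), default_grid(2.0, 30)
        )
        assert np.allclose(c1.values, c2.values, atol=1e-8)

    def test_matches_welch_oracle_on_long_simulation(self):
        z = simulate_var(B_CROSS, np.eye(2), 50_000, seed=10)
        w = welch_coherence_oracle(z[:, 0], z[:, 1], dt=1.0, segment_length=512)
        par = coherence(fit_var_yule_walker(z[:, 0], z[:, 1], 1, dt=1.0), w.frequencies)
        assert np.abs(par.values - w.values).mean() < 0.05
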