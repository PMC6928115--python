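"""Gaussian-approximation filter, smoother, and the particle-filter oracle."""

import numpy as np
import pytest

from mtssm.filtering import ga_filter, ga_smoother, particle_loglik
from mtssm.model import (
    ModelParams,
    attraction_prob,
    mixture_logdensity,
    stimuli_equation,
    vonmises_logdensity,
)
from mtssm.simulate import default_scenario, simulate_dataset


def uninformative_params(**kw):
    """Identical components: observations carry no information about z."""
    return ModelParams(gamma=np.zeros(1), kappa1=2.0, kappa2=2.0, mu1=0.9, mu2=0.9, **kw)


def grid_forward_backward(Y_i, beta, params, n_grid=4001, span=10.0):
    """Exact smoothing moments and log-likelihood by dense-grid integration.

    Brute-force forward-backward over a fine z grid: an independent oracle
    for the Gaussian approximation on small problems.
    """
    J, Np1 = Y_i.shape
    z = np.linspace(-span, span, n_grid)
    dz = z[1] - z[0]
    trans = np.exp(
        -0.5 * (z[None, :] - z[:, None]) ** 2 / params.sigma ** 2
    ) / np.sqrt(2 * np.pi * params.sigma ** 2)

    def meas(n):
        pi = attraction_prob(beta[:, None], z[None, :])
        lp = np.zeros_like(z)
        for j in range(J):
            lp += mixture_logdensity(Y_i[j, n], pi[j], params)
        return np.exp(lp - lp.max()), lp.max()

    prior0 = np.exp(-0.5 * (z - params.z0_mean) ** 2 / params.z0_var)
    prior0 /= prior0.sum() * dz
    loglik = 0.0
    alphas = np.empty((Np1, n_grid))
    pred = prior0
    for n in range(Np1):
        like, shift = meas(n)
        post = pred * like
        norm = post.sum() * dz
        loglik += np.log(norm) + shift
        post /= norm
        alphas[n] = post
        pred = trans @ post * dz
    # backward
    betas = np.ones(n_grid)
    smooth = np.empty((Np1, n_grid))
    smooth[-1] = alphas[-1]
    for n in range(Np1 - 2, -1, -1):
        like, _ = meas(n + 1)
        betas = trans @ (like * betas) * dz
        betas /= betas.max()
        s = alphas[n] * betas
        smooth[n] = s / (s.sum() * dz)
    means = smooth @ z * dz
    vars_ = smooth @ (z ** 2) * dz - means ** 2
    return loglik, means, vars_


class TestAnalyticLimit:
    def test_filtered_moments_follow_prior_recursion(self):
        params = uninformative_params()
        rng = np.random.default_rng(0)
        Y_i = rng.uniform(0, np.pi, size=(3, 21))
        fr = ga_filter(Y_i, np.zeros(3), params)
        n = np.arange(21)
        np.testing.assert_allclose(fr.P_filt, params.z0_var + n * params.sigma ** 2, atol=1e-10)
        np.testing.assert_allclose(fr.m_filt, params.z0_mean, atol=1e-10)

    def test_loglik_equals_von_mises_sum(self):
        params = uninformative_params()
        rng = np.random.default_rng(1)
        Y_i = rng.uniform(0, np.pi, size=(3, 21))
        fr = ga_filter(Y_i, np.zeros(3), params)
        exact = vonmises_logdensity(Y_i, params.mu1, params.kappa1).sum()
        assert fr.loglik == pytest.approx(float(exact), abs=1e-8)

    def test_no_trials_gives_prior_recursion_and_zero_loglik(self):
        params = uninformative_params()
        fr = ga_filter(np.empty((0, 11)), np.empty(0), params)
        assert fr.loglik == 0.0
        n = np.arange(11)
        np.testing.assert_allclose(fr.P_filt, 1.0 + n)


class TestFilterVsOracles:
    def test_matches_dense_grid_oracle(self, small_scenario):
        scen = default_scenario(I=1, J=3, K=3, N=12, seed=9)
        Y, _ = simulate_dataset(scen)
        beta = stimuli_equation(scen.design, scen.theta_true)
        fr = ga_smoother(ga_filter(Y.angles[0], beta, scen.theta_true), scen.theta_true)
        ll, means, vars_ = grid_forward_backward(
            Y.angles[0], beta, scen.theta_true, n_grid=6001, span=14.0
        )
        # tolerances reflect the documented Gaussian-closure accuracy
        assert fr.loglik == pytest.approx(ll, abs=max(0.1, 5e-3 * abs(ll)))
        np.testing.assert_allclose(fr.m_smooth, means, atol=0.15)
        np.testing.assert_allclose(fr.P_smooth, vars_, rtol=0.35, atol=0.05)

    def test_matches_particle_filter_within_monte_carlo_error(self):
        scen = default_scenario(I=2, J=4, K=2, N=50, seed=17)
        Y, _ = simulate_dataset(scen)
        beta = stimuli_equation(scen.design, scen.theta_true)
        for i in range(2):
            fr = ga_filter(Y.angles[i], beta, scen.theta_true)
            pl, se = particle_loglik(Y.angles[i], beta, scen.theta_true, 50_000, seed=i)
            # 1% relative: this instance uses the most concentrated kappa regime
            assert abs(fr.loglik - pl) <= max(3 * se, 1e-2 * abs(pl))

    def test_loglik_continuous_in_kappa(self, small_data, small_scenario):
        Y, _ = small_data
        beta = stimuli_equation(small_scenario.design, small_scenario.theta_true)
        p = small_scenario.theta_true
        base = ga_filter(Y.angles[0], beta, p).loglik
        bumped = ga_filter(Y.angles[0], beta, p.with_(kappa1=p.kappa1 + 1e-6)).loglik
        assert abs(bumped - base) < 1e-4

    def test_information_never_increases_uncertainty(self, small_data, small_scenario):
        Y, _ = small_data
        beta = stimuli_equation(small_scenario.design, small_scenario.theta_true)
        p = small_scenario.theta_true
        for i in range(Y.n_subjects):
            fr = ga_filter(Y.angles[i], beta, p)
            prior_var = p.z0_var + np.arange(Y.n_steps + 1) * p.sigma ** 2
            assert np.all(fr.P_filt <= prior_var + 1e-9)


class TestSmoother:
    def test_terminal_step_equals_filtered(self, small_data, small_scenario):
        Y, _ = small_data
        p = small_scenario.theta_true
        beta = stimuli_equation(small_scenario.design, p)
        fr = ga_smoother(ga_filter(Y.angles[0], beta, p), p)
        assert fr.m_smooth[-1] == fr.m_filt[-1]
        assert fr.P_smooth[-1] == fr.P_filt[-1]

    def test_smoothing_reduces_variance(self, small_data, small_scenario):
        Y, _ = small_data
        p = small_scenario.theta_true
        beta = stimuli_equation(small_scenario.design, p)
        for i in range(Y.n_subjects):
            fr = ga_smoother(ga_filter(Y.angles[i], beta, p), p)
            assert np.all(fr.P_smooth <= fr.P_filt + 1e-9)

    def test_uninformative_limit_constant_smoothed_mean(self):
        params = uninformative_params()
        rng = np.random.default_rng(4)
        Y_i = rng.uniform(0, np.pi, size=(2, 15))
        fr = ga_smoother(ga_filter(Y_i, np.zeros(2), params), params)
        np.testing.assert_allclose(fr.m_smooth, params.z0_mean, atol=1e-9)

    def test_requires_filter_pass(self):
        from mtssm.filtering import FilterResult

        fr = FilterResult(None, None, None, None, 0.0)
        with pytest.raises(ValueError):
            ga_smoother(fr, uninformative_params())


class TestParticleFilter:
    def test_uninformative_limit_matches_closed_form(self):
        params = uninformative_params()
        rng = np.random.default_rng(5)
        Y_i = rng.uniform(0, np.pi, size=(2, 20))
        exact = float(vonmises_logdensity(Y_i, params.mu1, params.kappa1).sum())
        pl, se = particle_loglik(Y_i, np.zeros(2), params, 5000, seed=11)
        assert abs(pl - exact) <= max(3 * se, 1e-8)

    def test_deterministic_under_seed(self, small_data, small_scenario):
        Y, _ = small_data
        beta = stimuli_equation(small_scenario.design, small_scenario.theta_true)
        a = particle_loglik(Y.angles[0], beta, small_scenario.theta_true, 2000, seed=3)
        b = particle_loglik(Y.angles[0], beta, small_scenario.theta_true, 2000, seed=3)
        assert a == b

    def test_error_scales_with_particle_count(self):
        scen = default_scenario(I=1, J=4, K=2, N=30, seed=23)
        Y, _ = simulate_dataset(scen)
        beta = stimuli_equation(scen.design, scen.theta_true)
        small = [
            particle_loglik(Y.angles[0], beta, scen.theta_true, 1000, seed=s)[0]
            for s in range(16)
        ]
        large = [
            particle_loglik(Y.angles[0], beta, scen.theta_true, 4000, seed=100 + s)[0]
            for s in range(16)
        ]
        ratio = np.std(small) / np.std(large)
        # quadrupling particles should halve the spread, within MC noise
        assert 1.2 < ratio < 3.5

    def test_minimum_particle_count(self):
        with pytest.raises(ValueError):
            particle_loglik(np.full((1, 3), 1.0), np.zeros(1), uninformative_params(), 10, 0)


class TestFilterTrace:
    def test_trace_frame_columns_and_length(self, small_data, small_scenario):
        from mtssm.model import stimuli_equation

        Y, _ = small_data
        p = small_scenario.theta_true
        beta = stimuli_equation(small_scenario.design, p)
        fr = ga_smoother(ga_filter(Y.angles[0], beta, p), p)
        df = fr.to_frame()
        assert list(df.columns) == ["step", "m_filt", "P_filt", "m_smooth", "P_smooth"]
        assert len(df) == Y.n_steps + 1
        assert df["P_smooth"].notna().all()
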