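"""Cart-pole dynamics, pole rendering, photon likelihood, belief filter."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from lowlight.sensor import NoiseModel, effective_rate
from lowlight.track import (GaussianBelief, PendulumConfig, TrackerConfig,
                            convergence_time, dynamics_jacobian,
                            initialize_belief, mechanical_energy,
                            pendulum_dynamics, photon_loglik, predict_belief,
                            render_pendulum, simulate_pendulum, track,
                            update_belief, weighted_moments)

CFG = PendulumConfig()


class TestDynamics:
    def test_upright_rest_is_equilibrium(self):
        z = pendulum_dynamics([0.0, 0.0, 3.0, 0.0], 0.5, CFG)
        np.testing.assert_allclose(z, [0.0, 0.0, 3.0, 0.0], atol=1e-12)

    def test_energy_conserved_over_ten_seconds(self):
        z = np.array([np.deg2rad(35.0), 0.0, 0.0, 0.0])
        e0 = mechanical_energy(z, CFG)
        for _ in range(100):
            z = pendulum_dynamics(z, 0.1, CFG)
        assert abs(mechanical_energy(z, CFG) - e0) / abs(e0) < 1e-6

    def test_hanging_small_oscillation_period(self):
        """Linearized hanging frequency: omega^2 = g (1 + r) / l; the default
        gravity makes the period exactly 1 s."""
        omega = math.sqrt(CFG.gravity * (1 + CFG.mass_ratio) / CFG.pole_length)
        assert 2 * math.pi / omega == pytest.approx(1.0, abs=1e-12)
        z = np.array([math.pi - 0.02, 0.0, 0.0, 0.0])
        prev = z[0] - math.pi
        crossings = []
        t = 0.0
        for _ in range(2500):
            z = pendulum_dynamics(z, 0.001, CFG)
            t += 0.001
            cur = z[0] - math.pi
            if prev < 0 <= cur:
                crossings.append(t)
            prev = cur
        assert crossings[1] - crossings[0] == pytest.approx(1.0, abs=2e-3)

    def test_momentum_conserved(self):
        """With no external horizontal force the total horizontal momentum
        (cart + bob, per unit cart mass) is constant."""
        def momentum(z):
            a, ad, _, bd = z
            return bd + CFG.mass_ratio * (bd + CFG.pole_length * ad * math.cos(a))
        z = np.array([0.7, 1.0, 0.0, -2.0])
        p0 = momentum(z)
        for _ in range(50):
            z = pendulum_dynamics(z, 0.05, CFG)
        assert momentum(z) == pytest.approx(p0, abs=1e-6)


class TestJacobian:
    def test_small_dt_is_identity(self):
        jac = dynamics_jacobian(np.array([0.4, 0.2, 1.0, -0.5]), 1e-9, CFG)
        np.testing.assert_allclose(jac, np.eye(4), atol=1e-5)

    def test_linear_map_recovered_exactly(self, rng):
        A = rng.normal(size=(4, 4))
        jac = dynamics_jacobian(rng.normal(size=4), 0.1, CFG,
                                fn=lambda z, dt, cfg: A @ z)
        np.testing.assert_allclose(jac, A, atol=1e-8)

    def test_agrees_with_finer_stencil(self):
        z = np.array([0.8, -1.0, 2.0, 0.3])
        coarse = dynamics_jacobian(z, 0.05, CFG, step=1e-5)
        fine = dynamics_jacobian(z, 0.05, CFG, step=1e-7)
        np.testing.assert_allclose(coarse, fine, atol=1e-5)


class TestRendering:
    def test_upright_pole_is_axis_aligned_block(self):
        img = render_pendulum(0.0, 0.0, CFG)
        rows, cols = np.nonzero(img > 0.99)
        assert cols.min() >= 38 and cols.max() <= 40
        assert rows.max() < CFG.pivot_row
        assert img.sum() == pytest.approx(90.0, rel=0.02)

    @pytest.mark.parametrize("alpha", [0.0, 0.6, 1.5, np.pi, 4.0])
    def test_brightness_conserved(self, alpha):
        assert render_pendulum(alpha, 2.0, CFG).sum() == \
            pytest.approx(90.0, rel=0.02)

    def test_full_turn_identical(self):
        a = render_pendulum(1.1, -3.0, CFG)
        b = render_pendulum(1.1 + 2 * np.pi, -3.0, CFG)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestLoglik:
    NOISE = NoiseModel(10.0, 0.3)

    def test_zero_frame(self):
        ll = photon_loglik(np.zeros(CFG.scene_shape), 0.5, 0.0, self.NOISE,
                           CFG, 0.1)
        lam = effective_rate(render_pendulum(0.5, 0.0, CFG), self.NOISE) * 0.1
        assert ll == pytest.approx(-lam.sum(), rel=1e-10)

    def test_matches_poisson_pmf_up_to_constant(self, rng):
        frame = rng.poisson(0.3, CFG.scene_shape)
        poses = [(0.2, 1.0), (2.5, -2.0)]
        lls = [photon_loglik(frame, a, b, self.NOISE, CFG, 0.1)
               for a, b in poses]
        pmfs = []
        for a, b in poses:
            lam = effective_rate(render_pendulum(a, b, CFG),
                                 self.NOISE).ravel() * 0.1
            pmfs.append(poisson.logpmf(frame.ravel(), lam).sum())
        # the X-dependent log-factorial constant cancels in differences
        assert lls[0] - lls[1] == pytest.approx(pmfs[0] - pmfs[1], abs=1e-8)

    def test_maximized_at_true_pose(self, rng):
        true_a, true_b = 0.9, 3.0
        lam = effective_rate(render_pendulum(true_a, true_b, CFG), self.NOISE)
        frame = rng.poisson(lam * 5.0)                   # high exposure
        grid_a = true_a + np.arange(24) * 2 * np.pi / 24   # includes truth
        grid_b = true_b + np.linspace(-6, 6, 9)
        aa, bb = np.meshgrid(grid_a, grid_b, indexing="ij")
        ll = photon_loglik(frame, aa.ravel(), bb.ravel(), self.NOISE, CFG, 5.0)
        best = np.argmax(ll)
        assert aa.ravel()[best] == true_a and bb.ravel()[best] == true_b


class TestBelief:
    def test_zero_covariance_propagates_mean_only(self):
        mu = np.array([0.3, 0.0, 1.0, 0.0])
        out = predict_belief(GaussianBelief(mu, np.zeros((4, 4))), 0.05, CFG)
        np.testing.assert_allclose(out.mu, pendulum_dynamics(mu, 0.05, CFG))
        np.testing.assert_allclose(out.sigma, 0.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_predicted_covariance_psd(self, seed):
        gen = np.random.default_rng(seed)
        a = gen.normal(size=(4, 4))
        sigma = a @ a.T * 0.01
        mu = gen.normal(size=4) * np.array([1.0, 2.0, 3.0, 3.0])
        out = predict_belief(GaussianBelief(mu, sigma), 0.05, CFG,
                             process_noise=0.0)
        assert np.linalg.eigvalsh(out.sigma).min() >= -1e-10

    def test_uniform_weights_match_textbook_formula(self, rng):
        samples = rng.normal(size=(50, 4))
        w = np.full(50, 1.0 / 50)
        mu, sigma, degenerate = weighted_moments(samples, w)
        assert not degenerate
        np.testing.assert_allclose(mu, samples.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sigma, np.cov(samples.T, ddof=1),
                                   atol=1e-10)

    def test_one_hot_weight_is_degenerate(self, rng):
        samples = rng.normal(size=(10, 4))
        w = np.zeros(10)
        w[3] = 1.0
        mu, sigma, degenerate = weighted_moments(samples, w)
        assert degenerate and sigma is None
        np.testing.assert_allclose(mu, samples[3])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_moments_match_brute_force(self, seed):
        gen = np.random.default_rng(seed)
        samples = gen.normal(size=(30, 4))
        w = gen.random(30)
        w /= w.sum()
        mu, sigma, degenerate = weighted_moments(samples, w)
        mu_bf = sum(w[s] * samples[s] for s in range(30))
        np.testing.assert_allclose(mu, mu_bf, atol=1e-12)
        if not degenerate:
            sig_bf = sum(w[s] * np.outer(samples[s] - mu_bf,
                                         samples[s] - mu_bf)
                         for s in range(30)) / (1.0 - np.sum(w ** 2))
            np.testing.assert_allclose(sigma, sig_bf, atol=1e-12)

    def test_weight_validation(self, rng):
        with pytest.raises(ValueError):
            weighted_moments(rng.normal(size=(5, 4)), np.full(5, 0.5))

    def test_degenerate_update_falls_back(self, rng):
        """A frame that annihilates every sample weight (bright photons on
        dark pixels at zero dark current) keeps the predictive belief."""
        noise = NoiseModel(5.0, 0.0)
        pred = GaussianBelief(np.array([np.pi, 0.0, 0.0, 0.0]),
                              np.diag([1e-6, 1e-6, 1e-6, 1e-6]))
        frame = np.zeros(CFG.scene_shape)
        frame[0, 0] = 5.0       # impossible photon under every sampled pose
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = update_belief(pred, frame, noise, CFG, 0.1, rng, K=50)
        assert out is pred


def test_sampled_update_matches_kalman_closed_form(rng):
    """With a linear-Gaussian observation the weighted-sample moment match
    converges to the exact Kalman update (K = 10^4)."""
    mu = np.array([0.5, -0.2, 1.0, 0.3])
    a = rng.normal(size=(4, 4))
    sigma = a @ a.T * 0.1
    H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
    R = np.diag([0.05, 0.08])
    obs = np.array([0.7, 0.8])
    # closed form
    Sk = H @ sigma @ H.T + R
    K = sigma @ H.T @ np.linalg.inv(Sk)
    mu_kf = mu + K @ (obs - H @ mu)
    sig_kf = (np.eye(4) - K @ H) @ sigma
    # weighted-sample route through the module's moment matching
    samples = rng.multivariate_normal(mu, sigma, size=10_000)
    innov = obs - samples @ H.T
    logw = -0.5 * np.einsum("ni,ij,nj->n", innov, np.linalg.inv(R), innov)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mu_s, sig_s, degenerate = weighted_moments(samples, w)
    assert not degenerate
    np.testing.assert_allclose(mu_s, mu_kf, atol=0.03)
    np.testing.assert_allclose(sig_s, sig_kf, atol=0.03)


class TestTracking:
    def test_bright_regime_converges_quickly(self):
        """At high SNR the angle estimate is within a degree inside 0.5 s."""
        noise = NoiseModel(100.0, 0.01)
        rng = np.random.default_rng(11)
        z0 = np.array([np.deg2rad(25.0), 0.0, 0.0, 0.0])
        states, frames = simulate_pendulum(z0, 50, 0.01, CFG, noise, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = track(frames, 0.01, noise, CFG, TrackerConfig(K=1000),
                        rng, true_states=states)
        assert res["alpha_err_deg"][-10:].mean() < 1.0

    def test_reproducible_under_seed(self):
        noise = NoiseModel(20.0, 0.1)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            z0 = np.array([0.3, 0.0, 0.0, 0.0])
            states, frames = simulate_pendulum(z0, 10, 0.02, CFG, noise, rng)
            res = track(frames, 0.02, noise, CFG, TrackerConfig(K=200),
                        rng, true_states=states)
            outs.append(res["alpha_err_deg"])
        np.testing.assert_array_equal(outs[0], outs[1])


class TestConvergenceTime:
    TIMES = np.array([0.1, 0.2, 0.3, 0.4])

    def test_always_within_tolerance(self):
        assert convergence_time(np.zeros(4), self.TIMES, 0.5) == 0.1

    def test_never_within_tolerance(self):
        assert convergence_time(np.full(4, 9.0), self.TIMES, 0.5) == np.inf

    def test_remain_vs_first(self):
        err = np.array([0.1, 5.0, 0.2, 0.2])
        assert convergence_time(err, self.TIMES, 0.5, mode="first") == 0.1
        assert convergence_time(err, self.TIMES, 0.5, mode="remain") == 0.3

    def test_excursion_at_end_never_converges(self):
        err = np.array([0.1, 0.1, 0.1, 5.0])
        assert convergence_time(err, self.TIMES, 0.5) == np.inf

    def test_rejects_bad_tolerance(self):
        with pytest.raises(ValueError):
            convergence_time(np.zeros(3), self.TIMES[:3], 0.0)
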