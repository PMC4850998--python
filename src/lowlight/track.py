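"""Tracking a moving object from photon streams.

The test system is an uncontrolled inverted pendulum: a point mass on a
massless pole of length ``l`` (pixels), hinged on a cart that slides
frictionlessly in 1-D.  The state is ``Z = (alpha, alpha_dot, beta,
beta_dot)`` — pole angle from upright (radians, counter-clockwise positive),
its angular velocity, cart offset (pixels) and cart velocity.  Only the pole
is bright (intensity 1); everything else is dark, so each photon frame is a
Poisson sample of the rendered pole plus dark current.

The tracker is a Gaussian-belief filter, a hybrid of the extended Kalman
filter and a weighted-sample particle update:

1. *predict* — push the belief mean through the deterministic dynamics and
   the covariance through the dynamics Jacobian (linearization);
2. *update* — draw K samples from the predictive Gaussian, weight each by
   the Poisson photon likelihood of the new frame, and moment-match a
   Gaussian to the weighted sample cloud (unbiased weighted covariance with
   denominator ``1 - sum W_s^2``).

With no process-noise floor (the default) the covariance can collapse over
long runs and the filter may diverge — a deliberate property of the plain
linearized recursion that the experiments retain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import rect_coverage_batch
from .sensor import NoiseModel, effective_rate

__all__ = [
    "PendulumConfig",
    "TrackerConfig",
    "GaussianBelief",
    "pendulum_dynamics",
    "dynamics_jacobian",
    "render_pendulum",
    "photon_loglik",
    "predict_belief",
    "update_belief",
    "weighted_moments",
    "simulate_pendulum",
    "initialize_belief",
    "track",
    "convergence_time",
    "mechanical_energy",
]


@dataclass(frozen=True)
class PendulumConfig:
    """Geometry and physics of the pendulum scene.

    The pole is a 3x30-pixel bright bar in an 80x80 scene; the pendulum bob
    carries half the cart's mass.  Gravity defaults to the value that gives
    the hanging pendulum a 1-second small-oscillation period,
    ``g = l (2 pi)^2 / (1 + mass_ratio)``; time is in seconds, lengths in
    pixels.
    """

    scene_shape: tuple = (80, 80)
    pole_length: float = 30.0
    pole_width: float = 3.0
    mass_ratio: float = 0.5          # pendulum mass / cart mass
    gravity: float | None = None
    integration_step: float = 0.002
    pivot_row: float = 44.0

    def __post_init__(self) -> None:
        if self.gravity is None:
            g = self.pole_length * (2.0 * math.pi) ** 2 / (1.0 + self.mass_ratio)
            object.__setattr__(self, "gravity", g)
        if self.pole_length <= 0 or self.pole_width <= 0:
            raise ValueError("pole dimensions must be positive")
        if self.integration_step <= 0:
            raise ValueError("integration step must be positive")

    def pivot(self, beta: float) -> tuple:
        return (self.pivot_row, (self.scene_shape[1] - 1) / 2.0 + beta)


@dataclass
class GaussianBelief:
    """Multivariate normal belief over the pendulum state."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(4)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(4, 4)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-8:
            raise ValueError("covariance must be positive semidefinite")


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _accelerations(z: np.ndarray, config: PendulumConfig) -> np.ndarray:
    """Time derivative of the state for the frictionless, unforced cart-pole.

    From the Euler-Lagrange equations of a point mass m on a massless pole
    (cart mass M, r = m/M):

        (M+m) beta_dd + m l (alpha_dd cos a - alpha_d^2 sin a) = 0
        l alpha_dd + beta_dd cos a - g sin a = 0

    solved for (alpha_dd, beta_dd); upright (alpha = 0) is an equilibrium.
    """
    a, ad, _, bd = z
    r = config.mass_ratio                 # m / M
    g, l = config.gravity, config.pole_length
    sin, cos = math.sin(a), math.cos(a)
    det = l * (1.0 + r * sin * sin)       # both equations divided through by M
    alpha_dd = sin * ((1.0 + r) * g - r * l * ad * ad * cos) / det
    beta_dd = r * l * sin * (l * ad * ad - g * cos) / det
    return np.array([ad, alpha_dd, bd, beta_dd])


def pendulum_dynamics(z, dt: float, config: PendulumConfig) -> np.ndarray:
    """Advance the state by ``dt`` seconds (classic 4th-order Runge-Kutta,
    fixed substeps no longer than ``config.integration_step``)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = np.asarray(z, dtype=float).reshape(4)
    n_sub = max(1, int(math.ceil(dt / config.integration_step)))
    h = dt / n_sub
    for _ in range(n_sub):
        k1 = _accelerations(z, config)
        k2 = _accelerations(z + 0.5 * h * k1, config)
        k3 = _accelerations(z + 0.5 * h * k2, config)
        k4 = _accelerations(z + h * k3, config)
        z = z + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return z


def mechanical_energy(z, config: PendulumConfig) -> float:
    """Total mechanical energy per unit cart mass (conserved quantity)."""
    a, ad, _, bd = np.asarray(z, dtype=float).reshape(4)
    r, l, g = config.mass_ratio, config.pole_length, config.gravity
    vbx = bd + l * ad * math.cos(a)      # bob velocity components
    vby = -l * ad * math.sin(a)
    kinetic = 0.5 * bd * bd + 0.5 * r * (vbx * vbx + vby * vby)
    potential = r * g * l * math.cos(a)
    return kinetic + potential


def dynamics_jacobian(z, dt: float, config: PendulumConfig,
                      step: float = 1e-6, fn=None) -> np.ndarray:
    """Jacobian of the ``dt``-step transition map by central differences.

    ``step`` is the per-coordinate perturbation; central differences are
    exact for linear maps and O(step^2) otherwise.  ``fn(z, dt, config)``
    overrides the transition map (defaults to :func:`pendulum_dynamics`).
    """
    fn = pendulum_dynamics if fn is None else fn
    z = np.asarray(z, dtype=float).reshape(4)
    jac = np.empty((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = step
        jac[:, j] = (np.asarray(fn(z + e, dt, config))
                     - np.asarray(fn(z - e, dt, config))) / (2.0 * step)
    return jac


# ---------------------------------------------------------------------------
# rendering and photon likelihood
# ---------------------------------------------------------------------------

def _pole_centers_angles(alphas, betas, config: PendulumConfig):
    """Rectangle centers and raster angles for pole states (vectorized).

    The pole extends from the pivot along the direction ``alpha`` from
    upright (CCW positive), so its center sits half a pole length out; the
    rasterizer measures angles CCW from horizontal, hence ``90 - alpha``.
    """
    alphas = np.asarray(alphas, dtype=float).reshape(-1)
    betas = np.asarray(betas, dtype=float).reshape(-1)
    half = config.pole_length / 2.0
    prow, pcol0 = config.pivot_row, (config.scene_shape[1] - 1) / 2.0
    rows = prow - half * np.cos(alphas)
    cols = pcol0 + betas + half * np.sin(alphas)
    angles = 90.0 - np.rad2deg(alphas)
    return np.stack([rows, cols], axis=1), angles


def render_pendulum(alpha: float, beta: float,
                    config: PendulumConfig) -> np.ndarray:
    """Intensity image of the pole at angle ``alpha`` (radians from upright)
    and cart offset ``beta`` (pixels); anti-aliased, values in [0, 1]."""
    centers, angles = _pole_centers_angles([alpha], [beta], config)
    return rect_coverage_batch(config.scene_shape, centers, angles,
                               config.pole_length, config.pole_width)[0]


def photon_loglik(frame, alpha, beta, noise: NoiseModel,
                  config: PendulumConfig, delta_t: float):
    """Poisson log-likelihood of a photon frame given pole pose(s).

    ``log P(X | alpha, beta) = sum_i X_i log(lambda_i dt) - sum_i lambda_i dt``
    up to the ``log X_i!`` constant.  ``alpha``/``beta`` may be arrays (one
    log-likelihood per pose).  With zero dark current a bright photon on a
    dark pixel yields ``-inf``.
    """
    frame2d = np.asarray(frame, dtype=float)
    h, w = config.scene_shape
    alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
    betas = np.atleast_1d(np.asarray(beta, dtype=float))
    out = np.empty(len(alphas))
    lam_dark = noise.lambda_max * noise.eps_dc / (1.0 + noise.eps_dc) * delta_t
    x_total = frame2d.sum()
    chunk = 250
    for s in range(0, len(alphas), chunk):
        centers, angles = _pole_centers_angles(alphas[s:s + chunk],
                                               betas[s:s + chunk], config)
        # outside the union bounding box of the poles the rate is the flat
        # dark-current rate, handled in closed form
        half = (config.pole_length + config.pole_width) / 2.0 + 1.0
        r0 = max(0, int(np.floor(centers[:, 0].min() - half)))
        r1 = min(h, int(np.ceil(centers[:, 0].max() + half)) + 1)
        c0 = max(0, int(np.floor(centers[:, 1].min() - half)))
        c1 = min(w, int(np.ceil(centers[:, 1].max() + half)) + 1)
        sub_centers = centers - np.array([r0, c0])
        cov = rect_coverage_batch((r1 - r0, c1 - c0), sub_centers, angles,
                                  config.pole_length, config.pole_width)
        lam = effective_rate(cov.reshape(len(cov), -1), noise) * delta_t
        x_sub = frame2d[r0:r1, c0:c1].ravel()
        nz = np.nonzero(x_sub)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            xlog = (x_sub[nz] * np.log(lam[:, nz])).sum(axis=1)
            xlog[np.isnan(xlog)] = -np.inf
        n_out = h * w - (r1 - r0) * (c1 - c0)
        x_out = x_total - x_sub.sum()
        with np.errstate(divide="ignore"):
            tail = (x_out * np.log(lam_dark) if x_out > 0 else 0.0) \
                - n_out * lam_dark
        out[s:s + chunk] = xlog - lam.sum(axis=1) + tail
    return out if np.ndim(alpha) or np.ndim(beta) else float(out[0])


# ---------------------------------------------------------------------------
# belief recursion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackerConfig:
    """Filter settings: sample count K, optional process-noise floor
    (variance added to the predicted covariance diagonal; 0 reproduces the
    plain linearized recursion), and the multi-start initialization grid."""

    K: int = 1000
    process_noise: float = 0.0
    n_init_starts: int = 12
    init_sigma: tuple = (0.12, 1.0, 4.0, 4.0)   # std dev per state component

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.process_noise < 0:
            raise ValueError("process noise must be >= 0")


def predict_belief(belief: GaussianBelief, dt: float, config: PendulumConfig,
                   process_noise: float = 0.0) -> GaussianBelief:
    """Linearized propagation: mean through the dynamics, covariance through
    the Jacobian (``J Sigma J^T`` plus an optional diagonal floor)."""
    mu = pendulum_dynamics(belief.mu, dt, config)
    jac = dynamics_jacobian(belief.mu, dt, config)
    sigma = jac @ belief.sigma @ jac.T + process_noise * np.eye(4)
    return GaussianBelief(mu, _psd_project(sigma))


def _psd_project(sigma: np.ndarray) -> np.ndarray:
    sigma = 0.5 * (sigma + sigma.T)
    vals, vecs = np.linalg.eigh(sigma)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


def weighted_moments(samples: np.ndarray, weights: np.ndarray):
    """Mean and unbiased weighted covariance of a weighted sample set.

    ``mu = sum_s W_s Z_s``; ``Sigma = sum_s W_s (Z_s - mu)(Z_s - mu)^T /
    (1 - sum_s W_s^2)``.  Weights must be normalized.  Returns
    ``(mu, Sigma, degenerate)`` where ``degenerate`` flags an effective
    sample size of one (denominator ~ 0), in which case ``Sigma`` is None.
    """
    weights = np.asarray(weights, dtype=float)
    samples = np.asarray(samples, dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    mu = weights @ samples
    denom = 1.0 - float(weights @ weights)
    if denom < 1e-12:
        return mu, None, True
    diff = samples - mu
    sigma = (diff * weights[:, None]).T @ diff / denom
    return mu, sigma, False


def update_belief(predictive: GaussianBelief, frame, noise: NoiseModel,
                  config: PendulumConfig, delta_t: float,
                  rng: np.random.Generator, K: int = 1000) -> GaussianBelief:
    """Weighted-sample measurement update.

    Draws K samples from the predictive Gaussian, weights them by the photon
    likelihood of the frame (uniform state prior; weights normalized in log
    space), and moment-matches.  If every weight underflows, or the weights
    collapse onto a single sample, the predictive belief is returned
    unchanged and a degeneracy warning is issued.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    samples = rng.multivariate_normal(predictive.mu, predictive.sigma, size=K,
                                      method="eigh")
    logw = photon_loglik(frame, samples[:, 0], samples[:, 2], noise, config,
                         delta_t)
    finite = np.isfinite(logw)
    if not finite.any():
        warnings.warn("degenerate update: all weights vanished; "
                      "keeping predictive belief", RuntimeWarning)
        return predictive
    logw = logw - logw[finite].max()
    w = np.where(finite, np.exp(np.where(finite, logw, -np.inf)), 0.0)
    w = w / w.sum()
    mu, sigma, degenerate = weighted_moments(samples, w)
    if degenerate:
        warnings.warn("degenerate update: effective sample size 1; "
                      "keeping predictive belief", RuntimeWarning)
        return predictive
    return GaussianBelief(mu, _psd_project(sigma))


# ---------------------------------------------------------------------------
# simulation and the tracking loop
# ---------------------------------------------------------------------------

def simulate_pendulum(z0, n_frames: int, delta_t: float,
                      config: PendulumConfig, noise: NoiseModel,
                      rng: np.random.Generator):
    """Ground-truth trajectory and its photon stream.

    Returns ``(states, frames)``: states (n_frames+1, 4) including the
    initial state, frames (n_frames, H, W) where frame ``t`` is the Poisson
    readout of the scene rendered at state ``t+1`` (the pose at the end of
    the exposure interval; exposures are short relative to the dynamics).
    """
    z = np.asarray(z0, dtype=float).reshape(4)
    states = [z.copy()]
    frames = np.empty((n_frames,) + tuple(config.scene_shape))
    for t in range(n_frames):
        z = pendulum_dynamics(z, delta_t, config)
        states.append(z.copy())
        lam = effective_rate(render_pendulum(z[0], z[2], config), noise)
        frames[t] = rng.poisson(lam * delta_t)
    return np.asarray(states), frames


def initialize_belief(first_frame, noise: NoiseModel, config: PendulumConfig,
                      tracker: TrackerConfig, delta_t: float,
                      rng: np.random.Generator) -> GaussianBelief:
    """Multi-start initialization for the uniform-angle prior.

    A uniform prior on a circle has no Gaussian representation, so candidate
    beliefs are seeded on an angle grid over [0, 2 pi) with wide covariance;
    each candidate is updated with the first frame and the one with the
    highest marginal likelihood (log-sum-exp of its sample weights) wins.
    """
    sig0 = np.diag(np.square(tracker.init_sigma))
    best, best_score = None, -np.inf
    for a0 in np.arange(tracker.n_init_starts) * 2.0 * np.pi / tracker.n_init_starts:
        mu0 = np.array([a0, 0.0, 0.0, 0.0])
        samples = rng.multivariate_normal(mu0, sig0, size=tracker.K,
                                          method="eigh")
        logw = photon_loglik(first_frame, samples[:, 0], samples[:, 2],
                             noise, config, delta_t)
        finite = np.isfinite(logw)
        if not finite.any():
            continue
        mx = logw[finite].max()
        score = mx + np.log(np.exp(logw[finite] - mx).sum() / tracker.K)
        if score > best_score:
            w = np.where(finite, np.exp(np.where(finite, logw - mx, -np.inf)), 0.0)
            w = w / w.sum()
            mu, sigma, degenerate = weighted_moments(samples, w)
            if not degenerate:
                best, best_score = GaussianBelief(mu, _psd_project(sigma)), score
    if best is None:
        return GaussianBelief(np.zeros(4), sig0)
    return best


def _wrap_angle(a):
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def track(frames, delta_t: float, noise: NoiseModel, config: PendulumConfig,
          tracker: TrackerConfig, rng: np.random.Generator,
          init_belief: GaussianBelief | None = None, true_states=None):
    """Run the predict/update recursion over a photon stream.

    ``frames``: (T, H, W) photon frames; ``true_states``: optional
    (T+1, 4) ground truth aligned as produced by :func:`simulate_pendulum`.
    Returns a dict with the belief trajectory and, when truth is given,
    per-frame absolute angle error (degrees, wrapped to [0, 180]) and cart
    error (pixels).
    """
    frames = np.asarray(frames, dtype=float)
    if init_belief is None:
        belief = initialize_belief(frames[0], noise, config, tracker,
                                   delta_t, rng)
    else:
        belief = init_belief
    beliefs = [belief]
    for t in range(1, len(frames)):
        pred = predict_belief(belief, delta_t, config,
                              process_noise=tracker.process_noise)
        belief = update_belief(pred, frames[t], noise, config, delta_t, rng,
                               K=tracker.K)
        beliefs.append(belief)
    out = {"beliefs": beliefs,
           "times": delta_t * np.arange(1, len(frames) + 1)}
    if true_states is not None:
        true_states = np.asarray(true_states, dtype=float)
        mus = np.stack([b.mu for b in beliefs])
        out["alpha_err_deg"] = np.abs(np.rad2deg(
            _wrap_angle(mus[:, 0] - true_states[1:len(frames) + 1, 0])))
        out["beta_err_px"] = np.abs(mus[:, 2] - true_states[1:len(frames) + 1, 2])
    return out


def convergence_time(alpha_err_deg, times, tolerance_deg: float,
                     mode: str = "remain") -> float:
    """First time the angle error enters the tolerance band.

    ``mode="remain"`` (default) requires the error to stay within tolerance
    for the rest of the trial; ``mode="first"`` only that it reaches it.
    Returns ``inf`` if the tolerance is never satisfied.
    """
    if tolerance_deg <= 0:
        raise ValueError("tolerance must be positive")
    err = np.asarray(alpha_err_deg, dtype=float)
    times = np.asarray(times, dtype=float)
    ok = err <= tolerance_deg
    if mode == "first":
        idx = np.nonzero(ok)[0]
        return float(times[idx[0]]) if len(idx) else float("inf")
    if mode != "remain":
        raise ValueError("mode must be 'remain' or 'first'")
    # last index where the error is out of tolerance
    bad = np.nonzero(~ok)[0]
    if len(bad) == 0:
        return float(times[0]) if len(times) else 0.0
    if bad[-1] == len(err) - 1:
        return float("inf")
    return float(times[bad[-1] + 1])
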