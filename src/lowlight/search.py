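"""Bayesian visual search from photon streams.

A display has ``L`` non-overlapping windows; ``M`` of them contain an
oriented bar (one may be the target, orientation ``y_T``; the rest are
distractors at ``y_D``), the others are empty.  The task is the binary
decision "is a target present?" (``C = 1``) from the per-window photon
counts, while the scene properties ``phi = (M, y_T, y_D)`` may themselves be
unknown and carry a prior.

Inference composes *local* per-window orientation posteriors
``f_y = P(Y(l)=y | X(l))`` into a global log-likelihood ratio

    S(t) = log [ (1/L) * sum_{l,phi} R(l,phi) P(phi | X) ],

where ``R(l,phi)`` is the local target-vs-no-target evidence ratio and the
scene-property posterior ``P(phi | X)`` is accumulated across windows.  A
two-threshold sequential test on ``S(t)`` (declare present above ``theta1``,
absent below ``theta0``) controls false-accept and false-reject rates
separately while stopping as early as the photons allow.

The local classifiers here are exact Poisson template posteriors; a trained
sequential classifier (see :mod:`lowlight.classify`) can be dropped in via
the same log-posterior interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .raster import rect_coverage
from .sensor import NoiseModel, effective_rate, sample_stream

__all__ = [
    "SearchSceneConfig",
    "BarScene",
    "SearchPosteriorState",
    "SearchDecision",
    "standard_search_config",
    "render_bar_window",
    "generate_scene",
    "sample_scene_streams",
    "local_log_posteriors",
    "scene_posterior",
    "local_ratio",
    "global_llr",
    "init_search_state",
    "update_search_state",
    "sprt_search",
    "llr_from_counts",
    "simulate_llr_trajectories",
    "write_scene_image",
    "operating_point",
    "search_er_ppp",
]

EMPTY = None  # the "no bar in this window" hypothesis


# ---------------------------------------------------------------------------
# configuration and scene generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSceneConfig:
    """Search display geometry, scene-property prior, and noise.

    ``phi_support`` lists admissible ``(M, y_T, y_D)`` triples with prior
    weights ``phi_prior``; ``hypotheses`` is the per-window content space
    ``[EMPTY, orientation_1, ...]`` (degrees).  ``local_prior`` selects the
    prior the local classifiers use over that space: "uniform" (default;
    makes the global composition an exact Bayes computation under the
    independent-window model) or "marginal" (the generative marginal
    ``P(Y(l)=y)``).
    """

    L: int = 14
    window: int = 7
    bar_length: float = 7.0
    bar_width: float = 3.0
    phi_support: tuple = ((12, 90.0, 70.0),)
    phi_prior: tuple = (1.0,)
    p_target: float = 0.5
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(3.0, 0.5))
    delta_t: float = 1.0 / 30.0
    local_prior: str = "uniform"

    def __post_init__(self) -> None:
        if len(self.phi_support) != len(self.phi_prior):
            raise ValueError("phi prior/support length mismatch")
        if not np.isclose(sum(self.phi_prior), 1.0):
            raise ValueError("phi prior must sum to 1")
        for m, y_t, y_d in self.phi_support:
            if not (1 <= m <= self.L):
                raise ValueError(f"M={m} must be in 1..L={self.L}")
            if y_t == y_d:
                raise ValueError("target and distractor orientations must differ")
        if not (0.0 < self.p_target < 1.0):
            raise ValueError("p_target must be in (0, 1)")
        if self.local_prior not in ("uniform", "marginal"):
            raise ValueError("local_prior must be 'uniform' or 'marginal'")

    @property
    def hypotheses(self) -> list:
        ys = sorted({y for _, y_t, y_d in self.phi_support for y in (y_t, y_d)})
        return [EMPTY] + ys

    def hypothesis_index(self, y) -> int:
        return self.hypotheses.index(y)

    def cond_no_target(self, phi) -> np.ndarray:
        """``P(Y(l)=y | phi, C(l)=0)`` over the hypothesis list."""
        m, _, y_d = phi
        p = np.zeros(len(self.hypotheses))
        p[0] = (self.L - m) / self.L
        p[self.hypothesis_index(y_d)] = m / self.L
        return p

    def cond_target(self, phi) -> np.ndarray:
        """``P(Y(l)=y | phi, C(l)=1)``: a point mass on ``y_T``."""
        p = np.zeros(len(self.hypotheses))
        p[self.hypothesis_index(phi[1])] = 1.0
        return p

    def marginal_hypothesis_prior(self) -> np.ndarray:
        """Generative marginal ``P(Y(l)=y)`` under the independence model."""
        p_cl1 = self.p_target / self.L
        out = np.zeros(len(self.hypotheses))
        for phi, w in zip(self.phi_support, self.phi_prior):
            out += w * (p_cl1 * self.cond_target(phi)
                        + (1.0 - p_cl1) * self.cond_no_target(phi))
        return out

    def local_prior_vector(self) -> np.ndarray:
        if self.local_prior == "uniform":
            return np.full(len(self.hypotheses), 1.0 / len(self.hypotheses))
        return self.marginal_hypothesis_prior()


def standard_search_config(M=12, known_m=True, dy=20.0, known_dy=True,
                           lambda_max=3.0, eps_dc=0.5, delta_t=1.0 / 30.0,
                           L=14, p_target=0.5) -> SearchSceneConfig:
    """Oriented-bar search display: L windows of 7x7 px, 3x7 bars, the
    target vertical (90 deg) and distractors rotated by ``dy``.

    ``known_m=False`` puts a uniform prior on M in {3, 6, 12};
    ``known_dy=False`` a uniform prior on dy in {20, 30, 90} degrees.
    """
    m_set = [M] if known_m else [3, 6, 12]
    dy_set = [dy] if known_dy else [20.0, 30.0, 90.0]
    support = tuple((m, 90.0, 90.0 - d) for m, d in product(m_set, dy_set))
    prior = tuple(np.full(len(support), 1.0 / len(support)))
    return SearchSceneConfig(L=L, phi_support=support, phi_prior=prior,
                             p_target=p_target,
                             noise=NoiseModel(lambda_max, eps_dc),
                             delta_t=delta_t)


def render_bar_window(config: SearchSceneConfig, y) -> np.ndarray:
    """Intensity image of one window: an oriented bar, or zeros if empty."""
    w = config.window
    if y is EMPTY:
        return np.zeros((w, w))
    c = (w - 1) / 2.0
    return rect_coverage((w, w), (c, c), float(y),
                         config.bar_length, config.bar_width)


@dataclass(frozen=True)
class BarScene:
    """A sampled display: per-window content and rendered intensities."""

    contents: tuple          # per-location orientation or EMPTY
    target_location: int     # -1 when target absent
    phi: tuple               # true (M, y_T, y_D)
    windows: np.ndarray      # (L, window, window) intensities

    @property
    def c(self) -> int:
        return int(self.target_location >= 0)


def generate_scene(config: SearchSceneConfig, c_true: int,
                   rng: np.random.Generator) -> BarScene:
    """Draw scene properties from the prior and place bars.

    ``M`` locations are occupied uniformly at random; under ``c_true = 1``
    one occupied location (uniformly chosen) holds the target at ``y_T``,
    the rest hold distractors at ``y_D``.  At most one target ever appears.
    """
    phi_idx = rng.choice(len(config.phi_support), p=np.asarray(config.phi_prior))
    m, y_t, y_d = config.phi_support[phi_idx]
    occupied = rng.choice(config.L, size=int(m), replace=False)
    contents = [EMPTY] * config.L
    for l in occupied:
        contents[l] = y_d
    target_loc = -1
    if c_true:
        target_loc = int(rng.choice(occupied))
        contents[target_loc] = y_t
    windows = np.stack([render_bar_window(config, y) for y in contents])
    return BarScene(tuple(contents), target_loc, (int(m), y_t, y_d), windows)


def sample_scene_streams(scene: BarScene, config: SearchSceneConfig,
                         n_frames: int, rng: np.random.Generator) -> list:
    """One photon stream per display window (shared ``delta_t``)."""
    return [sample_stream(scene.windows[l], config.noise, config.delta_t,
                          n_frames, int(rng.integers(0, 2**31 - 1)))
            for l in range(config.L)]


# ---------------------------------------------------------------------------
# inference: Eq. composition of local posteriors
# ---------------------------------------------------------------------------

def _hypothesis_rates(config: SearchSceneConfig) -> np.ndarray:
    """Per-hypothesis photon rate maps, flattened: (H, window**2)."""
    return np.stack([
        effective_rate(render_bar_window(config, y), config.noise).ravel()
        for y in config.hypotheses])


def local_log_posteriors(S, duration: float,
                         config: SearchSceneConfig) -> np.ndarray:
    """Log of ``f_y(X(l))``: exact per-window Poisson-template posteriors.

    ``S``: per-window cumulative counts, shape (L, window, window) or
    (L, window**2); ``duration`` the elapsed exposure in seconds.  With no
    photons observed at ``duration = 0`` the posterior equals the local
    hypothesis prior.  Rows are log-normalized.
    """
    rates = _hypothesis_rates(config)
    S = np.asarray(S, dtype=float).reshape(-1, rates.shape[1])
    logq = np.log(config.local_prior_vector())
    ll = logq + S @ np.log(rates).T - duration * rates.sum(axis=1)
    return ll - _logsumexp(ll, axis=-1, keepdims=True)


def _logsumexp(a, axis=None, keepdims=False):
    amax = np.max(a, axis=axis, keepdims=True)
    out = amax + np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


def scene_posterior(log_f: np.ndarray, config: SearchSceneConfig) -> np.ndarray:
    """Posterior over scene properties ``phi`` given all windows.

    ``P(phi | X) ∝ P(phi) prod_l sum_y f_y(X(l)) P(Y(l)=y | phi, C(l)=0)
    / P(Y(l)=y)``, with the same prior the local classifiers used in the
    denominator, so the product reduces to the no-target likelihood of each
    window.  Raises if every ``phi`` has zero mass (degenerate evidence).
    """
    logq = np.log(config.local_prior_vector())
    log_post = np.empty(len(config.phi_support))
    for i, phi in enumerate(config.phi_support):
        cond = config.cond_no_target(phi)
        with np.errstate(divide="ignore"):
            term = log_f + np.log(cond) - logq
        log_post[i] = np.log(config.phi_prior[i]) + \
            _logsumexp(term, axis=-1).sum()
    if np.all(np.isneginf(log_post)):
        raise ValueError("degenerate configuration: zero mass on every phi")
    return np.exp(log_post - _logsumexp(log_post))


def local_ratio(l: int, phi, log_f: np.ndarray,
                config: SearchSceneConfig) -> float:
    """Local evidence ratio ``R(l, phi)``: the f-weighted odds that window
    ``l`` holds the target rather than generic no-target content."""
    f = np.exp(log_f[l])
    num = float(f @ config.cond_target(phi))
    den = float(f @ config.cond_no_target(phi))
    if den <= 0.0:
        raise ValueError("degenerate configuration: zero no-target mass")
    return num / den


def global_llr(log_f: np.ndarray, phi_post: np.ndarray,
               config: SearchSceneConfig) -> float:
    """Global log-likelihood ratio
    ``S(t) = log[(1/L) sum_{l,phi} R(l,phi) P(phi|X)]``; 0 before any
    photons when the local posteriors equal their prior."""
    total = 0.0
    for i, phi in enumerate(config.phi_support):
        if phi_post[i] == 0.0:
            continue
        for l in range(config.L):
            total += local_ratio(l, phi, log_f, config) * phi_post[i]
    return float(np.log(total / config.L))


# ---------------------------------------------------------------------------
# sequential decision
# ---------------------------------------------------------------------------

@dataclass
class SearchPosteriorState:
    """Running sufficient statistics of the search inference."""

    config: SearchSceneConfig
    t: int
    S_counts: np.ndarray       # (L, npx) cumulative photon counts
    log_f: np.ndarray          # (L, H) local log-posteriors
    phi_post: np.ndarray       # posterior over phi_support
    llr: float                 # S(t)


def init_search_state(config: SearchSceneConfig) -> SearchPosteriorState:
    npx = config.window ** 2
    log_f = local_log_posteriors(np.zeros((config.L, npx)), 0.0, config)
    phi_post = scene_posterior(log_f, config)
    return SearchPosteriorState(config, 0, np.zeros((config.L, npx)),
                                log_f, phi_post, global_llr(log_f, phi_post, config))


def update_search_state(state: SearchPosteriorState,
                        frame_counts) -> SearchPosteriorState:
    """Fold one frame (per-window counts, shape (L, window, window)) into the
    local posteriors, then refresh the scene posterior and ``S(t)``."""
    config = state.config
    x = np.asarray(frame_counts, dtype=float).reshape(config.L, -1)
    S = state.S_counts + x
    t = state.t + 1
    log_f = local_log_posteriors(S, t * config.delta_t, config)
    phi_post = scene_posterior(log_f, config)
    return SearchPosteriorState(config, t, S, log_f, phi_post,
                                global_llr(log_f, phi_post, config))


@dataclass(frozen=True)
class SearchDecision:
    """Outcome of a sequential search run."""

    c_hat: int
    stop_frame: int      # -1 for a decision before any frame
    stop_ppp: float
    llr: float
    capped: bool


def _threshold_check(llr: float, theta0: float, theta1: float):
    # ties at the lower threshold resolve to target-absent (deterministic)
    if llr > theta1:
        return 1
    if llr <= theta0:
        return 0
    return None


def sprt_search(streams, theta0: float, theta1: float,
                config: SearchSceneConfig, ppp_cap: float = 50.0) -> SearchDecision:
    """Two-threshold sequential search over per-window photon streams.

    ``streams`` is the list of L per-window :class:`PhotonStream` objects
    (as from :func:`sample_scene_streams`).  Declares ``C=1`` when
    ``S(t) > theta1`` and ``C=0`` when ``S(t) <= theta0``; at the exposure
    cap the sign of ``S`` decides, flagged ``capped``.
    """
    if not (theta0 <= 0.0 <= theta1):
        raise ValueError("need theta0 <= 0 <= theta1")
    state = init_search_state(config)
    verdict = _threshold_check(state.llr, theta0, theta1)
    if verdict is not None:
        return SearchDecision(verdict, -1, 0.0, state.llr, False)
    n_frames = min(len(s) for s in streams)
    lam = config.noise.lambda_max
    for t in range(n_frames):
        frame = np.stack([s.frames[t] for s in streams])
        state = update_search_state(state, frame)
        verdict = _threshold_check(state.llr, theta0, theta1)
        ppp = lam * (t + 1) * config.delta_t
        if verdict is not None:
            return SearchDecision(verdict, t, ppp, state.llr, False)
        if ppp >= ppp_cap:
            break
    return SearchDecision(int(state.llr > 0), t, ppp, state.llr, True)


# ---------------------------------------------------------------------------
# vectorized trial simulation (threshold sweeps share one set of trials)
# ---------------------------------------------------------------------------

class _VectorizedInference:
    """Precomputed tables for lock-step inference across many trials."""

    def __init__(self, config: SearchSceneConfig):
        self.config = config
        self.hyp_rates = _hypothesis_rates(config)          # (H, npx)
        self.log_rates = np.log(self.hyp_rates)
        self.tot_rates = self.hyp_rates.sum(axis=1)
        self.logq = np.log(config.local_prior_vector())
        self.cond0 = np.stack([config.cond_no_target(phi)
                               for phi in config.phi_support])
        self.cond1 = np.stack([config.cond_target(phi)
                               for phi in config.phi_support])
        self.log_phi_prior = np.log(np.asarray(config.phi_prior))
        with np.errstate(divide="ignore"):
            self.log_cond0 = np.log(self.cond0)

    def step(self, loglik: np.ndarray, counts_t: np.ndarray):
        """Fold one frame of counts (n, L, npx) into the running local
        log-likelihoods (n, L, H); returns (new loglik, S values (n,))."""
        cfg = self.config
        loglik = loglik + np.einsum("nlp,hp->nlh", counts_t, self.log_rates) \
            - cfg.delta_t * self.tot_rates
        lf = self.logq + loglik
        lf = lf - _logsumexp(lf, axis=-1, keepdims=True)
        # phi posterior: sum over windows of log sum_y exp(lf + log c0 - logq)
        term = lf[:, :, None, :] + self.log_cond0[None, None, :, :] - self.logq
        log_w = _logsumexp(term, axis=-1).sum(axis=1) + self.log_phi_prior
        phi_post = np.exp(log_w - _logsumexp(log_w, axis=-1, keepdims=True))
        f = np.exp(lf)
        num = np.einsum("nlh,ph->nlp", f, self.cond1)
        den = np.einsum("nlh,ph->nlp", f, self.cond0)
        ratio = (num / den).sum(axis=1)                    # (n, nphi)
        return loglik, np.log((ratio * phi_post).sum(axis=1) / cfg.L)


def llr_from_counts(config: SearchSceneConfig, counts: np.ndarray) -> np.ndarray:
    """``S(t)`` trajectories from pre-drawn per-frame window counts.

    ``counts`` has shape (n_trials, n_frames, L, window**2).  The per-frame
    math is identical to :func:`update_search_state`, vectorized across
    trials (a test pins the equivalence).
    """
    counts = np.asarray(counts, dtype=float)
    n_trials, n_frames = counts.shape[:2]
    counts = counts.reshape(n_trials, n_frames, config.L, -1)
    inf = _VectorizedInference(config)
    loglik = np.zeros((n_trials, config.L, len(config.hypotheses)))
    out = np.empty((n_trials, n_frames))
    for t in range(n_frames):
        loglik, out[:, t] = inf.step(loglik, counts[:, t])
    return out


def simulate_llr_trajectories(config: SearchSceneConfig, c_true: int,
                              n_trials: int, n_frames: int,
                              rng: np.random.Generator) -> np.ndarray:
    """``S(t)`` trajectories, shape (n_trials, n_frames), for freshly drawn
    scenes with the given ground truth.

    All trials advance frame-by-frame in lock-step with vectorized photon
    sampling and posterior updates, so threshold sweeps can share one set
    of simulated trials.
    """
    hyp_rates = _hypothesis_rates(config)
    scene_idx = np.zeros((n_trials, config.L), dtype=int)
    for i in range(n_trials):
        scene = generate_scene(config, c_true, rng)
        scene_idx[i] = [config.hypothesis_index(y) for y in scene.contents]
    scene_rates = hyp_rates[scene_idx]             # (n, L, npx)
    inf = _VectorizedInference(config)
    loglik = np.zeros((n_trials, config.L, len(config.hypotheses)))
    out = np.empty((n_trials, n_frames))
    for t in range(n_frames):
        counts = rng.poisson(scene_rates * config.delta_t)
        loglik, out[:, t] = inf.step(loglik, counts)
    return out


def _first_crossing(traj: np.ndarray, theta0: float, theta1: float):
    """Stop index and decision per trial from an LLR trajectory.

    Trials that never cross decide by the sign of the final value (capped).
    """
    up = traj > theta1
    down = traj <= theta0
    hit = up | down
    any_hit = hit.any(axis=1)
    t_stop = np.where(any_hit, hit.argmax(axis=1), traj.shape[1] - 1)
    rows = np.arange(len(traj))
    decision = np.where(any_hit, up[rows, t_stop],
                        traj[rows, -1] > 0).astype(int)
    return t_stop, decision, ~any_hit


def operating_point(traj_present: np.ndarray, traj_absent: np.ndarray,
                    config: SearchSceneConfig, target_er: float,
                    theta_grid=None):
    """Locate the symmetric threshold pair achieving ``target_er`` and report
    the median stop-PPP there.

    Sweeps ``theta`` over ``theta_grid`` (thresholds ``(-theta, +theta)``),
    evaluates error rate and median stop-PPP on the shared trajectories, and
    linearly interpolates the median PPP between the two grid points whose
    error rates bracket the target.  Returns a dict with the interpolated
    ``median_ppp`` plus the full sweep table.
    """
    if theta_grid is None:
        theta_grid = np.arange(0.25, 8.01, 0.25)
    lam_dt = config.noise.lambda_max * config.delta_t
    rows = []
    for theta in theta_grid:
        t_p, d_p, _ = _first_crossing(traj_present, -theta, theta)
        t_a, d_a, _ = _first_crossing(traj_absent, -theta, theta)
        errors = np.concatenate([d_p != 1, d_a != 0])
        ppp = np.concatenate([(t_p + 1), (t_a + 1)]) * lam_dt
        rows.append({
            "theta": float(theta),
            "error_rate": float(errors.mean()),
            "fa_rate": float((d_a != 0).mean()),
            "fr_rate": float((d_p != 1).mean()),
            "median_ppp": float(np.median(ppp)),
            "median_ppp_present": float(np.median((t_p + 1) * lam_dt)),
            "median_ppp_absent": float(np.median((t_a + 1) * lam_dt)),
        })
    ers = np.array([r["error_rate"] for r in rows])
    med = np.array([r["median_ppp"] for r in rows])
    below = np.nonzero(ers <= target_er)[0]
    if len(below) == 0:
        return {"median_ppp": float("nan"), "theta": float("nan"),
                "rows": rows}
    j = below[0]
    if j == 0 or ers[j] == target_er:
        m, th = med[j], rows[j]["theta"]
    else:
        w = (ers[j - 1] - target_er) / (ers[j - 1] - ers[j])
        m = med[j - 1] + w * (med[j] - med[j - 1])
        th = rows[j - 1]["theta"] + w * (rows[j]["theta"] - rows[j - 1]["theta"])
    return {"median_ppp": float(m), "theta": float(th), "rows": rows}


def scene_image(scene: BarScene, config: SearchSceneConfig,
                n_cols: int = 7, gap: int = 2):
    """Tile the display windows into one intensity image.

    Returns ``(image, bounds)`` where ``bounds[l] = (row0, col0, row1,
    col1)`` locates window ``l`` (half-open pixel ranges).
    """
    w = config.window
    n_rows = int(np.ceil(config.L / n_cols))
    img = np.zeros((n_rows * (w + gap) - gap, n_cols * (w + gap) - gap))
    bounds = []
    for l in range(config.L):
        r0 = (l // n_cols) * (w + gap)
        c0 = (l % n_cols) * (w + gap)
        img[r0:r0 + w, c0:c0 + w] = scene.windows[l]
        bounds.append((r0, c0, r0 + w, c0 + w))
    return img, bounds


def write_scene_image(path, scene: BarScene, config: SearchSceneConfig) -> None:
    """Write the tiled display as PGM/PNG plus a JSON sidecar with the
    window boundaries and true scene properties (``<path>.windows.json``)."""
    import json
    from pathlib import Path

    from .io import write_image

    img, bounds = scene_image(scene, config)
    write_image(path, img)
    sidecar = {"windows": [list(map(int, b)) for b in bounds],
               "target_location": scene.target_location,
               "phi": {"M": scene.phi[0], "y_T": scene.phi[1],
                       "y_D": scene.phi[2]}}
    Path(str(path) + ".windows.json").write_text(json.dumps(sidecar, indent=2))


def search_er_ppp(conditions, n_trials: int, n_frames: int,
                  rng: np.random.Generator, theta_grid=None) -> list:
    """Error-rate / median-PPP curves across scene conditions.

    ``conditions`` maps names to :class:`SearchSceneConfig`; per condition the
    full symmetric-threshold sweep is evaluated on ``n_trials`` balanced
    target-present/absent trials, reporting present and absent stop-PPP
    separately.  Returns rows suitable for a CSV.
    """
    if theta_grid is None:
        theta_grid = np.arange(0.25, 8.01, 0.25)
    out = []
    for name, config in conditions.items():
        tp = simulate_llr_trajectories(config, 1, n_trials // 2, n_frames, rng)
        ta = simulate_llr_trajectories(config, 0, n_trials - n_trials // 2,
                                       n_frames, rng)
        res = operating_point(tp, ta, config, target_er=0.05,
                              theta_grid=theta_grid)
        for r in res["rows"]:
            r = dict(r)
            r["condition"] = name
            r["n_trials"] = n_trials
            out.append(r)
    return out
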