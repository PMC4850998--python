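"""Sequential classification from photon streams.

Two classifier families share one sequential interface:

* :class:`LayeredNet` — a stack of linear stages interleaved with rectified
  group-max pooling and a softmax head, approximating ``P(Y | X_{1:t})`` from
  the cumulative photon counts ``S_t``.  The first stage is linear in ``S_t``
  with a bias that accumulates with the frame index ``t`` (``h = W S_t + b t``),
  which makes the network exposure-aware and lets its state be updated
  incrementally, frame by frame, instead of re-evaluating from scratch.
* :class:`PoissonTemplateClassifier` — the exact Bayes posterior for a finite
  set of known intensity templates under the Poisson imaging model; used as
  an oracle and for stimuli whose generative model is known.

Either classifier can drive the sequential probability ratio test
(:func:`sprt_classify`): photons are accumulated until the posterior log-odds
of the leading class exceed a threshold ``theta``, which caps the error rate
at ``1 - sigmoid(theta)`` when the model matches the generative distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sensor import NoiseModel, PhotonStream, effective_rate, sample_stream

__all__ = [
    "Layer",
    "LayeredNet",
    "ClassifierState",
    "TrainConfig",
    "SPRTDecision",
    "PoissonTemplateClassifier",
    "threshold_for_error",
    "make_dense_net",
    "conv_layer",
    "dense_layer",
    "forward",
    "init_state",
    "incremental_update",
    "train",
    "make_training_set",
    "sprt_classify",
    "er_ppp_curve",
    "specialist_classify",
]

DEFAULT_PPP_LEVELS = (0.22, 2.2, 22.0, 220.0)
DEFAULT_PPP_CAP = 220.0
DEFAULT_THETA_SWEEP = (-2.2, 9.2)


def threshold_for_error(gamma: float) -> float:
    """SPRT threshold guaranteeing an error rate of at most ``gamma``.

    Solves ``1 - sigmoid(theta) = gamma``: ``theta = log((1 - gamma)/gamma)``.
    A 10% target gives ``log 9 ≈ 2.2``; 1% gives ``log 99 ≈ 4.6``.
    """
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"target error must be in (0, 1), got {gamma}")
    return float(np.log((1.0 - gamma) / gamma))


def _softmax(z):
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_odds(p: float) -> float:
    if p >= 1.0:
        return np.inf
    if p <= 0.0:
        return -np.inf
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# network definition
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """One linear stage plus its rectified group-max pooling.

    ``groups`` must partition the unit indices; the layer's output has one
    entry per group, ``m_k = max(0, max_{j in G_k} h_j)``.  ``w_tie`` and
    ``b_tie`` optionally tie entries to shared parameters (convolutional
    weight sharing): integer parameter ids per entry, -1 marking structural
    zeros.
    """

    W: np.ndarray
    b: np.ndarray
    groups: list
    w_tie: np.ndarray | None = None
    b_tie: np.ndarray | None = None
    perm: np.ndarray = field(init=False)
    starts: np.ndarray = field(init=False)
    group_of: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.W.shape[0]
        if self.b.shape != (n,):
            raise ValueError("bias shape mismatch")
        groups = [np.asarray(g, dtype=int) for g in self.groups]
        flat = np.concatenate(groups) if groups else np.empty(0, int)
        if len(flat) != n or len(np.unique(flat)) != n:
            raise ValueError("pooling groups must partition the layer's units")
        self.groups = groups
        self.perm = flat
        sizes = np.array([len(g) for g in groups])
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
        self.group_of = np.empty(n, dtype=int)
        for k, g in enumerate(groups):
            self.group_of[g] = k

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    @property
    def n_out(self) -> int:
        return len(self.groups)


@dataclass
class LayeredNet:
    """Linear / pooled stages ending in a softmax over ``n_classes`` outputs."""

    layers: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if b.W.shape[1] != a.n_out:
                raise ValueError("layer input size must match previous pooled output")

    @property
    def n_classes(self) -> int:
        return self.layers[-1].n_out

    @property
    def input_dim(self) -> int:
        return self.layers[0].W.shape[1]

    def posterior_from_cumulative(self, S, t_index, delta_t=None):
        return forward(self, S, t_index)

    def stepper(self, delta_t: float) -> "_NetStepper":
        return _NetStepper(self)


def dense_layer(n_in: int, n_units: int, pool: int, rng: np.random.Generator,
                scale: float = 1.0) -> Layer:
    """Fully-connected layer with non-overlapping pools of size ``pool``."""
    if n_units % pool:
        raise ValueError("pool size must divide the number of units")
    W = rng.normal(0.0, scale / np.sqrt(n_in), size=(n_units, n_in))
    b = np.zeros(n_units)
    groups = [np.arange(k * pool, (k + 1) * pool) for k in range(n_units // pool)]
    return Layer(W, b, groups)


def conv_layer(input_shape, n_filters: int, kernel: int, pool: int,
               rng: np.random.Generator, scale: float = 1.0) -> Layer:
    """Valid convolution with per-filter weight sharing, expanded into a dense
    tied layer, followed by non-overlapping ``pool x pool`` spatial pooling.

    ``input_shape`` is ``(H, W)`` or ``(C, H, W)``; the pooled output is the
    flattened ``(n_filters, H'/pool, W'/pool)`` feature map.
    """
    shape = tuple(input_shape)
    if len(shape) == 2:
        shape = (1,) + shape
    c_in, h_in, w_in = shape
    h_out, w_out = h_in - kernel + 1, w_in - kernel + 1
    if h_out <= 0 or w_out <= 0 or h_out % pool or w_out % pool:
        raise ValueError("kernel/pool incompatible with input shape")
    n_units = n_filters * h_out * w_out
    d = c_in * h_in * w_in
    params = rng.normal(0.0, scale / np.sqrt(c_in * kernel * kernel),
                        size=n_filters * c_in * kernel * kernel)
    W = np.zeros((n_units, d))
    w_tie = np.full((n_units, d), -1, dtype=int)
    unit = 0
    for f in range(n_filters):
        for r in range(h_out):
            for cc in range(w_out):
                for ch in range(c_in):
                    for ki in range(kernel):
                        cols = ch * h_in * w_in + (r + ki) * w_in + cc + np.arange(kernel)
                        pids = (f * c_in + ch) * kernel * kernel + ki * kernel + np.arange(kernel)
                        W[unit, cols] = params[pids]
                        w_tie[unit, cols] = pids
                unit += 1
    b_tie = np.repeat(np.arange(n_filters), h_out * w_out)
    b = np.zeros(n_units)
    groups = []
    for f in range(n_filters):
        base = f * h_out * w_out
        for r in range(0, h_out, pool):
            for cc in range(0, w_out, pool):
                g = [base + (r + i) * w_out + (cc + j)
                     for i in range(pool) for j in range(pool)]
                groups.append(np.array(g))
    return Layer(W, b, groups, w_tie=w_tie, b_tie=b_tie)


def make_dense_net(input_dim: int, specs, rng: np.random.Generator,
                   scale: float = 1.0) -> LayeredNet:
    """Build a dense net from ``specs`` = [(n_units, pool_size), ...].

    The pooled output size of the last spec is the number of classes.
    """
    layers = []
    d = input_dim
    for n_units, pool in specs:
        layer = dense_layer(d, n_units, pool, rng, scale=scale)
        layers.append(layer)
        d = layer.n_out
    return LayeredNet(layers)


# ---------------------------------------------------------------------------
# batch forward pass
# ---------------------------------------------------------------------------

def _pool(layer: Layer, z: np.ndarray):
    """Rectified group-max over the last axis; returns (m, global argmax)."""
    zp = z[..., layer.perm]
    maxv = np.maximum.reduceat(zp, layer.starts, axis=-1)
    sizes = np.diff(np.append(layer.starts, len(layer.perm)))
    mask = zp == np.repeat(maxv, sizes, axis=-1)
    pos = np.where(mask, np.arange(len(layer.perm)), len(layer.perm))
    amax = layer.perm[np.minimum.reduceat(pos, layer.starts, axis=-1)]
    return np.maximum(maxv, 0.0), amax


def _forward_cached(net: LayeredNet, S, t):
    """Forward pass keeping per-layer caches (for training / state init)."""
    S = np.asarray(S, dtype=float)
    t = np.asarray(t, dtype=float)
    caches = []
    a = S
    for li, layer in enumerate(net.layers):
        bias = layer.b * t[..., None] if li == 0 else layer.b
        z = a @ layer.W.T + bias
        m, amax = _pool(layer, z)
        caches.append({"a_in": a, "z": z, "m": m, "amax": amax})
        a = m
    return _softmax(a), caches


def forward(net: LayeredNet, S, t) -> np.ndarray:
    """Class posterior from cumulative counts ``S`` at frame index ``t``.

    ``S`` may be a single vector or a batch ``(B, d)``; ``t`` is a scalar or
    per-example.  The output sums to 1 along the last axis.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != net.input_dim:
        raise ValueError(f"input dim {S.shape[-1]} != net input {net.input_dim}")
    f, _ = _forward_cached(net, S, t)
    return f


# ---------------------------------------------------------------------------
# incremental evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierState:
    """Running activations after ``t`` frames.

    ``h[l]`` are the pre-pool accumulators, ``m[l]`` the rectified pooled
    values and ``amax[l]`` a per-group index attaining the group maximum of
    ``h[l]``.  The state reproduces the batch forward pass on the running
    cumulative counts (up to floating-point summation order).
    """

    t: int
    h: list
    m: list
    amax: list
    posterior: np.ndarray


def init_state(net: LayeredNet) -> ClassifierState:
    f, caches = _forward_cached(net, np.zeros(net.input_dim), 0.0)
    return ClassifierState(
        t=0,
        h=[c["z"].copy() for c in caches],
        m=[c["m"].copy() for c in caches],
        amax=[c["amax"].copy() for c in caches],
        posterior=f,
    )


def _update_pools(layer: Layer, h_new, amax, m, changed_idx, contrib, bias):
    """Refresh pooled maxima after ``h`` changed at ``changed_idx``.

    Uses the sparse rule — candidates are the changed units plus the group's
    previous argmax — whenever it is exact: all updates in the group
    non-negative and any per-frame bias uniform within the group (then the
    unchanged units keep their relative order and cannot overtake the old
    maximum by more than the shared shift).  Groups violating either
    condition are recomputed in full, so the result always equals batch
    pooling.  Returns (m_new, amax_new, indices of groups whose m changed).
    """
    m_new = m.copy()
    amax_new = amax.copy()
    changed_groups = []
    attention = set(np.unique(layer.group_of[changed_idx]).tolist())
    if bias is not None:
        attention.update(k for k, g in enumerate(layer.groups)
                         if np.any(bias[g] != 0.0))
    for k in attention:
        g = layer.groups[k]
        in_g = changed_idx[layer.group_of[changed_idx] == k]
        full = np.any(contrib[in_g] < 0) or (
            bias is not None and np.ptp(bias[g]) != 0.0)
        if full:
            j = g[np.argmax(h_new[g])]
        else:
            cand = np.append(in_g, amax[k])
            j = cand[np.argmax(h_new[cand])]
        amax_new[k] = j
        val = max(0.0, h_new[j])
        if val != m[k]:
            m_new[k] = val
            changed_groups.append(k)
    return m_new, amax_new, np.array(sorted(changed_groups), dtype=int)


def incremental_update(state: ClassifierState, frame_counts,
                       net: LayeredNet) -> ClassifierState:
    """Advance the state by one photon frame.

    Layer-1 accumulators change only at units with support on the frame's
    nonzero pixels (every unit also receives its per-frame bias); deeper
    stages are touched only where their pooled inputs changed.  The
    resulting posterior equals ``forward`` on the running cumulative counts.
    """
    x = np.asarray(frame_counts, dtype=float).ravel()
    layer = net.layers[0]
    if x.shape[0] != layer.W.shape[1]:
        raise ValueError("frame size does not match network input")
    h = list(state.h)
    m = list(state.m)
    amax = list(state.amax)

    nz = np.nonzero(x)[0]
    contrib = layer.W[:, nz] @ x[nz] if len(nz) else np.zeros(layer.n_units)
    h[0] = h[0] + contrib + layer.b
    changed_idx = np.nonzero(contrib)[0]
    m[0], amax[0], dm_idx = _update_pools(
        layer, h[0], amax[0], m[0], changed_idx, contrib, bias=layer.b)

    for li in range(1, len(net.layers)):
        if len(dm_idx) == 0:
            break
        layer = net.layers[li]
        dm = m[li - 1][dm_idx] - state.m[li - 1][dm_idx]
        contrib = layer.W[:, dm_idx] @ dm
        h[li] = h[li] + contrib
        changed_idx = np.nonzero(contrib)[0]
        m[li], amax[li], dm_idx = _update_pools(
            layer, h[li], amax[li], m[li], changed_idx, contrib, bias=None)

    posterior = _softmax(m[-1])
    return ClassifierState(t=state.t + 1, h=h, m=m, amax=amax,
                           posterior=posterior)


class _NetStepper:
    """Frame-by-frame evaluation of a :class:`LayeredNet`."""

    def __init__(self, net: LayeredNet):
        self.net = net
        self.state = init_state(net)

    @property
    def n_classes(self) -> int:
        return self.net.n_classes

    def update(self, frame_counts) -> np.ndarray:
        self.state = incremental_update(self.state, frame_counts, self.net)
        return self.state.posterior


# ---------------------------------------------------------------------------
# exact Poisson template classifier
# ---------------------------------------------------------------------------

class PoissonTemplateClassifier:
    """Exact Bayes posterior over a set of known intensity templates.

    The cumulative count over ``[0, T]`` is Poisson with mean ``rate * T``,
    so the class log-likelihood (up to class-independent terms) is
    ``sum_i S_i log(rate_i) - T sum_i rate_i`` and the posterior follows by
    normalizing against the class prior.  Every template rate must be
    strictly positive, which any nonzero dark current guarantees.
    """

    def __init__(self, templates, noise: NoiseModel, prior=None):
        self.templates = [np.asarray(tpl, dtype=float) for tpl in templates]
        self.noise = noise
        self.rates = np.stack(
            [effective_rate(tpl, noise).ravel() for tpl in self.templates])
        if np.any(self.rates <= 0):
            raise ValueError("template rates must be positive (use eps_dc > 0)")
        self.log_rates = np.log(self.rates)
        self.total_rates = self.rates.sum(axis=1)
        self.prior = (np.full(len(self.templates), 1.0 / len(self.templates))
                      if prior is None else np.asarray(prior, dtype=float))
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("class prior must sum to 1")
        self.log_prior = np.log(self.prior)

    @property
    def n_classes(self) -> int:
        return len(self.templates)

    def log_likelihoods(self, S, duration: float) -> np.ndarray:
        """Per-class log-likelihoods (up to a class-independent constant)."""
        npx = self.rates.shape[1]
        S = np.asarray(S, dtype=float)
        S = S.reshape(-1) if S.size == npx else S.reshape(len(S), npx)
        return S @ self.log_rates.T - duration * self.total_rates

    def posterior_from_cumulative(self, S, t_index: int,
                                  delta_t: float) -> np.ndarray:
        return _softmax(self.log_prior +
                        self.log_likelihoods(S, t_index * delta_t))

    def stepper(self, delta_t: float) -> "_TemplateStepper":
        return _TemplateStepper(self, delta_t)


class _TemplateStepper:
    def __init__(self, clf: PoissonTemplateClassifier, delta_t: float):
        self.clf = clf
        self.delta_t = delta_t
        self.logpost = clf.log_prior.copy()

    @property
    def n_classes(self) -> int:
        return self.clf.n_classes

    def update(self, frame_counts) -> np.ndarray:
        x = np.asarray(frame_counts, dtype=float).ravel()
        self.logpost = (self.logpost + x @ self.clf.log_rates.T
                        - self.delta_t * self.clf.total_rates)
        return _softmax(self.logpost)


# ---------------------------------------------------------------------------
# SPRT stopping rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPRTDecision:
    """Outcome of a sequential classification run."""

    label: int
    stop_frame: int
    stop_ppp: float
    posterior: np.ndarray
    capped: bool


def sprt_classify(stream: PhotonStream, theta: float, model,
                  ppp_cap: float = DEFAULT_PPP_CAP) -> SPRTDecision:
    """Classify a photon stream with the sequential probability ratio test.

    After each frame the model posterior ``f`` is refreshed; the leading
    class ``c* = argmax_c f_c`` (ties broken toward the lowest index) is
    reported as soon as ``log(f_{c*} / (1 - f_{c*})) > theta``, so an
    uncapped decision carries posterior mass at least ``sigmoid(theta)``.
    If the exposure reaches ``ppp_cap`` photons per bright pixel first, the
    current argmax is returned with ``capped=True``.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    if ppp_cap <= 0:
        raise ValueError("ppp_cap must be positive")
    stepper = model.stepper(stream.delta_t)
    f = None
    t = 0
    for t in range(len(stream)):
        f = stepper.update(stream.frames[t])
        c = int(np.argmax(f))
        if _log_odds(float(f[c])) > theta:
            return SPRTDecision(c, t, stream.ppp_at(t), f, False)
        if stream.ppp_at(t) >= ppp_cap:
            break
    c = int(np.argmax(f))
    return SPRTDecision(c, t, stream.ppp_at(t), f, True)


def er_ppp_curve(images, labels, model, theta_grid, noise: NoiseModel,
                 delta_t: float, rng: np.random.Generator, n_trials: int,
                 ppp_cap: float = DEFAULT_PPP_CAP):
    """Speed-accuracy tradeoff: error rate and median stop-PPP per threshold.

    Each trial simulates one photon stream up to ``ppp_cap`` and records the
    posterior log-odds trajectory once; every threshold in ``theta_grid`` is
    then evaluated on the same trajectories (first crossing), so the whole
    sweep shares one set of simulations.  The median (not mean) stop-PPP is
    reported because the stopping-time distribution is heavy-tailed.

    Returns a list of dicts with keys theta, error_rate, median_ppp, n_trials.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta_grid must be non-empty")
    images = [np.asarray(im, dtype=float) for im in images]
    labels = np.asarray(labels, dtype=int)
    n_frames = max(1, int(np.ceil(ppp_cap / (noise.lambda_max * delta_t))))
    trajectories = []
    for trial in range(n_trials):
        i = trial % len(images)
        stream = sample_stream(images[i], noise, delta_t, n_frames,
                               int(rng.integers(0, 2**31 - 1)))
        stepper = model.stepper(delta_t)
        arg = np.empty(n_frames, dtype=int)
        odds = np.empty(n_frames)
        for t in range(n_frames):
            f = stepper.update(stream.frames[t])
            c = int(np.argmax(f))
            arg[t] = c
            odds[t] = _log_odds(float(f[c]))
        trajectories.append((labels[i], arg, odds))
    rows = []
    for theta in theta_grid:
        errs, ppps = [], []
        for y, arg, odds in trajectories:
            hit = np.nonzero(odds > theta)[0]
            t_stop = int(hit[0]) if len(hit) else n_frames - 1
            errs.append(arg[t_stop] != y)
            ppps.append(noise.lambda_max * (t_stop + 1) * delta_t)
        rows.append({"theta": float(theta), "error_rate": float(np.mean(errs)),
                     "median_ppp": float(np.median(ppps)),
                     "n_trials": n_trials})
    return rows


def specialist_classify(S, current_ppp: float, ppp_star: float,
                        net_star: LayeredNet, t_star: float) -> int:
    """Classify with a single-light-level specialist by exposure rescaling.

    Cumulative counts are scaled by ``ppp_star / current_ppp`` so their
    expected magnitude matches the level the specialist was trained at, then
    evaluated at the specialist's nominal frame index ``t_star``.  There is
    no stopping rule; the argmax label is returned.
    """
    if current_ppp <= 0 or ppp_star <= 0:
        raise ValueError("exposures must be positive")
    S = np.asarray(S, dtype=float).ravel() * (ppp_star / current_ppp)
    return int(np.argmax(forward(net_star, S, t_star)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Mini-batch SGD hyper-parameters.

    Defaults: L2 weight decay 5e-4, batches of 100, 60 epochs, learning rate
    1e-3, momentum 0.9, training light levels PPP in {0.22, 2.2, 22, 220}.
    """

    weight_decay: float = 0.0005
    batch_size: int = 100
    epochs: int = 60
    learning_rate: float = 0.001
    momentum: float = 0.9
    ppp_levels: tuple = DEFAULT_PPP_LEVELS
    resample_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")
        if not self.ppp_levels:
            raise ValueError("ppp_levels must be non-empty")


def make_training_set(images, labels, noise: NoiseModel, delta_t: float,
                      rng: np.random.Generator, ppp_levels=DEFAULT_PPP_LEVELS):
    """Draw one ``{S, t, Y}`` tuple per image at a random training light level.

    The cumulative count over ``[0, T]`` is Poisson with mean ``rate * T``,
    so it is sampled in one draw rather than frame by frame.  ``t`` is the
    equivalent frame index ``PPP / (lambda_max * delta_t)``.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    labels = np.asarray(labels, dtype=int)
    levels = np.asarray(ppp_levels, dtype=float)
    ppp = rng.choice(levels, size=len(images))
    t_frames = ppp / (noise.lambda_max * delta_t)
    S = np.empty((len(images), images[0].size))
    for i, im in enumerate(images):
        rate = effective_rate(im, noise).ravel()
        S[i] = rng.poisson(rate * t_frames[i] * delta_t)
    return S, t_frames, labels


def _apply_tie(grad: np.ndarray, tie: np.ndarray) -> np.ndarray:
    """Sum gradients over tied entries and broadcast back; zero where tie<0."""
    valid = tie >= 0
    acc = np.bincount(tie[valid], weights=grad[valid],
                      minlength=int(tie.max()) + 1)
    out = np.zeros_like(grad, dtype=float)
    out[valid] = acc[tie[valid]]
    return out


def _gradients(net: LayeredNet, S, t, Y, weight_decay: float):
    """Loss and parameter gradients for one mini-batch.

    The loss is the mean negative log-likelihood plus
    ``weight_decay * sum_l ||W^(l)||^2`` over the materialized weights.
    Gradient of the rectified group-max flows to the argmax unit of each
    group when the pooled value is positive, and is zero otherwise.
    """
    B = len(S)
    t = np.broadcast_to(np.asarray(t, dtype=float), (B,))
    f, caches = _forward_cached(net, S, t)
    picked = np.maximum(f[np.arange(B), Y], 1e-300)
    nll = -float(np.mean(np.log(picked)))
    dm = (f - np.eye(net.n_classes)[Y]) / B
    grads = [None] * len(net.layers)
    for li in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[li]
        cache = caches[li]
        dz = np.zeros_like(cache["z"])
        rows = np.repeat(np.arange(B), layer.n_out)
        cols = cache["amax"].ravel()
        gate = (cache["m"] > 0).ravel()
        np.add.at(dz, (rows[gate], cols[gate]), dm.ravel()[gate])
        dW = dz.T @ cache["a_in"] + 2.0 * weight_decay * layer.W
        db = dz.T @ t if li == 0 else dz.sum(axis=0)
        if layer.w_tie is not None:
            dW = _apply_tie(dW, layer.w_tie)
            db = _apply_tie(db, layer.b_tie)
        grads[li] = (dW, db)
        if li > 0:
            dm = dz @ layer.W
    penalty = weight_decay * sum(float(np.sum(l.W ** 2)) for l in net.layers)
    return nll + penalty, grads


def train(dataset, config: TrainConfig, net: LayeredNet,
          rng: np.random.Generator, resample_source=None):
    """Fit ``net`` in place by penalized maximum likelihood.

    ``dataset`` is ``(S, t, Y)``: cumulative counts ``S`` of shape (N, d),
    frame indices ``t`` (N,), integer labels ``Y`` in ``0..C-1``.  Optimizes
    the mean negative log-likelihood plus an L2 weight penalty with
    mini-batch SGD and momentum.  When ``resample_source = (images, labels,
    noise, delta_t)`` is given and ``config.resample_each_epoch`` is set,
    the photon counts are redrawn each epoch so the net never memorizes one
    shot-noise realization.

    Returns the per-epoch mean training loss; raises ``FloatingPointError``
    if the loss turns non-finite.
    """
    S, t, Y = dataset
    S = np.asarray(S, dtype=float)
    t = np.broadcast_to(np.asarray(t, dtype=float), (len(S),)).copy()
    Y = np.asarray(Y, dtype=int)
    if len(S) == 0:
        raise ValueError("empty training set")
    if Y.min() < 0 or Y.max() >= net.n_classes:
        raise ValueError("labels out of range")
    vel_W = [np.zeros_like(layer.W) for layer in net.layers]
    vel_b = [np.zeros_like(layer.b) for layer in net.layers]
    losses = []
    for epoch in range(config.epochs):
        if epoch > 0 and config.resample_each_epoch and resample_source is not None:
            images, im_labels, noise, delta_t = resample_source
            S, t, Y = make_training_set(images, im_labels, noise, delta_t,
                                        rng, config.ppp_levels)
        order = rng.permutation(len(S))
        epoch_loss = 0.0
        for start in range(0, len(S), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = _gradients(net, S[idx], t[idx], Y[idx],
                                     config.weight_decay)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}")
            for li, layer in enumerate(net.layers):
                dW, db = grads[li]
                vel_W[li] = config.momentum * vel_W[li] - config.learning_rate * dW
                vel_b[li] = config.momentum * vel_b[li] - config.learning_rate * db
                layer.W += vel_W[li]
                layer.b += vel_b[li]
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(S))
    return losses
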