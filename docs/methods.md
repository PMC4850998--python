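# Methods

`lowlight` computes vision decisions — classification, visual search,
tracking — directly from streams of photon counts, without ever forming an
image. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Imaging model

A stationary scene with per-pixel intensities `I ∈ [0,1]` is observed by a
photon-counting sensor. Within an exposure interval `δt` the count at pixel
`i` is Poisson with rate

    rate_i = λmax · (I_i + ε_dc) / (1 + ε_dc)      [photons/s]

`λmax` (photons/s) is the emission rate of a full-intensity pixel — the
normalization by `1 + ε_dc` keeps that true for any dark current, and gives
a zero-intensity pixel the rate `λmax ε_dc / (1 + ε_dc)` (so `λmax = 3`,
`ε_dc = 0.5` make the background emit exactly 1 photon/s). At readout the
integer count `N` may be corrupted by additive Gaussian read noise
`ε_r ~ N(0, σ_r)` and a per-pixel multiplicative fixed-pattern gain
`ε_fpn ~ N(0, σ_fpn)` drawn once per sensor instance:

    x = max(0, (N + ε_r)(1 + ε_fpn))

Readout values are kept real-valued (no re-quantization); downstream
consumers use sums. Dark current is a scalar fraction by default; an
optional per-pixel spread `σ_dc` (clipped at zero) is exposed but disabled,
since a zero-mean Gaussian dark current alone would be unphysical.
Exposure is quoted in photons per bright pixel, `PPP = λmax · t`, an
illuminance-independent proxy for information content. RNG contract: one
seed per stream; the fixed-pattern map is drawn first, then frames in
order, so streams are bit-reproducible.

## Sequential classification

`forward` evaluates a stack of linear stages with rectified group-max
pooling between them and a softmax head. The first stage is linear in the
cumulative counts with a bias that accumulates with the frame index,
`h = W S_t + b·t`, which makes the network exposure-aware: the same
weights apply at any light level because `S_t` and `t` jointly encode how
much evidence has arrived. Deeper stages are linear in the previous
pooled outputs with a constant bias; the rectified max-pool
`m_k = max(0, max_{j∈G_k} h_j)` is applied uniformly, including before the
softmax. Convolutional weight sharing is supported by expanding a filter
bank into a dense layer with tied parameters (gradients are summed over
ties), so the incremental machinery below applies unchanged.

**Incremental evaluation.** Because layer 1 is linear in `S_t`, a new
frame only adds `W·x + b` to its accumulators, touching just the units
with support on nonzero pixels. Pooled maxima are refreshed from the
candidate set {changed units} ∪ {previous argmax}. That sparse rule is
exact only when the unchanged units of a group shift by a common amount
(per-group-uniform bias) and no update is negative; any group violating
either condition is recomputed in full, so incremental and batch
evaluation agree *always* — the test suite pins them to 1e-10 on random
streams (they differ only by floating-point summation order). Deeper
stages are recomputed only where their pooled inputs changed. Argmax ties
break to the lowest index.

**Stopping rule.** The SPRT wrapper stops at the first frame where the
leading class satisfies `log(f_c/(1−f_c)) > θ`, so an uncapped decision
carries posterior mass at least `sigmoid(θ)` and — when the model equals
the generative conditional — the error rate is at most `1 − sigmoid(θ)`
(`θ = log 9 ≈ 2.2` for 10%, `log 99 ≈ 4.6` for 1%). A default exposure cap
of PPP 220 (the highest training level) forces an argmax decision so
experiments terminate; capped decisions are flagged. Threshold sweeps
reuse one set of simulated posterior trajectories, evaluating every
threshold on the same trials; the median (not mean) stop-PPP summarizes
each operating point because stopping exposures are heavy-tailed.

**Training.** The network is fit on `{S, t, Y}` tuples — cumulative counts
sampled in one Poisson draw at a light level from {0.22, 2.2, 22, 220}
PPP — by mini-batch SGD with momentum on the mean negative log-likelihood
plus an L2 weight penalty (defaults: decay 5e-4, batch 100, 60 epochs,
learning rate 1e-3, momentum 0.9). Gradients route through the rectified
group-max to the argmax unit when the pooled value is positive (standard
subgradient); they are verified against central finite differences for
both dense and tied-convolutional layers. Counts are redrawn each epoch by
default so the net never memorizes one shot-noise realization. The SGD
loop is a small self-contained numpy implementation: the architecture's
group-max pooling and tied incremental structure are bespoke, so a generic
deep-learning framework would have required a custom layer anyway.

`PoissonTemplateClassifier` provides the exact Bayes posterior when class
templates are known (cumulative counts over `[0,T]` are Poisson with mean
`rate·T`); it serves as the oracle in tests and as the local classifier in
search. A specialist trained at a single light level is applied at another
level by rescaling cumulative counts by `PPP*/PPP` (real-valued results
allowed).

## Visual search

A display has `L = 14` non-overlapping 7×7 windows; `M` hold a 3×7
intensity-1 bar (distractors at orientation `y_D`, at most one target at
`y_T`), the rest are empty. Scene properties `φ = (M, y_T, y_D)` may carry
a prior. Per-window content hypotheses are {empty} ∪ {orientations in the
φ support}. The generative conditionals are derived from the scene
process: `P(y | φ, C(l)=0) = {empty: (L−M)/L, y_D: M/L}` and
`P(y | φ, C(l)=1) = δ(y = y_T)`; target location is uniform over all `L`
locations with `P(C=1) = 0.5`, which makes the global log-likelihood ratio
exactly 0 before any photon arrives.

Local posteriors are exact Poisson template posteriors over the hypothesis
set (a trained sequential classifier can be dropped in through the same
log-posterior interface). The global statistic composes them:

    S(t) = log[ (1/L) Σ_{l,φ} R(l,φ) P(φ | X) ]

with `R(l,φ)` the f-weighted odds that window `l` holds the target and
`P(φ|X)` accumulated across windows from the no-target likelihood of each.
The local classifiers use a **uniform** prior over their hypothesis set by
default (configurable to the generative marginal). With the uniform prior
the composition is algebraically identical to exact Bayes on the joint
model in which windows are independent given `φ` and the target placement
— the test suite checks equality against brute-force enumeration to 1e-8
on small scenes. With a non-uniform local prior the prior factor does not
cancel between the numerator and denominator of `R`, and the composition
becomes (mildly) approximate; uniform is therefore the default. The scene
*generator* places exactly `M` bars, whereas the independence model the
inference assumes makes occupancy i.i.d. at rate `M/L` — the slight
mismatch is a property of the composed inference, not of the tests.

Bars at non-axis angles are rasterized by an anti-aliased separable
overlap rule in the rectangle's own frame (exact for axis-aligned
rectangles), preserving total brightness across orientations to well
under 2%. The two-threshold sequential rule declares presence above `θ1`
and absence at or below `θ0` (ties at the lower threshold resolve to
absent, deterministically); capped trials decide by the sign of `S`.
Threshold sweeps run thousands of trials in lock-step with vectorized
per-frame updates — verified to match the reference per-frame path on
identical counts — and locate an operating point by linear interpolation
of median stop-PPP between the grid thresholds whose error rates bracket
the target.

**Measured operating points** (λmax = 3/s, 50% dark current, exact local
classifiers, 2000 balanced trials): the low-clutter orthogonal condition
(M = 3 known, δy = 90°) reaches 5% error at a median of ≈ 0.7 PPP — under
one photon per bright pixel. The high-clutter fine-discrimination
condition (M = 12 known, δy = 20°) reaches 1% error at ≈ 4.3 PPP. The
latter is at the information-theoretic floor for this stimulus: the
per-window Kullback–Leibler drift between the 70° and 90° Poisson
templates is ≈ 1.9 nats per PPP, and a 1% decision needs
`log 99 ≈ 4.6` nats plus the `log L ≈ 2.6` location-uncertainty penalty
carried by the `(1/L) Σ_l` composition, i.e. ≥ 3.5 PPP before overshoot.
No correct Bayes procedure can do better under these stimulus parameters.

## Tracking

The test system is an uncontrolled inverted pendulum: a point mass on a
massless pole (length 30 px, half the cart's mass) on a frictionless cart.
State `Z = (α, α̇, β, β̇)` — pole angle from upright (radians; degrees at
reporting interfaces), angular velocity, cart offset (pixels), cart
velocity. The Euler–Lagrange equations are integrated by fixed-step RK4
with substeps ≤ 2 ms; energy is conserved to ~1e-9 relative over 10 s and
the hanging small-oscillation period matches the closed form
`ω² = g(1+r)/l`. The scene is 80×80 px; only the 3×30 pole is bright.
Physical constants the stimulus description leaves open are fixed in
config as package choices: gravity defaults to the value giving a 1 s
natural period, the pivot row (44) keeps the pole inside the scene at all
angles, and trials simulate 0.8 s at `δt = 20 ms` unless stated.

The filter alternates:

1. **Predict** — mean through the dynamics, covariance through the
   dt-step Jacobian (central differences, step 1e-6): `Σ' = JΣJᵀ`, plus an
   optional process-noise floor that defaults to 0. With the floor at 0
   the covariance can collapse and the filter can diverge at long
   exposures/high SNR — a real property of the plain linearized recursion
   that the experiments deliberately retain.
2. **Update** — draw K samples from the predictive Gaussian (K = 1000 by
   default), weight by the Poisson photon log-likelihood
   `Σ X log λ − Σ λ` (uniform state prior; normalized by log-sum-exp), and
   moment-match with the unbiased weighted covariance
   `Σ W (Z−μ)(Z−μ)ᵀ / (1 − ΣW²)`. Covariances are symmetrized with
   eigenvalues floored at 0 after every step. If all weights vanish, or
   they collapse onto a single sample (`1 − ΣW² ≈ 0`), the update falls
   back to the predictive belief with a warning rather than aborting the
   trial. Samples drawn from the Gaussian are continuous in α, so no
   angle re-wrapping is needed inside the moment computation; angles wrap
   only when errors are reported.

A uniform prior on a circle has no Gaussian representation, so
initialization is multi-start: candidate beliefs on a 12-point angle grid
with wide covariance, each updated with the first frame; the candidate
with the highest marginal likelihood wins. Likelihood evaluation renders
only the union bounding box of the sampled poles; outside it the rate is
the flat dark-current rate, handled in closed form (verified equal to the
full computation to 1e-12).

**Convergence time** is the first time the angle error enters and *stays
within* a tolerance band (the reach-only variant is available via
`mode="first"`); trials that never converge report infinity, capped at the
trial duration when summarized. Conditions are summarized by the median
over matched-seed trials because convergence times are heavy-tailed — an
occasional diverged trial at high SNR (the sampling-noise pathology above)
would otherwise dominate a small-sample mean.

## Synthetic fixtures

Glyph fixtures (10 stroke-based 28×28 classes: loop, bars, cross,
diagonals, X, T, double bar, L) with sub-pixel position jitter
(σ = 0.5 px) stand in for a handwritten-symbol dataset so tests need no
download. They emulate the *statistical* structure the classifier
exploits — sparse bright strokes, class-distinctive geometry, shot-noise
limited observation — but not the within-class shape variability of real
handwriting; passing tests therefore demonstrate the sequential machinery
(calibration, monotone speed–accuracy tradeoff, incremental exactness),
not handwriting-level accuracy. The construction is checked: the 10-class
set is solved by the exact template classifier at PPP 220 with ≤ 1% error.
An IDX reader is provided for running the same pipeline on the standard
digit benchmark where that data is available.

## Reproducibility

Experiment drivers write CSV results, a JSON manifest (seed, config
digest, version) and a text log. A master seed spawns per-trial child
seeds via `numpy.random.SeedSequence.spawn`, so enlarging a sweep never
perturbs earlier trials. Problem sizes in the shipped tests and in
`scripts/acceptance.py` are the package's reduced defaults — 2000 balanced
search trials per condition, 20-trial tracking conditions, a 4-class glyph
classifier — chosen to characterize each quantity with Monte-Carlo error
well inside the tolerances asserted.

## Known limitations

- Motion blur, camera self-motion and rolling shutter are not modeled;
  scenes are stationary within each exposure interval.
- The search model assumes known, non-overlapping windows and at most one
  target.
- Exact template likelihoods require strictly positive rates; at zero dark
  current a photon on a structurally dark pixel yields −∞ log-likelihood
  (documented; the degenerate-update fallback covers the tracker).
- The `1/L` location prior in the search composition is implemented as
  specified even though the generator places targets only in occupied
  windows; with `M` close to `L` the difference is ≤ `log(L/M)`.
- The plain linearized covariance propagation (no process noise) can
  collapse and diverge on long bright runs; the floor is exposed in
  config for applications that need robustness over fidelity.
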