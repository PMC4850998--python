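# lowlight — vision from photon streams, without the image

Photon-counting sensors (SPADs, quanta image sensors) report photon
arrivals as they happen instead of integrating a frame. In photon-starved
settings — low-light microscopy where exposure is capped by phototoxicity
and bleaching, astronomy, night surveillance — waiting to accumulate a
clean image wastes the scarcest resource. `lowlight` takes the other
route: it computes the task variable (class, target presence, object
state) *directly* from the count stream and stops the moment the evidence
suffices.

The package provides a sensor simulator and three inference engines:

- **Sensor model** — per-pixel counts are Poisson with rate
  `λmax (I + ε_dc) / (1 + ε_dc)` (intensity `I ∈ [0,1]`, dark-current
  fraction `ε_dc`), optionally corrupted at readout by Gaussian read noise
  and per-pixel fixed-pattern gain, `x = max(0, (N + ε_r)(1 + ε_fpn))`.
  Exposure is measured in photons per bright pixel, `PPP = λmax · t`.
- **Sequential classification** — a layered network (linear stages with
  rectified group-max pooling, softmax head) approximates
  `P(Y | X_{1:t})` from cumulative counts and is updatable frame by frame
  at sparse cost. A sequential probability ratio test stops when the
  leading class's posterior log-odds exceed `θ = log((1−γ)/γ)`, bounding
  the error rate by `γ` when the model matches the data.
- **Bayesian visual search** — per-window orientation posteriors over
  cluttered bar displays are composed into a global log-likelihood ratio
  for target presence, with scene properties (clutter level, target and
  distractor appearance) inferred jointly; a two-threshold sequential
  rule controls false accepts and false rejects separately.
- **Tracking** — a Gaussian-belief filter for a cart-pole (inverted
  pendulum) observed only through photon counts: linearized dynamics
  propagation, Poisson-likelihood weighting of predictive samples, and
  moment-matched posterior updates.

## Worked example

Classify a 28×28 stroke glyph from a simulated photon stream, demanding
1% error (θ = log 99):

```python
import numpy as np
from lowlight.sensor import NoiseModel, sample_stream
from lowlight.fixtures import make_glyph_fixtures
from lowlight.classify import (PoissonTemplateClassifier, sprt_classify,
                               threshold_for_error)

noise = NoiseModel(lambda_max=22.0, eps_dc=0.03)    # 3% dark current
fixtures = make_glyph_fixtures(n_classes=10, n_per_class=1, rng=0)
clf = PoissonTemplateClassifier(list(fixtures.templates), noise)

theta = threshold_for_error(0.01)                   # log 99 ~ 4.6
stream = sample_stream(fixtures.templates[3], noise, delta_t=0.001,
                       n_frames=2000, rng=42)       # a cross glyph, 1 ms frames
decision = sprt_classify(stream, theta, clf)
print(f"threshold theta = {theta:.3f}")
print(f"decided class {decision.label} after {decision.stop_frame + 1} frames "
      f"({decision.stop_ppp:.3f} photons per bright pixel), "
      f"max posterior {decision.posterior.max():.4f}, capped={decision.capped}")
print(f"photons collected: {int(stream.cumulative[decision.stop_frame].sum())}")
```

```
threshold theta = 4.595
decided class 3 after 4 frames (0.088 photons per bright pixel), max posterior 0.9997, capped=False
photons collected: 15
```

The decision lands after 15 photons spread over 784 pixels — under a tenth
of a photon per bright pixel, far short of anything resembling an image —
yet carries ≥ 99% posterior confidence. Sweeping `θ` traverses the full
speed–accuracy tradeoff (`lowlight.classify.er_ppp_curve`); stop exposures
are heavy-tailed, so operating points are summarized by the median PPP.

Command-line drivers wrap the same library functions:

```bash
lowlight classify-eval --seed 0 --out-dir results     # θ sweep on glyphs
lowlight search-eval   --seed 0 --out-dir results     # clutter conditions
lowlight track-eval    --seed 0 --out-dir results     # pendulum error curves
lowlight noise-sweep   --seed 0 --out-dir results     # sensor-noise robustness
```

Each driver writes a CSV, a JSON manifest (seed, config digest, version)
and a log, and is rerunnable bit-for-bit from the manifest.

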