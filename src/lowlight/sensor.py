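"""Photon-counting sensor simulation.

A stationary scene with per-pixel intensities ``I`` in [0, 1] is observed by a
photon-counting sensor that reports, every ``delta_t`` seconds, a frame of
per-pixel photon counts.  Counts are Poisson with rate

    rate_i = lambda_max * (I_i + eps_dc) / (1 + eps_dc)        [photons/s]

where ``lambda_max`` is the emission rate of a full-intensity pixel and
``eps_dc`` is the dark-current fraction (a zero-intensity pixel still emits
``lambda_max * eps_dc / (1 + eps_dc)`` photons/s).  At readout the integer
count ``N`` is optionally corrupted by additive Gaussian read noise and a
per-pixel multiplicative fixed-pattern gain:

    x = max(0, (N + e_r) * (1 + e_fpn)),   e_r ~ N(0, sigma_r) fresh per frame,
                                           e_fpn fixed per sensor instance.

Exposure is quoted in photons per bright pixel (PPP): the expected count
collected so far by a full-intensity pixel, ``lambda_max * t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseModel",
    "PhotonFrame",
    "PhotonStream",
    "as_intensity_image",
    "effective_rate",
    "make_fpn_map",
    "apply_readout",
    "sample_frame",
    "sample_stream",
    "ppp",
    "time_for_ppp",
]


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise parameters.

    Parameters
    ----------
    lambda_max : float
        Photon emission rate (photons/s) of a pixel at maximum intensity.
    eps_dc : float
        Dark-current fraction in [0, 1].
    sigma_r : float
        Standard deviation of the additive Gaussian read noise (counts).
    sigma_fpn : float
        Standard deviation of the multiplicative fixed-pattern gain offsets.
    sigma_dc : float
        Optional per-pixel spread of the dark-current fraction (disabled by
        default); per-pixel values are clipped to be non-negative.
    """

    lambda_max: float
    eps_dc: float = 0.0
    sigma_r: float = 0.0
    sigma_fpn: float = 0.0
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda_max > 0 and np.isfinite(self.lambda_max)):
            raise ValueError(f"lambda_max must be positive, got {self.lambda_max}")
        if not (0.0 <= self.eps_dc <= 1.0):
            raise ValueError(f"eps_dc must be in [0, 1], got {self.eps_dc}")
        for name in ("sigma_r", "sigma_fpn", "sigma_dc"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be >= 0, got {v}")


def as_intensity_image(image) -> np.ndarray:
    """Validate and return an intensity image as a float array in [0, 1]."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 0 or arr.size == 0:
        raise ValueError("intensity image must be a non-empty array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensity image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("intensity values must lie in [0, 1]")
    return arr


def effective_rate(image, noise: NoiseModel, dc_map=None) -> np.ndarray:
    """Per-pixel photon emission rate in photons/s.

    ``rate = lambda_max * (I + eps_dc) / (1 + eps_dc)``, so a full-intensity
    pixel emits exactly ``lambda_max`` regardless of the dark current, and a
    dark pixel emits ``lambda_max * eps_dc / (1 + eps_dc)``.

    ``dc_map`` optionally supplies a per-pixel dark-current fraction (see
    :class:`NoiseModel.sigma_dc`); when omitted the scalar ``eps_dc`` is used.
    """
    arr = as_intensity_image(image)
    dc = noise.eps_dc if dc_map is None else np.asarray(dc_map, dtype=float)
    return noise.lambda_max * (arr + dc) / (1.0 + dc)


def make_fpn_map(shape, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Draw the per-pixel fixed-pattern gain offsets for one sensor instance."""
    return rng.normal(0.0, noise.sigma_fpn, size=shape) if noise.sigma_fpn > 0 else np.zeros(shape)


def make_dc_map(shape, noise: NoiseModel, rng: np.random.Generator):
    """Per-pixel dark-current fractions, or None when the spread is disabled."""
    if noise.sigma_dc == 0:
        return None
    return np.clip(noise.eps_dc + rng.normal(0.0, noise.sigma_dc, size=shape), 0.0, 1.0)


def apply_readout(counts, noise: NoiseModel, fpn_map, rng: np.random.Generator) -> np.ndarray:
    """Readout transform ``max(0, (N + e_r) * (1 + e_fpn))``.

    Read noise is drawn fresh per call; ``fpn_map`` must be held fixed across
    all frames of one stream.  With both noises at zero this is the identity
    on the integer counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("photon counts must be non-negative")
    if noise.sigma_r > 0:
        counts = counts + rng.normal(0.0, noise.sigma_r, size=counts.shape)
    return np.maximum(0.0, counts * (1.0 + np.asarray(fpn_map)))


@dataclass(frozen=True)
class PhotonFrame:
    """Per-pixel readouts for one exposure interval."""

    counts: np.ndarray
    t_index: int
    delta_t: float


@dataclass
class PhotonStream:
    """An ordered sequence of photon frames from one sensor instance.

    ``frames`` has shape ``(T, *image_shape)``; ``cumulative[t]`` is the
    elementwise sum of frames ``0..t``.  All frames share one fixed-pattern
    map and one ``delta_t``.
    """

    frames: np.ndarray
    delta_t: float
    noise: NoiseModel
    seed: int | None = None
    fpn_map: np.ndarray | None = None
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim < 2 or self.frames.shape[0] < 1:
            raise ValueError("stream needs at least one frame")
        self.cumulative = np.cumsum(self.frames, axis=0)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        for t in range(len(self)):
            yield PhotonFrame(self.frames[t], t, self.delta_t)

    @property
    def duration(self) -> float:
        """Total elapsed exposure time in seconds."""
        return len(self) * self.delta_t

    def ppp_at(self, t_index: int) -> float:
        """Exposure (photons per bright pixel) after frame ``t_index``."""
        return ppp((t_index + 1) * self.delta_t, self.noise)


def sample_frame(
    image,
    noise: NoiseModel,
    delta_t: float,
    rng: np.random.Generator,
    fpn_map=None,
    dc_map=None,
) -> np.ndarray:
    """Sample one frame of readouts for an exposure of ``delta_t`` seconds."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    rate = effective_rate(image, noise, dc_map=dc_map)
    n = rng.poisson(rate * delta_t)
    if fpn_map is None:
        fpn_map = np.zeros_like(rate)
    return apply_readout(n, noise, fpn_map, rng)


def sample_stream(
    image,
    noise: NoiseModel,
    delta_t: float,
    n_frames: int,
    rng: np.random.Generator | int,
) -> PhotonStream:
    """Simulate a reproducible photon stream.

    The fixed-pattern map (and optional per-pixel dark-current map) are drawn
    first from the generator, then frames in order, so a given seed yields a
    bit-identical stream.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng
    arr = as_intensity_image(image)
    fpn_map = make_fpn_map(arr.shape, noise, gen)
    dc_map = make_dc_map(arr.shape, noise, gen)
    frames = np.empty((n_frames,) + arr.shape, dtype=float)
    for t in range(n_frames):
        frames[t] = sample_frame(arr, noise, delta_t, gen, fpn_map=fpn_map, dc_map=dc_map)
    return PhotonStream(frames, delta_t, noise, seed=seed, fpn_map=fpn_map)


def ppp(t: float, noise: NoiseModel) -> float:
    """Photons per bright pixel after ``t`` seconds: ``lambda_max * t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return noise.lambda_max * t


def time_for_ppp(target_ppp: float, noise: NoiseModel) -> float:
    """Exposure time (seconds) at which a bright pixel expects ``target_ppp`` photons."""
    return target_ppp / noise.lambda_max
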