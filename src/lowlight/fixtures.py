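"""Procedural glyph fixtures for classification experiments.

Stroke glyphs (bars, loops, crosses) on a 28x28 canvas stand in for a
handwritten-symbol dataset so that experiments and tests need no external
download: each class has a fixed template plus small per-sample position
jitter.  The templates are pairwise well separated, so an exact Poisson
template classifier solves the 10-class task near-perfectly at high
exposure — a construction the fixtures are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import rect_coverage

__all__ = ["GlyphFixtureSet", "make_glyph_fixtures", "glyph_template"]

CANVAS = 28


def _ring(shape, center, radius, thickness) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    d = np.hypot(rows - center[0], cols - center[1])
    inner, outer = radius - thickness / 2.0, radius + thickness / 2.0
    return np.clip(np.minimum(d - inner + 0.5, outer + 0.5 - d), 0.0, 1.0)


def _bar(center, angle, length, width=3.0):
    return rect_coverage((CANVAS, CANVAS), center, angle, length, width)


def glyph_template(cls: int, offset=(0.0, 0.0)) -> np.ndarray:
    """Render the template for class ``cls`` (0..9), shifted by ``offset``."""
    r0, c0 = 13.5 + offset[0], 13.5 + offset[1]
    c = (r0, c0)
    if cls == 0:                                   # loop
        img = _ring((CANVAS, CANVAS), c, 8.0, 3.0)
    elif cls == 1:                                 # vertical bar
        img = _bar(c, 90.0, 18.0)
    elif cls == 2:                                 # horizontal bar
        img = _bar(c, 0.0, 18.0)
    elif cls == 3:                                 # cross
        img = _bar(c, 0.0, 18.0) + _bar(c, 90.0, 18.0)
    elif cls == 4:                                 # rising diagonal
        img = _bar(c, 45.0, 20.0)
    elif cls == 5:                                 # falling diagonal
        img = _bar(c, 135.0, 20.0)
    elif cls == 6:                                 # X
        img = _bar(c, 45.0, 20.0) + _bar(c, 135.0, 20.0)
    elif cls == 7:                                 # T
        img = _bar((r0 - 7.0, c0), 0.0, 18.0) + _bar(c, 90.0, 16.0)
    elif cls == 8:                                 # two horizontal bars
        img = _bar((r0 - 5.0, c0), 0.0, 18.0) + _bar((r0 + 5.0, c0), 0.0, 18.0)
    elif cls == 9:                                 # L
        img = _bar((r0, c0 - 5.0), 90.0, 16.0) + _bar((r0 + 6.5, c0 + 2.0), 0.0, 12.0)
    else:
        raise ValueError("glyph classes are 0..9")
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class GlyphFixtureSet:
    """Labeled glyph images with a train/test split."""

    templates: np.ndarray        # (n_classes, 28, 28)
    images: np.ndarray           # (n, 28, 28)
    labels: np.ndarray           # (n,)
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.templates)

    def split(self, which: str):
        idx = self.train_idx if which == "train" else self.test_idx
        return self.images[idx], self.labels[idx]


def make_glyph_fixtures(n_classes: int, n_per_class: int,
                        jitter: float = 0.5,
                        rng: np.random.Generator | int = 0,
                        test_fraction: float = 0.25) -> GlyphFixtureSet:
    """Draw a glyph dataset: ``n_per_class`` jittered copies per class.

    ``jitter`` is the standard deviation (pixels) of the per-sample
    sub-pixel position offset.  Deterministic for a fixed seed/generator.
    """
    if not (2 <= n_classes <= 10):
        raise ValueError("n_classes must be in 2..10")
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    templates = np.stack([glyph_template(k) for k in range(n_classes)])
    images, labels = [], []
    for k in range(n_classes):
        for _ in range(n_per_class):
            off = gen.normal(0.0, jitter, size=2) if jitter > 0 else (0.0, 0.0)
            images.append(glyph_template(k, offset=tuple(off)))
            labels.append(k)
    images = np.stack(images)
    labels = np.asarray(labels)
    order = gen.permutation(len(images))
    n_test = int(round(test_fraction * len(images)))
    return GlyphFixtureSet(templates, images, labels,
                           train_idx=order[n_test:], test_idx=order[:n_test])
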