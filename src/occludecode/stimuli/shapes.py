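"""Parametric silhouette renderer for the four object categories.

Stand-in shapes (not photographs): each category is a distinct composition
of ellipses, polygons and discs, rendered as a filled silhouette on a
256×256 canvas, size-matched across categories and translated by an integer
position jitter of at most ±15 px.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from skimage import draw as skdraw

from ..errors import ConfigurationError

__all__ = ["render_object", "CATEGORIES", "JITTER_MAX"]

CATEGORIES = ("camel", "deer", "car", "motor")
JITTER_MAX = 15

#: grayscale levels of the composed image
BACKGROUND_LEVEL = 0.8
OBJECT_LEVEL = 0.45
OCCLUDER_LEVEL = 0.0

#: target silhouette area (px) that every category is scaled to
TARGET_AREA = 8000


def _ellipse(mask, cy, cx, ry, rx):
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=mask.shape)
    mask[rr, cc] = True


def _disk(mask, cy, cx, r):
    rr, cc = skdraw.disk((cy, cx), r, shape=mask.shape)
    mask[rr, cc] = True


def _rect(mask, y0, x0, y1, x1):
    rr, cc = skdraw.rectangle((int(y0), int(x0)), end=(int(y1), int(x1)), shape=mask.shape)
    mask[rr, cc] = True


def _poly(mask, ys, xs):
    rr, cc = skdraw.polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = True


def _camel(mask, c, s):
    _ellipse(mask, c, c, 28 * s, 52 * s)                       # body
    _disk(mask, c - 24 * s, c - 18 * s, 16 * s)                # front hump
    _disk(mask, c - 24 * s, c + 14 * s, 14 * s)                # rear hump
    _poly(mask, [c - 10 * s, c - 52 * s, c - 56 * s, c + 2 * s],
          [c - 50 * s, c - 72 * s, c - 58 * s, c - 34 * s])    # neck
    _ellipse(mask, c - 56 * s, c - 70 * s, 8 * s, 13 * s)      # head
    for dx in (-38, -16, 12, 34):                              # legs
        _rect(mask, c + 16 * s, c + dx * s, c + 62 * s, c + (dx + 9) * s)


def _deer(mask, c, s):
    _ellipse(mask, c, c, 22 * s, 44 * s)                       # body
    _poly(mask, [c - 6 * s, c - 52 * s, c - 56 * s, c + 2 * s],
          [c + 26 * s, c + 52 * s, c + 42 * s, c + 12 * s])    # neck
    _ellipse(mask, c - 56 * s, c + 52 * s, 7 * s, 11 * s)      # head
    for dx, dy in ((-4, -90), (6, -84), (16, -78)):            # antlers
        _rect(mask, c - (88 + dy / 10) * s, c + (48 + dx) * s,
              c - 56 * s, c + (51 + dx) * s)
    for dx in (-34, -20, 16, 30):                              # thin legs
        _rect(mask, c + 12 * s, c + dx * s, c + 62 * s, c + (dx + 6) * s)


def _car(mask, c, s):
    _rect(mask, c - 6 * s, c - 56 * s, c + 22 * s, c + 56 * s)          # body
    _poly(mask, [c - 6 * s, c - 30 * s, c - 30 * s, c - 6 * s],
          [c - 34 * s, c - 18 * s, c + 20 * s, c + 38 * s])             # cabin
    _disk(mask, c + 24 * s, c - 32 * s, 14 * s)                         # wheels
    _disk(mask, c + 24 * s, c + 32 * s, 14 * s)


def _motor(mask, c, s):
    _disk(mask, c + 18 * s, c - 36 * s, 20 * s)                         # wheels
    _disk(mask, c + 18 * s, c + 36 * s, 20 * s)
    _poly(mask, [c + 18 * s, c - 10 * s, c - 14 * s, c + 18 * s],
          [c - 36 * s, c - 6 * s, c + 14 * s, c + 36 * s])              # frame
    _rect(mask, c - 26 * s, c - 46 * s, c - 2 * s, c - 38 * s)          # fork
    _rect(mask, c - 30 * s, c - 52 * s, c - 24 * s, c - 30 * s)         # handlebar
    _ellipse(mask, c - 20 * s, c + 8 * s, 8 * s, 16 * s)                # seat/tank


_BUILDERS = {"camel": _camel, "deer": _deer, "car": _car, "motor": _motor}


def _render_centered(category: str, size: int, scale: float) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    _BUILDERS[category](mask, size // 2, scale * size / 256.0)
    return mask


def render_object(category: str, jitter: Tuple[int, int] = (0, 0),
                  seed: int = 0, size: int = 256) -> Tuple[np.ndarray, np.ndarray]:
    """Render one category silhouette.

    Returns ``(pixels, object_mask)``: a grayscale image in [0, 1] of the
    object on a uniform background, and the boolean silhouette mask. The
    silhouette is area-matched across categories (binary search on a global
    scale factor) and shifted by the integer ``jitter = (dx, dy)``; the
    shifted mask is the exact translate of the centered one. ``seed`` is
    accepted for interface uniformity; the silhouettes are purely
    parametric.
    """
    if category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {category!r}; choose from {CATEGORIES}")
    dx, dy = int(jitter[0]), int(jitter[1])
    if abs(dx) > JITTER_MAX or abs(dy) > JITTER_MAX:
        raise ConfigurationError(
            f"jitter {jitter} exceeds ±{JITTER_MAX} px in at least one component")

    target = TARGET_AREA * (size / 256.0) ** 2
    lo, hi = 0.5, 1.8
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        area = _render_centered(category, size, mid).sum()
        if area < target:
            lo = mid
        else:
            hi = mid
    mask = _render_centered(category, size, 0.5 * (lo + hi))
    mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)

    pixels = np.full((size, size), BACKGROUND_LEVEL)
    pixels[mask] = OBJECT_LEVEL
    return pixels, mask
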