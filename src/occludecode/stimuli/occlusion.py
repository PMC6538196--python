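"""Circular occluders: coverage measurement and iterative placement."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from skimage import draw as skdraw

from .._rng import child_rng
from ..errors import ConfigurationError, ConvergenceError
from .shapes import BACKGROUND_LEVEL, OBJECT_LEVEL, OCCLUDER_LEVEL

__all__ = ["Circle", "OccluderConfig", "occlusion_fraction", "place_occluders",
           "compose_image"]


@dataclass(frozen=True)
class Circle:
    x: int
    y: int
    radius: int
    depth: str  # "front" or "back"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("circle radius must be positive")
        if self.depth not in ("front", "back"):
            raise ConfigurationError("depth must be 'front' or 'back'")


@dataclass
class OccluderConfig:
    """Black circles placed in front of and behind the target object."""

    circles: List[Circle] = field(default_factory=list)
    canvas_size: int = 256

    def __post_init__(self) -> None:
        for c in self.circles:
            if not (0 <= c.x < self.canvas_size and 0 <= c.y < self.canvas_size):
                raise ConfigurationError(f"circle center ({c.x}, {c.y}) outside canvas")

    def front_mask(self) -> np.ndarray:
        return self._mask("front")

    def back_mask(self) -> np.ndarray:
        return self._mask("back")

    def _mask(self, depth: str) -> np.ndarray:
        m = np.zeros((self.canvas_size, self.canvas_size), dtype=bool)
        for c in self.circles:
            if c.depth == depth:
                rr, cc = skdraw.disk((c.y, c.x), c.radius, shape=m.shape)
                m[rr, cc] = True
        return m


def occlusion_fraction(object_mask: np.ndarray, occluders: OccluderConfig) -> float:
    """Fraction of object pixels covered by at least one *front* circle.

    Back circles are drawn behind the object and never cover it.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    n_obj = int(object_mask.sum())
    if n_obj == 0:
        raise ConfigurationError("empty object mask")
    covered = object_mask & occluders.front_mask()
    return float(covered.sum()) / n_obj


def place_occluders(
    object_mask: np.ndarray,
    target_fraction: float,
    tolerance: float = 0.02,
    seed: int = 0,
    radius_range: Tuple[int, int] = (8, 40),
    max_iterations: int = 200,
) -> OccluderConfig:
    """Iteratively sample random circles until the measured occlusion
    fraction is within ``tolerance`` of the target.

    Circles get a uniform random radius, position and depth. A candidate
    circle that overshoots the target is discarded and re-sampled. For a
    target of 0, front circles overlapping the object are rejected, so the
    object is surrounded by occluders that never cover it (at least one
    circle is always placed).
    """
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be positive")
    if not (0.0 <= target_fraction < 1.0):
        raise ConfigurationError("target_fraction must lie in [0, 1)")
    object_mask = np.asarray(object_mask, dtype=bool)
    if not object_mask.any():
        raise ConfigurationError("empty object mask")
    size = object_mask.shape[0]
    rng = child_rng(seed, 20)
    cfg = OccluderConfig(circles=[], canvas_size=size)

    # back circles are decorative (never affect coverage); a few everywhere
    for _ in range(int(rng.integers(2, 6))):
        cfg.circles.append(Circle(
            x=int(rng.integers(0, size)), y=int(rng.integers(0, size)),
            radius=int(rng.integers(radius_range[0], radius_range[1] + 1)),
            depth="back"))

    if target_fraction == 0.0:
        # surround the object with front circles that never touch it; the
        # budget matches typical occluded-image circle counts so the levels
        # stay balanced in gross low-level statistics
        placed = 0
        wanted = int(rng.integers(4, 11))
        for _ in range(max_iterations):
            if placed >= wanted:
                return cfg
            r = int(rng.integers(radius_range[0], radius_range[1] + 1))
            x, y = int(rng.integers(0, size)), int(rng.integers(0, size))
            rr, cc = skdraw.disk((y, x), r, shape=object_mask.shape)
            if object_mask[rr, cc].any():
                continue
            cfg.circles.append(Circle(x, y, r, "front"))
            placed += 1
        raise ConvergenceError(
            f"could not place non-covering front circles within "
            f"{max_iterations} iterations")

    n_obj = int(object_mask.sum())
    obj_rows, obj_cols = np.nonzero(object_mask)
    covered = np.zeros_like(object_mask)
    frac = 0.0
    for _ in range(max_iterations):
        if abs(frac - target_fraction) <= tolerance:
            return cfg
        # adapt the radius to the remaining uncovered object area so late
        # iterations can still make accepted progress
        need = (target_fraction + tolerance - frac) * n_obj
        r_hi = int(np.clip(np.sqrt(need / np.pi) * 1.5, radius_range[0],
                           radius_range[1]))
        r = int(rng.integers(radius_range[0], r_hi + 1))
        # aim near the object so circles actually intersect it
        k = int(rng.integers(n_obj))
        x = int(np.clip(obj_cols[k] + rng.integers(-r, r + 1), 0, size - 1))
        y = int(np.clip(obj_rows[k] + rng.integers(-r, r + 1), 0, size - 1))
        rr, cc = skdraw.disk((y, x), r, shape=object_mask.shape)
        hit = np.zeros_like(object_mask)
        hit[rr, cc] = True
        new_covered = covered | (hit & object_mask)
        new_frac = new_covered.sum() / n_obj
        if new_frac > target_fraction + tolerance:
            continue  # overshoot: discard and re-sample
        cfg.circles.append(Circle(x, y, r, "front"))
        covered = new_covered
        frac = new_frac

    raise ConvergenceError(
        f"failed to reach occlusion {target_fraction:.2f} ± {tolerance:.2f} "
        f"within {max_iterations} iterations (last fraction {frac:.3f}, "
        f"{len(cfg.circles)} circles)")


def compose_image(object_mask: np.ndarray, occluders: OccluderConfig) -> np.ndarray:
    """Render background, back circles, object, then front circles."""
    size = object_mask.shape[0]
    img = np.full((size, size), BACKGROUND_LEVEL)
    img[occluders.back_mask()] = OCCLUDER_LEVEL
    img[np.asarray(object_mask, dtype=bool)] = OBJECT_LEVEL
    img[occluders.front_mask()] = OCCLUDER_LEVEL
    return img
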