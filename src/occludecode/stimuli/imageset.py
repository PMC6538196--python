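"""Full image-set generation with low-level-feature rejection loop."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

from .._rng import child_rng
from ..errors import ConfigurationError, ConvergenceError
from .control import LowLevelCheckResult, lowlevel_control_check
from .occlusion import OccluderConfig, compose_image, occlusion_fraction, place_occluders
from .shapes import CATEGORIES, JITTER_MAX, render_object

__all__ = ["StimulusImage", "ImageSetSettings", "generate_image_set", "save_image_set"]


@dataclass
class StimulusImage:
    pixels: np.ndarray
    object_mask: np.ndarray
    category: str
    occlusion_level_nominal: int  # percent
    occluders: OccluderConfig
    jitter: Tuple[int, int]
    measured_fraction: float


@dataclass(frozen=True)
class ImageSetSettings:
    m_per_condition: int = 4
    occlusion_levels: Tuple[int, ...] = (0, 60, 80)
    categories: Tuple[str, ...] = CATEGORIES
    tolerance: float = 0.02
    jitter_max: int = JITTER_MAX
    size: int = 256
    radius_range: Tuple[int, int] = (8, 40)
    max_placement_iterations: int = 200
    run_control_check: bool = True
    max_regenerations: int = 5

    def __post_init__(self) -> None:
        if self.m_per_condition <= 0:
            raise ConfigurationError("m_per_condition must be positive")


@dataclass
class ImageSet:
    images: List[StimulusImage]
    settings: ImageSetSettings
    seed: int
    control_check: Optional[LowLevelCheckResult] = None

    @property
    def n_conditions(self) -> int:
        return len({(im.category, im.occlusion_level_nominal) for im in self.images})


def _build_once(settings: ImageSetSettings, seed: int) -> ImageSet:
    images = []
    for li, level in enumerate(settings.occlusion_levels):
        for ci, cat in enumerate(settings.categories):
            for m in range(settings.m_per_condition):
                rng = child_rng(seed, 30, li, ci, m)
                jitter = tuple(int(v) for v in
                               rng.integers(-settings.jitter_max,
                                            settings.jitter_max + 1, size=2))
                _, mask = render_object(cat, jitter=jitter, size=settings.size)
                occ = place_occluders(
                    mask, level / 100.0, tolerance=settings.tolerance,
                    seed=int(rng.integers(2 ** 31)),
                    radius_range=settings.radius_range,
                    max_iterations=settings.max_placement_iterations)
                images.append(StimulusImage(
                    pixels=compose_image(mask, occ),
                    object_mask=mask,
                    category=cat,
                    occlusion_level_nominal=level,
                    occluders=occ,
                    jitter=jitter,
                    measured_fraction=occlusion_fraction(mask, occ)))
    return ImageSet(images=images, settings=settings, seed=seed)


def generate_image_set(settings: ImageSetSettings, seed: int) -> ImageSet:
    """Generate categories × occlusion levels × M images.

    When the low-level control check is enabled the whole set is regenerated
    with a fresh seed until Gabor/Gist features cannot discriminate the
    occlusion levels above chance (95% binomial CI containing chance); the
    final check result is attached to the set.
    """
    last = None
    for attempt in range(settings.max_regenerations):
        s = _build_once(settings, seed + attempt)
        if not settings.run_control_check or len(settings.occlusion_levels) < 2:
            return s
        check = lowlevel_control_check(
            [im.pixels for im in s.images],
            [im.occlusion_level_nominal for im in s.images],
            seed=seed + attempt)
        s.control_check = check
        if check.passed:
            return s
        last = check
    raise ConvergenceError(
        f"low-level control check failed after {settings.max_regenerations} "
        f"regenerations (last accuracy {last.accuracy:.3f}, "
        f"CI [{last.ci_low:.3f}, {last.ci_high:.3f}], chance {last.chance:.3f})")


def save_image_set(s: ImageSet, out_dir) -> None:
    """PNG per image plus a JSON sidecar with full provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, im in enumerate(s.images):
        stem = f"{im.category}_occ{im.occlusion_level_nominal}_{i:04d}"
        Image.fromarray((im.pixels * 255).astype(np.uint8)).save(out / f"{stem}.png")
        meta = {
            "category": im.category,
            "occlusion_level_nominal": im.occlusion_level_nominal,
            "jitter": list(im.jitter),
            "measured_fraction": im.measured_fraction,
            "circles": [
                {"x": c.x, "y": c.y, "radius": c.radius, "depth": c.depth}
                for c in im.occluders.circles
            ],
        }
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    if s.control_check is not None:
        (out / "control_check.json").write_text(json.dumps({
            "accuracy": s.control_check.accuracy,
            "chance": s.control_check.chance,
            "ci": [s.control_check.ci_low, s.control_check.ci_high],
            "passed": s.control_check.passed,
        }, indent=1))
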