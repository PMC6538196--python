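"""Pairwise decoding curves, condition-set time-courses, sensor-group maps."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np

from .._rng import child_rng
from ..errors import ConfigurationError
from ..synthgen.generator import EpochedDataset, SensorLayout
from .kernels import decode_curve_kernel
from .params import DecodingParams

logger = logging.getLogger(__name__)

__all__ = ["DecodingCurve", "SensorMap", "pairwise_decode", "decode_timecourse",
           "sensorwise_decode", "object_pairs"]

_STREAM_HOLDOUT = 7


@dataclass
class DecodingCurve:
    """Per-subject decoding accuracy over time, in percent (chance 50)."""

    accuracy: np.ndarray  # (subject, time)
    time_ms: np.ndarray
    label: str
    n_repetitions: int
    chance: float = 50.0

    def group_mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)


@dataclass
class SensorMap:
    """Per-subject, per-sensor-group decoding accuracy over time (percent)."""

    accuracy: np.ndarray  # (subject, group, time)
    time_ms: np.ndarray
    label: str
    n_repetitions: int
    chance: float = 50.0

    def peak_group(self) -> np.ndarray:
        """Group with the highest subject-mean accuracy at each time point."""
        return self.accuracy.mean(axis=0).argmax(axis=0)


def _holdouts(params: DecodingParams, subject: int, ca: int, cb: int,
              n: int) -> Tuple[np.ndarray, np.ndarray]:
    lo, hi = min(ca, cb), max(ca, cb)
    rng = child_rng(params.seed, _STREAM_HOLDOUT, subject, lo, hi)
    return (rng.integers(0, n, size=params.n_repetitions),
            rng.integers(0, n, size=params.n_repetitions))


def _pair_data(ds: EpochedDataset, ca: int, cb: int, window: slice,
               sensors: Optional[np.ndarray] = None
               ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Windowed float64 views for one condition pair; truncates to the
    minimum trial count if they differ (logged, never resampled)."""
    xa = ds.data[:, ca]
    xb = ds.data[:, cb]
    na, nb = xa.shape[1], xb.shape[1]
    n = min(na, nb)
    if na != nb:
        logger.warning("trial counts differ (%d vs %d); truncating to %d", na, nb, n)
    xa, xb = xa[:, :n], xb[:, :n]
    if sensors is not None:
        xa, xb = xa[:, :, sensors], xb[:, :, sensors]
    return (np.ascontiguousarray(xa[..., window], dtype=np.float64),
            np.ascontiguousarray(xb[..., window], dtype=np.float64), n)


def pairwise_decode(ds: EpochedDataset, condition_a: int, condition_b: int,
                    params: DecodingParams = DecodingParams(),
                    sensors: Optional[np.ndarray] = None) -> DecodingCurve:
    """Pairwise decoding accuracy per subject and time point.

    Symmetric in its condition arguments: the class labeling and hold-out
    draws are keyed by the unordered pair.
    """
    if condition_a == condition_b:
        raise ConfigurationError("cannot decode a condition against itself")
    # canonical orientation so (a, b) and (b, a) run identically
    ca, cb = min(condition_a, condition_b), max(condition_a, condition_b)
    window = ds.time_slice(*params.window_ms)
    xa_all, xb_all, n = _pair_data(ds, ca, cb, window, sensors)
    if n < 2:
        raise ConfigurationError(f"need >= 2 trials per condition, got {n}")

    n_subj = ds.n_subjects
    t_axis = ds.time_ms[window]
    acc = np.empty((n_subj, t_axis.size))
    for s in range(n_subj):
        hoa, hob = _holdouts(params, s, ca, cb, n)
        acc[s] = decode_curve_kernel(
            xa_all[s], xb_all[s], hoa, hob, params.C,
            params.max_epochs, params.tol, params.standardize)
    return DecodingCurve(accuracy=100.0 * acc, time_ms=t_axis,
                         label=f"cond{ca}-vs-cond{cb}",
                         n_repetitions=params.n_repetitions)


def object_pairs(ds: EpochedDataset, occlusion_level: int,
                 mask_state: str = "no_mask") -> List[Tuple[int, int]]:
    """The C(4,2)=6 object-pair condition index pairs at one level."""
    cond = ds.conditions_at(occlusion_level, mask_state)
    objects = sorted(cond)
    if len(objects) < 2:
        raise ConfigurationError(
            f"no conditions found at occlusion={occlusion_level}, mask={mask_state!r}")
    expected = set(ds.condition_table["object"].unique())
    if set(objects) != expected:
        raise ConfigurationError(
            f"missing object conditions at occlusion={occlusion_level}: "
            f"have {objects}, expected {sorted(expected)}")
    return [(cond[a], cond[b]) for a, b in combinations(objects, 2)]


def decode_timecourse(ds: EpochedDataset, occlusion_level: int,
                      mask_state: str = "no_mask",
                      params: DecodingParams = DecodingParams()) -> DecodingCurve:
    """Mean of the six pairwise object-decoding curves at one
    (occlusion, mask) level."""
    pairs = object_pairs(ds, occlusion_level, mask_state)
    curves = [pairwise_decode(ds, ca, cb, params) for ca, cb in pairs]
    acc = np.mean([c.accuracy for c in curves], axis=0)
    return DecodingCurve(accuracy=acc, time_ms=curves[0].time_ms,
                         label=f"occ{occlusion_level}-{mask_state}",
                         n_repetitions=params.n_repetitions)


def sensorwise_decode(ds: EpochedDataset, layout: Optional[SensorLayout] = None,
                      params: DecodingParams = DecodingParams(),
                      occlusion_level: int = 0,
                      mask_state: str = "no_mask") -> SensorMap:
    """Pairwise decoding restricted to each sensor group's 3 features,
    averaged over the six object pairs."""
    layout = layout or ds.sensor_layout
    if layout.group_size != 3:
        raise ConfigurationError("sensorwise decoding expects triplet groups")
    if layout.n_sensors != ds.data.shape[3]:
        raise ConfigurationError("layout does not match dataset sensor count")
    pairs = object_pairs(ds, occlusion_level, mask_state)
    window = ds.time_slice(*params.window_ms)
    t_axis = ds.time_ms[window]
    acc = np.zeros((ds.n_subjects, layout.n_groups, t_axis.size))
    for g in range(layout.n_groups):
        sensors = layout.sensors_of_group(g)
        for ca, cb in pairs:
            xa, xb, n = _pair_data(ds, ca, cb, window, sensors)
            for s in range(ds.n_subjects):
                hoa, hob = _holdouts(params, s, ca, cb, n)
                acc[s, g] += decode_curve_kernel(
                    xa[s], xb[s], hoa, hob, params.C,
                    params.max_epochs, params.tol, params.standardize)
    acc *= 100.0 / len(pairs)
    return SensorMap(accuracy=acc, time_ms=t_axis,
                     label=f"sensorwise-occ{occlusion_level}-{mask_state}",
                     n_repetitions=params.n_repetitions)
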