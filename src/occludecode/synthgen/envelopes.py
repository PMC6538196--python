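"""Condition response envelopes.

Each (occlusion, mask) condition is assigned a temporal envelope that gates
the class-discriminative sensor pattern: zero before onset, a smooth rise to
a maximum exactly at the peak, exponential decay afterwards, and an optional
hard truncation modelling backward masking of the late response component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import ConfigurationError

__all__ = ["ConditionEnvelope", "envelope_value", "default_envelopes"]

#: Width (ms) of the cosine roll-off applied just before a mask truncation,
#: so the truncated envelope does not end in a step discontinuity.
TRUNCATION_ROLLOFF_MS = 20.0

CODE_MODES = ("sequential", "sustained_after_onset", "sequential_then_sustained")


@dataclass(frozen=True)
class ConditionEnvelope:
    """Parametric response envelope for one (occlusion, mask) condition.

    Attributes
    ----------
    onset_ms, peak_ms
        Envelope is zero before ``onset_ms`` and maximal exactly at
        ``peak_ms``.
    decay_tau_ms
        Exponential decay constant after the peak.
    amplitude
        Peak envelope value (arbitrary field-like units).
    code_mode
        How the spatial pattern evolves under this envelope: ``sequential``
        (pattern chain switching every dwell period, yielding diagonal
        temporal generalization), ``sustained_after_onset`` (one pattern held
        from onset), or ``sequential_then_sustained`` (chain early, a single
        held pattern in a late window, yielding off-diagonal generalization).
    mask_truncation_ms
        If set, the envelope is forced to zero for times beyond this value.
    """

    onset_ms: float
    peak_ms: float
    decay_tau_ms: float = 120.0
    amplitude: float = 1.0
    code_mode: str = "sequential"
    mask_truncation_ms: Optional[float] = None
    #: rise-shape exponent: the slow component climbs as
    #: ((t - onset)/(peak - onset)) ** rise_gamma; values < 1 make the
    #: response detectable within a few ms of onset
    rise_gamma: float = 0.3
    #: relative weight of a narrow Gaussian component centered at the peak;
    #: it localizes the envelope maximum so that smoothing and the
    #: saturating accuracy link do not displace the argmax
    peak_bump_frac: float = 0.5
    peak_bump_sd_ms: float = 15.0

    def __post_init__(self) -> None:
        if not self.onset_ms < self.peak_ms:
            raise ConfigurationError(
                f"onset_ms ({self.onset_ms}) must be earlier than peak_ms ({self.peak_ms})"
            )
        if self.decay_tau_ms <= 0:
            raise ConfigurationError("decay_tau_ms must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")
        if self.rise_gamma <= 0:
            raise ConfigurationError("rise_gamma must be positive")
        if self.code_mode not in CODE_MODES:
            raise ConfigurationError(
                f"code_mode must be one of {CODE_MODES}, got {self.code_mode!r}"
            )


def envelope_value(env: ConditionEnvelope, t_ms) -> np.ndarray:
    """Evaluate the envelope at time(s) ``t_ms`` (vectorized, total function).

    Zero before onset. The rising flank is a power law (exponent
    ``rise_gamma``, steep right after onset); the decay is exponential with
    ``decay_tau_ms``; a narrow Gaussian component of relative weight
    ``peak_bump_frac`` rides on top, centered at ``peak_ms``, so the
    maximum sits exactly at the peak and stays well localized. Zero beyond
    ``mask_truncation_ms`` when set, with a short cosine roll-off ending at
    the truncation time.
    """
    t = np.asarray(t_ms, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    base = np.zeros_like(t)
    rise = (t >= env.onset_ms) & (t <= env.peak_ms)
    u = (t[rise] - env.onset_ms) / (env.peak_ms - env.onset_ms)
    base[rise] = u ** env.rise_gamma
    fall = t > env.peak_ms
    base[fall] = np.exp(-(t[fall] - env.peak_ms) / env.decay_tau_ms)

    bump = np.exp(-0.5 * ((t - env.peak_ms) / env.peak_bump_sd_ms) ** 2)
    bump[t < env.onset_ms] = 0.0
    out = (base + env.peak_bump_frac * bump) / (1.0 + env.peak_bump_frac)
    out[t < env.onset_ms] = 0.0
    out *= env.amplitude

    if env.mask_truncation_ms is not None:
        tr = float(env.mask_truncation_ms)
        out[t > tr] = 0.0
        roll = (t > tr - TRUNCATION_ROLLOFF_MS) & (t <= tr)
        phase = (t[roll] - (tr - TRUNCATION_ROLLOFF_MS)) / TRUNCATION_ROLLOFF_MS
        out[roll] *= 0.5 * (1.0 + np.cos(np.pi * phase))

    return out[0] if scalar else out


def envelope_phase(env: ConditionEnvelope, t_ms) -> np.ndarray:
    """Normalized position within the envelope's rise: (t - onset)/(peak - onset).

    Occluded conditions re-use the unoccluded pattern chain through this
    phase variable, so a delayed + time-dilated envelope accesses the same
    chain elements later and more slowly (delayed-copy dynamics).
    """
    t = np.asarray(t_ms, dtype=float)
    return (t - env.onset_ms) / (env.peak_ms - env.onset_ms)


def default_envelopes(
    amplitude: float = 1.0,
    weak_amplitude_scale: float = 0.15,
    mask_truncation_ms: float = 160.0,
) -> dict:
    """Default envelope presets keyed by ``(occlusion_percent, mask_state)``.

    Unoccluded responses onset at 79 ms and peak at 139 ms with a sequential
    pattern code; 60%-occluded responses are the delayed (+44 ms) and
    time-dilated copy, onset 123 ms / peak 199 ms, with late sustained
    coding; 80%-occluded responses share the 60% dynamics at an amplitude
    too weak for group-level decoding at default noise. Masking truncates
    the late (>~150 ms) component and leaves unoccluded responses untouched.
    """
    # decay_tau ≈ rise_duration / rise_gamma balances the flanks around the peak
    unocc = ConditionEnvelope(79.0, 139.0, decay_tau_ms=150.0, amplitude=1.3 * amplitude,
                              code_mode="sequential")
    occ60 = ConditionEnvelope(123.0, 199.0, decay_tau_ms=190.0, amplitude=1.1 * amplitude,
                              code_mode="sequential_then_sustained")
    occ80 = ConditionEnvelope(123.0, 199.0, decay_tau_ms=190.0,
                              amplitude=1.1 * amplitude * weak_amplitude_scale,
                              code_mode="sequential_then_sustained")
    return {
        (0, "no_mask"): unocc,
        (60, "no_mask"): occ60,
        (80, "no_mask"): occ80,
        # mask has no effect without occlusion
        (0, "mask"): unocc,
        (60, "mask"): ConditionEnvelope(123.0, 199.0, decay_tau_ms=190.0,
                                        amplitude=1.1 * amplitude,
                                        code_mode="sequential_then_sustained",
                                        mask_truncation_ms=mask_truncation_ms),
        (80, "mask"): ConditionEnvelope(123.0, 199.0, decay_tau_ms=190.0,
                                        amplitude=1.1 * amplitude * weak_amplitude_scale,
                                        code_mode="sequential_then_sustained",
                                        mask_truncation_ms=mask_truncation_ms),
    }
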