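"""Multi-subject epoched sensor-space data generator.

The class-discriminative signal for a condition is the outer product of an
object-specific spatial sensor pattern and that condition's temporal
envelope, embedded in temporally autocorrelated noise whose statistics are
identical across conditions. Objects are encoded by chains of patterns so
that sequential vs sustained codes produce diagonal vs off-diagonal
temporal-generalization signatures, and occluded conditions re-use the
unoccluded chain through a delayed, time-dilated envelope phase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .._rng import child_rng
from ..errors import ConfigurationError
from .envelopes import ConditionEnvelope, default_envelopes, envelope_value, envelope_phase

__all__ = [
    "SensorLayout",
    "GeneratorSettings",
    "EpochedDataset",
    "generate_epochs",
    "split_half",
    "desk_settings",
    "paper_settings",
]

OBJECTS = ("camel", "deer", "car", "motor")
OCCLUSIONS = (0, 60, 80)
MASK_STATES = ("no_mask", "mask")

# rng stream ids for seed fan-out
_STREAM_PATTERN = 0
_STREAM_JITTER = 1
_STREAM_NOISE = 2
_STREAM_SPLIT = 3


@dataclass(frozen=True)
class SensorLayout:
    """Sensors partitioned into co-located groups (triplets for real MEG)."""

    n_sensors: int
    group_size: int = 3

    def __post_init__(self) -> None:
        if self.n_sensors <= 0 or self.group_size <= 0:
            raise ConfigurationError("n_sensors and group_size must be positive")
        if self.n_sensors % self.group_size != 0:
            raise ConfigurationError(
                f"n_sensors ({self.n_sensors}) not divisible by group_size ({self.group_size})"
            )

    @property
    def n_groups(self) -> int:
        return self.n_sensors // self.group_size

    @property
    def group_index(self) -> np.ndarray:
        """Group id of every sensor (disjoint, exhaustive, consecutive)."""
        return np.repeat(np.arange(self.n_groups), self.group_size)

    def sensors_of_group(self, g: int) -> np.ndarray:
        return np.arange(g * self.group_size, (g + 1) * self.group_size)


@dataclass(frozen=True)
class GeneratorSettings:
    """Full specification of the synthetic dataset.

    Noise parameters are free knobs of this generator, not quantities the
    analyses estimate; they are chosen so group nonparametric inference is
    well powered at the documented scales.
    """

    n_subjects: int = 15
    n_trials_per_condition: int = 64
    n_sensors: int = 306
    group_size: int = 3
    sample_rate_hz: float = 1000.0
    t_start_ms: float = -200.0
    t_end_ms: float = 700.0
    objects: Tuple[str, ...] = OBJECTS
    occlusions: Tuple[int, ...] = OCCLUSIONS
    mask_states: Tuple[str, ...] = MASK_STATES
    envelopes: Optional[Dict[Tuple[int, str], ConditionEnvelope]] = None
    snr: float = 1.0
    n_active_groups: int = 12
    code_dwell_ms: float = 20.0
    chain_length: int = 32
    sustain_start_ms: float = 150.0
    sustain_end_ms: float = 300.0
    ar_rho_at_1khz: float = 0.9
    white_noise_sd: float = 0.3
    subject_jitter_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_condition <= 0:
            raise ConfigurationError("n_subjects and n_trials_per_condition must be positive")
        if self.snr < 0:
            raise ConfigurationError("snr must be non-negative")
        if len(set(self.objects)) < 2:
            raise ConfigurationError("need at least two object categories")
        if not self.occlusions or not self.mask_states:
            raise ConfigurationError("occlusions and mask_states must be non-empty")
        env = self.resolved_envelopes()
        for occ in self.occlusions:
            for m in self.mask_states:
                if (occ, m) not in env:
                    raise ConfigurationError(
                        f"missing envelope for condition (occlusion={occ}, mask={m!r}); "
                        "the factorial must be fully specified"
                    )
        SensorLayout(self.n_sensors, self.group_size)  # validates divisibility

    def resolved_envelopes(self) -> Dict[Tuple[int, str], ConditionEnvelope]:
        return self.envelopes if self.envelopes is not None else default_envelopes()

    @property
    def layout(self) -> SensorLayout:
        return SensorLayout(self.n_sensors, self.group_size)

    @property
    def time_ms(self) -> np.ndarray:
        step = 1000.0 / self.sample_rate_hz
        n = int(round((self.t_end_ms - self.t_start_ms) / step)) + 1
        return self.t_start_ms + step * np.arange(n)

    @property
    def n_conditions(self) -> int:
        return len(self.objects) * len(self.occlusions) * len(self.mask_states)

    @property
    def shape(self) -> Tuple[int, int, int, int, int]:
        """(subject, condition, trial, sensor, time) without materializing."""
        return (
            self.n_subjects,
            self.n_conditions,
            self.n_trials_per_condition,
            self.n_sensors,
            self.time_ms.size,
        )

    def condition_table(self) -> pd.DataFrame:
        rows = [
            {"object": obj, "occlusion": occ, "mask": m}
            for m in self.mask_states
            for occ in self.occlusions
            for obj in self.objects
        ]
        return pd.DataFrame(rows)

    def replace(self, **kw) -> "GeneratorSettings":
        return dataclasses.replace(self, **kw)


@dataclass
class EpochedDataset:
    """Epoched trials: (subject, condition, trial, sensor, time) plus metadata."""

    data: np.ndarray
    time_ms: np.ndarray
    sample_rate_hz: float
    condition_table: pd.DataFrame
    sensor_layout: SensorLayout
    seed: int

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ConfigurationError("data must be 5-dimensional")
        if self.data.shape[4] != self.time_ms.size:
            raise ConfigurationError("time axis length mismatch")
        if self.data.shape[1] != len(self.condition_table):
            raise ConfigurationError("condition axis length mismatch")
        if self.data.shape[3] != self.sensor_layout.n_sensors:
            raise ConfigurationError("sensor axis length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def condition_index(self, obj: str, occlusion: int, mask: str = "no_mask") -> int:
        tab = self.condition_table
        hit = tab.index[
            (tab["object"] == obj) & (tab["occlusion"] == occlusion) & (tab["mask"] == mask)
        ]
        if len(hit) != 1:
            raise KeyError(f"condition (object={obj!r}, occlusion={occlusion}, mask={mask!r})")
        return int(hit[0])

    def conditions_at(self, occlusion: int, mask: str = "no_mask") -> Dict[str, int]:
        """Object → condition index for one (occlusion, mask) cell."""
        tab = self.condition_table
        sel = tab[(tab["occlusion"] == occlusion) & (tab["mask"] == mask)]
        return {row["object"]: int(i) for i, row in sel.iterrows()}

    def time_slice(self, t_min_ms: float, t_max_ms: float) -> slice:
        t = self.time_ms
        if t_min_ms < t[0] - 1e-9 or t_max_ms > t[-1] + 1e-9:
            raise ConfigurationError(
                f"window [{t_min_ms}, {t_max_ms}] ms outside data range [{t[0]}, {t[-1]}] ms"
            )
        i0 = int(np.searchsorted(t, t_min_ms - 1e-9))
        i1 = int(np.searchsorted(t, t_max_ms + 1e-9))
        return slice(i0, i1)


def _pattern_chain(rng: np.random.Generator, n_sensors: int, active: np.ndarray,
                   chain_length: int) -> np.ndarray:
    """Chain of unit-norm sensor patterns supported on the active sensors."""
    chain = np.zeros((chain_length, n_sensors))
    vals = rng.standard_normal((chain_length, active.size))
    vals /= np.linalg.norm(vals, axis=1, keepdims=True)
    chain[:, active] = vals
    return chain


def _chain_positions(env: ConditionEnvelope, t_ms: np.ndarray, dwell_ms: float,
                     rise_ms_ref: float, sustain: Tuple[float, float],
                     chain_length: int) -> np.ndarray:
    """Continuous chain position per time point (NaN where envelope is zero).

    Chain position is driven by envelope phase so that delayed/dilated
    envelopes traverse the same chain later and more slowly; the pattern is
    crossfaded between consecutive chain elements (one element per dwell
    period) so the sensor-space signal evolves without discontinuities.
    Sustained modes freeze the position over the configured window.
    """
    phase = envelope_phase(env, t_ms)
    pos = np.clip(phase * rise_ms_ref / dwell_ms, 0.0, chain_length - 1.0)
    if env.code_mode == "sustained_after_onset":
        pos[:] = 0.0
    elif env.code_mode == "sequential_then_sustained":
        s0, s1 = sustain
        if s0 >= env.onset_ms:
            held = float(np.clip(
                envelope_phase(env, np.asarray(s0)) * rise_ms_ref / dwell_ms,
                0.0, chain_length - 1.0))
            hold = (t_ms >= s0) & (t_ms <= s1)
            pos[hold] = held
    dead = (envelope_value(env, t_ms) <= 0) | (t_ms < env.onset_ms)
    pos[dead] = np.nan
    return pos


def _blend_patterns(chain: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Unit-norm crossfade through the chain: (n_sensors, n_t); zero where
    the position is NaN."""
    n_t = pos.size
    out = np.zeros((chain.shape[1], n_t))
    act = ~np.isnan(pos)
    if not act.any():
        return out
    p = pos[act]
    i0 = np.floor(p).astype(int)
    i1 = np.minimum(i0 + 1, chain.shape[0] - 1)
    f = (p - i0)[:, None]
    blend = (1.0 - f) * chain[i0] + f * chain[i1]
    norms = np.linalg.norm(blend, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out[:, act] = (blend / norms).T
    return out


def generate_epochs(config: GeneratorSettings, seed: int) -> EpochedDataset:
    """Generate a deterministic synthetic epoched dataset.

    Signal model per (subject, condition, trial):
    ``snr * envelope(t) * pattern(subject, object, chain(t))`` plus AR(1)
    temporal noise (unit marginal SD) and white sensor noise — the noise is
    drawn identically for every condition.
    """
    layout = config.layout
    time_ms = config.time_ms
    n_t = time_ms.size
    table = config.condition_table()
    envelopes = config.resolved_envelopes()

    n_groups_active = min(config.n_active_groups, layout.n_groups)
    active_groups = np.arange(n_groups_active)
    active_sensors = np.concatenate([layout.sensors_of_group(g) for g in active_groups])

    pat_rng = child_rng(seed, _STREAM_PATTERN)
    base_chains = {
        obj: _pattern_chain(pat_rng, layout.n_sensors, active_sensors, config.chain_length)
        for obj in config.objects
    }

    # reference rise duration: the unoccluded (first occlusion level) envelope
    ref_env = envelopes[(config.occlusions[0], config.mask_states[0])]
    rise_ref = ref_env.peak_ms - ref_env.onset_ms

    # precompute per-condition envelope values and chain positions
    env_vals = np.zeros((len(table), n_t))
    chain_pos = np.zeros((len(table), n_t))
    for c, row in table.iterrows():
        env = envelopes[(row["occlusion"], row["mask"])]
        env_vals[c] = envelope_value(env, time_ms)
        chain_pos[c] = _chain_positions(
            env, time_ms, config.code_dwell_ms, rise_ref,
            (config.sustain_start_ms, config.sustain_end_ms), config.chain_length,
        )

    step_ms = 1000.0 / config.sample_rate_hz
    rho = config.ar_rho_at_1khz ** step_ms
    ar_innov_sd = np.sqrt(1.0 - rho * rho)

    shape = config.shape
    data = np.empty(shape, dtype=np.float32)

    for s in range(config.n_subjects):
        jit_rng = child_rng(seed, _STREAM_JITTER, s)
        chains = {}
        for obj in config.objects:
            base = base_chains[obj]
            jit = 1.0 + config.subject_jitter_sd * jit_rng.standard_normal(base.shape)
            pert = base * jit
            norms = np.linalg.norm(pert, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            chains[obj] = pert / norms

        for c, row in table.iterrows():
            chain = chains[row["object"]]
            sig = _blend_patterns(chain, chain_pos[c]) * env_vals[c][None, :]
            sig *= config.snr

            noise_rng = child_rng(seed, _STREAM_NOISE, s, c)
            innov = noise_rng.standard_normal(
                (config.n_trials_per_condition, layout.n_sensors, n_t))
            ar = np.empty_like(innov)
            ar[..., 0] = innov[..., 0]
            for t in range(1, n_t):
                ar[..., t] = rho * ar[..., t - 1] + ar_innov_sd * innov[..., t]
            white = config.white_noise_sd * noise_rng.standard_normal(ar.shape)
            data[s, c] = (sig[None] + ar + white).astype(np.float32)

    return EpochedDataset(
        data=data,
        time_ms=time_ms,
        sample_rate_hz=config.sample_rate_hz,
        condition_table=table,
        sensor_layout=layout,
        seed=int(seed),
    )


def split_half(ds: EpochedDataset, seed: int) -> Tuple[EpochedDataset, EpochedDataset]:
    """Randomly split every condition's trials into two disjoint halves."""
    m = ds.n_trials
    if m % 2 != 0:
        raise ConfigurationError(f"trial count per condition must be even, got {m}")
    rng = child_rng(seed, _STREAM_SPLIT)
    n_cond = ds.data.shape[1]
    half = m // 2
    idx_a = np.empty((n_cond, half), dtype=int)
    idx_b = np.empty((n_cond, half), dtype=int)
    for c in range(n_cond):
        perm = rng.permutation(m)
        idx_a[c] = np.sort(perm[:half])
        idx_b[c] = np.sort(perm[half:])

    def take(idx: np.ndarray) -> EpochedDataset:
        out = np.empty(
            (ds.data.shape[0], n_cond, half, ds.data.shape[3], ds.data.shape[4]),
            dtype=ds.data.dtype,
        )
        for c in range(n_cond):
            out[:, c] = ds.data[:, c, idx[c]]
        return EpochedDataset(
            data=out,
            time_ms=ds.time_ms,
            sample_rate_hz=ds.sample_rate_hz,
            condition_table=ds.condition_table.copy(),
            sensor_layout=ds.sensor_layout,
            seed=ds.seed,
        )

    return take(idx_a), take(idx_b)


def paper_settings(**overrides) -> GeneratorSettings:
    """Full-scale configuration: 15 subjects, 306 sensors, 64 trials, 1 kHz.

    Note the materialized array is ~25 GB; use this for shape/metadata
    contracts and generate at desk scale for actual computation.
    """
    return GeneratorSettings(**overrides)


def desk_settings(**overrides) -> GeneratorSettings:
    """CI-scale configuration: 8 subjects, 30 sensors, 16 trials/condition."""
    kw = dict(
        n_subjects=8,
        n_trials_per_condition=16,
        n_sensors=30,
        n_active_groups=4,
        sample_rate_hz=500.0,
        mask_states=("no_mask",),
    )
    kw.update(overrides)
    return GeneratorSettings(**kw)
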