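"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from occludecode.synthgen import (
    GeneratorSettings,
    desk_settings,
    generate_epochs,
)
from occludecode.synthgen.envelopes import ConditionEnvelope


def tiny_settings(**overrides) -> GeneratorSettings:
    """Very small dataset: 3 subjects, 6 sensors, 6 trials, 500 Hz."""
    kw = dict(
        n_subjects=3,
        n_trials_per_condition=6,
        n_sensors=6,
        n_active_groups=2,
        sample_rate_hz=500.0,
        mask_states=("no_mask",),
    )
    kw.update(overrides)
    return GeneratorSettings(**kw)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_epochs(tiny_settings(), seed=7)


@pytest.fixture(scope="session")
def tiny_null_dataset():
    """No class-discriminative signal at all."""
    return generate_epochs(tiny_settings(snr=0.0), seed=8)


@pytest.fixture(scope="session")
def small_image_set():
    from occludecode.stimuli import ImageSetSettings, generate_image_set

    return generate_image_set(
        ImageSetSettings(m_per_condition=2, size=128, run_control_check=False),
        seed=5,
    )


def strong_envelopes(code_mode: str = "sequential",
                     mask_truncation_ms=None) -> dict:
    """Single-level envelope dict with a clearly decodable response."""
    env = ConditionEnvelope(100.0, 160.0, decay_tau_ms=120.0, amplitude=3.0,
                            code_mode=code_mode,
                            mask_truncation_ms=mask_truncation_ms)
    return {(0, "no_mask"): env}
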