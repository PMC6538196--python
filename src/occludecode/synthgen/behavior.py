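"""Behavioral multiclass-recognition trial simulator.

Enumerates the full factorial design (repetitions × occlusion × mask ×
category) per subject, shuffles trials into equal blocks, draws responses
from a confusion model, and draws response times from a log-normal whose
location increases with occlusion level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .._rng import child_rng
from ..errors import ConfigurationError
from .generator import OBJECTS, OCCLUSIONS, MASK_STATES

__all__ = ["BehavioralSettings", "simulate_behavior"]


def _default_accuracy() -> Dict[Tuple[int, str], float]:
    return {
        (0, "no_mask"): 0.95, (60, "no_mask"): 0.85, (80, "no_mask"): 0.60,
        (0, "mask"): 0.93, (60, "mask"): 0.55, (80, "mask"): 0.40,
    }


def _default_rt_median() -> Dict[int, float]:
    # median RT (ms) increases with occlusion level
    return {0: 450.0, 60: 550.0, 80: 650.0}


@dataclass(frozen=True)
class BehavioralSettings:
    n_subjects: int = 15
    n_repetitions: int = 32
    n_blocks: int = 4
    objects: Tuple[str, ...] = OBJECTS
    occlusions: Tuple[int, ...] = OCCLUSIONS
    mask_states: Tuple[str, ...] = MASK_STATES
    accuracy: Dict[Tuple[int, str], float] = field(default_factory=_default_accuracy)
    rt_median_ms: Dict[int, float] = field(default_factory=_default_rt_median)
    rt_sigma: float = 0.2
    rt_mask_shift_ms: float = 0.0

    def __post_init__(self) -> None:
        chance = 1.0 / len(self.objects)
        for key, acc in self.accuracy.items():
            if not (chance <= acc <= 1.0):
                raise ConfigurationError(
                    f"accuracy for {key} must lie in [{chance}, 1], got {acc}"
                )
        n_trials = self.trials_per_subject
        if n_trials % self.n_blocks != 0:
            raise ConfigurationError(
                f"{n_trials} trials not divisible into {self.n_blocks} blocks"
            )

    @property
    def trials_per_subject(self) -> int:
        return (self.n_repetitions * len(self.occlusions)
                * len(self.mask_states) * len(self.objects))

    def rt_mu(self, occlusion: int, mask: str) -> float:
        """Log-normal location for one cell (log median)."""
        med = self.rt_median_ms[occlusion]
        if mask == "mask":
            med = med + self.rt_mask_shift_ms
        return float(np.log(med))

    def expected_rt_ms(self, occlusion: int, mask: str = "no_mask") -> float:
        """Closed-form mean of the configured log-normal."""
        return float(np.exp(self.rt_mu(occlusion, mask) + 0.5 * self.rt_sigma ** 2))


def simulate_behavior(config: BehavioralSettings, seed: int) -> pd.DataFrame:
    """Simulate the behavioral table for all subjects.

    Columns: subject, trial, block, object, occlusion, mask, response,
    correct, rt_ms. Trials are block-randomized per subject; incorrect
    responses are drawn uniformly from the other categories.
    """
    records = []
    objects = list(config.objects)
    n_other = len(objects) - 1

    for s in range(config.n_subjects):
        rng = child_rng(seed, 10, s)
        cells = [
            (obj, occ, m)
            for _ in range(config.n_repetitions)
            for occ in config.occlusions
            for m in config.mask_states
            for obj in objects
        ]
        order = rng.permutation(len(cells))
        block_size = len(cells) // config.n_blocks
        for trial_pos, cell_i in enumerate(order):
            obj, occ, m = cells[cell_i]
            acc = config.accuracy[(occ, m)]
            correct = bool(rng.random() < acc)
            if correct:
                response = obj
            else:
                others = [o for o in objects if o != obj]
                response = others[rng.integers(n_other)]
            rt = float(rng.lognormal(config.rt_mu(occ, m), config.rt_sigma))
            records.append({
                "subject": s,
                "trial": trial_pos,
                "block": trial_pos // block_size,
                "object": obj,
                "occlusion": occ,
                "mask": m,
                "response": response,
                "correct": correct,
                "rt_ms": rt,
            })
    return pd.DataFrame.from_records(records)
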