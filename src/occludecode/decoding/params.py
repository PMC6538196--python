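"""Decoding parameters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from ..errors import ConfigurationError


@dataclass(frozen=True)
class DecodingParams:
    """Parameters shared by all decoding operations.

    ``n_repetitions`` random single-trial hold-outs (one per condition per
    repetition) re-drawn from the master ``seed`` via a counter scheme keyed
    by (subject, pair), so any cell is reproducible in isolation.
    Features are standardized by training-fold mean/SD per time point
    (switchable) before the soft-margin linear classifier (C default 1).
    """

    n_repetitions: int = 100
    C: float = 1.0
    window_ms: Tuple[float, float] = (-100.0, 700.0)
    standardize: bool = True
    seed: int = 0
    max_epochs: int = 80
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_repetitions <= 0:
            raise ConfigurationError("n_repetitions must be positive")
        if self.C <= 0:
            raise ConfigurationError("C must be positive")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ConfigurationError("window_ms must be increasing")
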