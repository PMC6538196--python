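"""Counter-based seed fan-out.

A single master seed is expanded into independent child streams keyed by
small integer tuples (e.g. ``(subject, pair, repetition)``) so any unit of
work is reproducible in isolation, regardless of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Derive a child ``SeedSequence`` from a master seed and an integer key."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """A ``Generator`` seeded deterministically from ``(master_seed, *key)``."""
    return np.random.default_rng(child_seed(master_seed, *key))
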