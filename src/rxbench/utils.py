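"""Shared helpers: seeded random streams and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive an independent seed stream for a named pipeline stage.

    Each stage draws from its own stream keyed by (master seed, stage name),
    so adding or reordering stages never perturbs the randomness of the
    others.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(int(master_seed), spawn_key=(key,))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator bound to the stage's independent stream."""
    return np.random.default_rng(stage_seed(master_seed, stage))
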