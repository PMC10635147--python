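"""Deterministic per-stage random streams derived from one global seed."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(global_seed: int, stage: str) -> int:
    """A stable 31-bit seed for a named stage, derived from the global seed."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))
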