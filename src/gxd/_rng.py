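"""Deterministic per-stage random streams.

Every stochastic stage of the pipeline draws from its own substream derived
from ``(seed, stage_name)`` so that stages can be reordered, re-run or
parallelised without perturbing each other's draws.  The underlying bit
generator is NumPy's PCG64 via ``default_rng``; identical (seed, stage)
pairs give bit-identical streams on every platform.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for a named pipeline stage.

    The stage name is folded in through its CRC32 so the mapping is stable
    across processes (unlike ``hash``).
    """
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Generator for a named stage; ``extra`` integers select sub-runs."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode()), *[int(e) for e in extra]]
    )
    return np.random.default_rng(ss)
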