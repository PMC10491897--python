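"""Seeded random-number substreams.

All randomness in the package flows from a single integer seed through
named substreams, so that independent stages (cohort synthesis, solver,
permutation control) draw from non-overlapping, reproducible streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a master seed.

    The stream key is derived from a CRC32 of the name, so the same
    (seed, name) pair always yields the same stream and distinct names
    yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
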