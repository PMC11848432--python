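"""Deterministic named RNG substreams.

Every stage of the pipeline draws its randomness from a single run seed
through a named substream, so that adding randomness to one stage never
perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and a label."""
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    mixed = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])
    return int(mixed.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator seeded by ``seed`` and a stage label."""
    return np.random.default_rng(child_seed(seed, name))
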