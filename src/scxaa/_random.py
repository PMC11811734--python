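"""Deterministic seed-substream derivation.

Every source of randomness in the package derives a child generator from a
single top-level integer seed plus a stable sequence of string/int keys, so
re-running any stage in isolation reproduces it bit-exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
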