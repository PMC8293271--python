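"""Counter-style random-stream derivation.

All randomness in the package flows from one master integer seed. Child
streams are derived from (seed, *keys) where string keys are mapped to
integers with CRC32, so any subset of samples / metabolites / permutations
is reproducible in isolation and independent of evaluation order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *keys)``."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
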