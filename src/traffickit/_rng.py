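"""Seed-substream management.

All generators take one global integer seed; independent substreams for each
plate / sample / curve are derived from it with stable string keys so that a
subset of outputs can be regenerated without re-running everything else.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Keys are reduced to CRC32 words so the mapping is stable across runs and
    platforms (Python's ``hash`` is salted and unsuitable).
    """
    words = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))
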