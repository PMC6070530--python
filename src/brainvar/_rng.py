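"""Deterministic random-stream derivation.

All stochastic stages derive independent substreams from one master seed so
that results are invariant to the order in which strata, resampling
repetitions, or permutations are evaluated.  A substream is keyed by the
master seed plus an arbitrary tuple of integers/strings; string keys are
hashed with CRC32 so the derivation is stable across processes.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = (1 << 31) - 1


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & _MASK
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & _MASK
    raise TypeError(f"substream keys must be int or str, got {type(key)!r}")


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    Identical arguments always yield an identical stream; distinct key tuples
    yield independent streams (via ``numpy.random.SeedSequence`` entropy
    pooling).
    """
    entropy = [int(seed) & _MASK] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
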