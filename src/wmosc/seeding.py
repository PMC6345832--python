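"""Deterministic child-seed derivation.

One global integer seed drives a run; every stochastic operation derives a
child RNG from ``(global seed, stage name, optional subject index, ...)``
so that stages — and individual subjects within a stage — are independently
reproducible regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key_to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative")
        return int(key)
    raise TypeError(f"seed key must be str or int, got {type(key).__name__}")


def child_seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for ``(seed, *keys)``; string keys are CRC32-hashed."""
    entropy = [_key_to_int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Generator seeded deterministically from ``(seed, *keys)``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))
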