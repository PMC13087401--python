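"""Deterministic seed splitting.

A single root seed per experiment is split into independent child streams,
one per operation (and per replicate inside batch operations), by hashing
string/integer keys into a :class:`numpy.random.SeedSequence`.  Replicate
streams are therefore reproducible independent of how many other draws an
experiment makes, and derived integer seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_sequence", "child_rng", "child_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    digest = hashlib.sha256(str(key).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def child_sequence(seed: int, *keys: object) -> np.random.SeedSequence:
    """Seed sequence for the child stream identified by ``keys``."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator for the child stream identified by ``keys``."""
    return np.random.default_rng(child_sequence(seed, *keys))


def child_seed(seed: int, *keys: object) -> int:
    """A plain integer seed (< 2**31) derived from the child stream."""
    return int(child_sequence(seed, *keys).generate_state(1)[0]) & 0x7FFFFFFF
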