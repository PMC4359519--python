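"""Small shared helpers: deterministic hashing and RNG stream derivation."""

from __future__ import annotations

import hashlib

import numpy as np


def stable_hash(text: str) -> int:
    """Platform-independent 64-bit hash of a string (for RNG stream keys)."""
    digest = hashlib.blake2b(text.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def derive_rng(*keys: int | str) -> np.random.Generator:
    """Build a Generator from an ordered tuple of integer/string keys.

    Strings are hashed with :func:`stable_hash` so the stream is independent
    of Python's per-process hash randomization.
    """
    entropy = [k if isinstance(k, int) else stable_hash(k) for k in keys]
    entropy = [k & 0xFFFFFFFFFFFFFFFF for k in entropy]
    return np.random.default_rng(np.random.SeedSequence(entropy))
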