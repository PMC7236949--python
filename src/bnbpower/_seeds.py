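"""Deterministic seed derivation.

A master seed plus a tuple of labels is hashed into a 31-bit child seed, so every
scenario cell and every simulation replicate gets its own reproducible stream
regardless of execution order.  Floats are canonicalised through ``repr`` of the
Python float, which is exact for IEEE doubles.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *parts) -> int:
    """Derive a child seed (< 2**31) from a master seed and hashable labels."""
    canon = tuple(
        repr(float(p)) if isinstance(p, float) else repr(p) for p in parts
    )
    payload = repr((int(master), canon)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def spawn_generators(seed: int, n: int) -> list[np.random.Generator]:
    """One independent generator per replicate, spawned from a single sequence."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [np.random.default_rng(c) for c in children]
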