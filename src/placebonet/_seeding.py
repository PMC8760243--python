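"""Deterministic seed derivation.

All randomness in the package flows from one integer master seed. Stage- and
item-specific generators are derived by hashing the master seed together with
string/integer keys, so any stage can be re-run in isolation and reproduce the
exact stream it saw inside the full pipeline, on any platform.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["subseed", "rng_for"]


def subseed(master: int, *keys) -> int:
    """Derive a 31-bit child seed from ``master`` and a key path.

    Keys may be strings, ints or floats; they are folded into a SHA-256
    digest, so distinct key paths give independent, reproducible seeds.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"\x00")
        h.update(repr(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master: int, *keys) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for the given key path."""
    return np.random.default_rng(subseed(master, *keys))
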