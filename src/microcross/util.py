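"""Seed derivation and small shared helpers."""

from __future__ import annotations

import logging

logger = logging.getLogger("microcross")

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (x ^ (x >> 31)) & _MASK64


def derive_seed(master: int, label: str) -> int:
    """Derive an independent 31-bit stage seed from a master seed and a label.

    A splitmix64 chain is seeded with the master seed and advanced through the
    bytes of ``label``, so every pipeline stage gets a reproducible stream that
    is decorrelated from its siblings and stable across runs.
    """
    state = _splitmix64(master & _MASK64)
    for b in label.encode("utf-8"):
        state = _splitmix64(state ^ b)
    return state % (2**31)
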