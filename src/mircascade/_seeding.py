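"""Deterministic seed derivation.

A single pipeline seed fans out to per-stage / per-unit seeds through a
stable hash of string keys, so every stage is independently reproducible
and insensitive to the order in which other stages consume randomness.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, *keys: object) -> int:
    """Derive a child seed from ``seed`` and a sequence of hashable keys.

    The derivation is a SHA-256 hash of the textual representation, truncated
    to 63 bits, so it is stable across processes and Python versions.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for key in keys:
        h.update(b"\x1f")
        h.update(str(key).encode())
    return int.from_bytes(h.digest()[:8], "big") >> 1
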