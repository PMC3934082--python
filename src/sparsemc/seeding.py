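"""Deterministic fan-out of one global seed into named sub-streams.

Every pipeline stage draws its randomness from ``child_seed(seed, name)`` so
that module-level determinism survives reordering of the stages and changing
the number of repeats never perturbs earlier repeats.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a global seed and a stream name."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
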