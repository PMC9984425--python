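"""Deterministic seed derivation.

A single top-level seed expands into per-stage child seeds by fixed
offsets, so every generator and permutation scheme is a pure function of
(inputs, seed).
"""

from __future__ import annotations

import zlib

# fixed stage offsets; stable across releases
STAGE_OFFSETS = {
    "panel": 1,
    "gwas": 2,
    "eqtl": 3,
    "triplet": 4,
    "usage": 5,
    "layout": 6,
    "cit_perm": 7,
}

_MOD = 2**31 - 1


def child_seed(seed: int, stage: str, *tokens: str) -> int:
    """Derive a child seed from a top-level seed, a stage name and
    optional string tokens (e.g. triplet ids).  Result is in [0, 2^31)."""
    offset = STAGE_OFFSETS.get(stage)
    if offset is None:
        offset = zlib.crc32(stage.encode()) % 1000
    h = zlib.crc32("|".join(tokens).encode()) if tokens else 0
    return (int(seed) * 1000003 + offset * 7919 + h) % _MOD
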