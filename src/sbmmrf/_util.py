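"""Shared helpers."""

from __future__ import annotations

_MASK = (1 << 64) - 1


def derived_seed(seed: int, *salts: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and salts.

    A small multiplicative hash keeps replicate/d-grid/K-scan seeds
    decorrelated while remaining reproducible across platforms.
    """
    h = (int(seed) * 2654435761) & _MASK
    for s in salts:
        h = ((h ^ (int(s) + 1)) * 40503) & _MASK
    return int(h % (2**31 - 1))
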