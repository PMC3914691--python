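"""Small shared helpers: rounding, seeded RNG derivation, interval arithmetic."""

from __future__ import annotations

import math
import zlib

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Matches the rounding used for printed percentages in summary tables
    (e.g. 58.37 -> 58, 66.59 -> 67, 29.5 -> 30, -2.5 -> -3).
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def lineage_rng(seed: int, lineage: str, salt: str = "") -> np.random.Generator:
    """Child generator derived deterministically from a root seed and a lineage name."""
    key = zlib.crc32(f"{lineage}|{salt}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
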