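"""Small shared helpers."""

from __future__ import annotations

import math
from typing import Iterable


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Used for all printed-style percentages (85.5 -> 86, 64.5 -> 65),
    which Python's banker's rounding would get wrong.
    """
    return int(math.floor(x + 0.5))


def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching [start, end) intervals; returns sorted, disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def runs_of_true(mask) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean sequence as [start, stop) index pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs
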