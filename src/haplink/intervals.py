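"""Small interval helpers (0-based, half-open)."""

from __future__ import annotations

from typing import Iterable


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals into a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_breadth(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of positions covered by the union of the intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))
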