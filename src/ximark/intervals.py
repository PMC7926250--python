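"""Sorted half-open interval arithmetic.

All coordinates are 0-based half-open ``[start, end)`` integers on a single
chromosome; chromosome dispatch happens in the callers.  Intervals are passed
as sequences of ``(start, end)`` pairs.
"""

from __future__ import annotations

import bisect
from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval], adjacent: bool = True) -> List[Interval]:
    """Merge overlapping (and, by default, bookended) intervals.

    ``adjacent=True`` merges ``[0,10)`` and ``[10,20)`` into ``[0,20)``, matching
    ``bedtools merge`` with distance 0.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end < start: ({s}, {e})")
        if out and (s < out[-1][1] or (adjacent and s == out[-1][1])):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Base-pair intersection of two sorted non-overlapping interval lists."""
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def contains_point(intervals: Sequence[Interval], pos: int) -> bool:
    """True if ``pos`` falls inside any interval of a sorted non-overlapping list."""
    i = bisect.bisect_right([iv[0] for iv in intervals], pos) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def any_overlap(intervals: Sequence[Interval], start: int, end: int) -> bool:
    """True if ``[start, end)`` overlaps any interval of a sorted
    non-overlapping list (for which interval ends are also increasing)."""
    i = bisect.bisect_left([iv[0] for iv in intervals], end)
    return i > 0 and intervals[i - 1][1] > start
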