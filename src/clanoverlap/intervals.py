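"""Closed-interval arithmetic on 1-based inclusive residue coordinates.

All coordinates in this package follow the HMMER3 tabular convention:
1-based, inclusive at both ends, so an interval (start, end) covers
``end - start + 1`` residues. These helpers are the single place that
convention is encoded.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def length(iv: Interval) -> int:
    """Number of residues covered by a closed interval."""
    start, end = iv
    return end - start + 1


def intersection_length(a: Interval, b: Interval) -> int:
    """Residues shared by two closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Normalize a set of closed intervals: sort and merge overlapping or
    adjacent ones. Adjacent means end + 1 == next start (no gap residue).

    Idempotent: ``merge(merge(x)) == merge(x)``.
    """
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def clip(intervals: Iterable[Interval], window: Interval) -> list[Interval]:
    """Restrict intervals to a closed window, dropping empty pieces."""
    lo, hi = window
    out: list[Interval] = []
    for start, end in intervals:
        s, e = max(start, lo), min(end, hi)
        if s <= e:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    """Residues covered by a *normalized* (disjoint) interval list."""
    return sum(length(iv) for iv in intervals)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two normalized interval lists (linear sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out
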