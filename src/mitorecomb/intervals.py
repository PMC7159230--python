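"""Arithmetic on 1-based inclusive genomic intervals.

All public functions take and return ``(start, end)`` tuples with
``1 <= start <= end``. This matches the coordinate convention used in the
repeat and homology tables produced by the pipeline.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def validate(iv: Interval) -> Interval:
    s, e = iv
    if s < 1 or e < s:
        raise ValueError(f"invalid 1-based inclusive interval {iv!r}")
    return (int(s), int(e))


def length(iv: Interval) -> int:
    s, e = iv
    return e - s + 1


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Touching intervals (end + 1 == next start) are merged.
    """
    ivs = sorted(validate(iv) for iv in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(length(iv) for iv in merge(intervals))


def complement(intervals: Iterable[Interval], total_length: int) -> List[Interval]:
    """Positions of ``[1, total_length]`` not covered by ``intervals``."""
    merged = merge(intervals)
    out: List[Interval] = []
    cursor = 1
    for s, e in merged:
        if e < 1 or s > total_length:
            continue
        s, e = max(s, 1), min(e, total_length)
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= total_length:
        out.append((cursor, total_length))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets, as disjoint sorted intervals."""
    ma, mb = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s <= e:
            out.append((s, e))
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return out


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def overlap_length(a: Interval, b: Interval) -> int:
    s = max(a[0], b[0])
    e = min(a[1], b[1])
    return max(0, e - s + 1)
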