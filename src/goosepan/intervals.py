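"""Small interval algebra on 0-based half-open intervals.

All functions take/return lists of ``(start, end)`` tuples with
``start < end``. These primitives back the contig-triage complement rule,
exon-union presence calling, and gene/region overlap computations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/adjacent runs merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def complement_intervals(length: int, covered: Iterable[Interval]) -> list[Interval]:
    """Maximal gaps of ``[0, length)`` not covered by ``covered``."""
    gaps: list[Interval] = []
    cursor = 0
    for s, e in merge_intervals(covered):
        s, e = max(s, 0), min(e, length)
        if s >= e:
            continue
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    return gaps


def overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total number of bases in the intersection of two interval unions."""
    ua, ub = merge_intervals(a), merge_intervals(b)
    i = j = shared = 0
    while i < len(ua) and j < len(ub):
        s = max(ua[i][0], ub[j][0])
        e = min(ua[i][1], ub[j][1])
        if s < e:
            shared += e - s
        if ua[i][1] <= ub[j][1]:
            i += 1
        else:
            j += 1
    return shared
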