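"""Small helpers for 0-based half-open genomic intervals.

Intervals are ``(start, end)`` tuples with ``start < end``.  All functions
return sorted, disjoint (merged) interval lists.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or abutting intervals into maximal disjoint blocks."""
    if not intervals:
        return []
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty interval ({s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b of two merged interval lists."""
    b = merge(b) if b else []
    out: list[Interval] = []
    for s, e in merge(a) if a else []:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    bi = merge(b) if b else []
    for s, e in merge(a) if a else []:
        for bs, be in bi:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((lo, hi))
    return merge(out)


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def contains(blocks: list[Interval], positions: list[Interval]) -> bool:
    """True iff every interval in ``positions`` is covered by ``blocks``."""
    return not subtract(positions, blocks)
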