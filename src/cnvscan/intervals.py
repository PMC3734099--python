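"""Closed-interval arithmetic shared across the screen.

Intervals are 1-based and fully closed; two intervals overlap when they
share at least one base, i.e. ``a.start <= b.end and b.start <= a.end``.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of bases shared by two closed intervals (0 when disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def gap_between(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two closed intervals; 0 if they touch or overlap."""
    if overlaps(a, b):
        return 0
    if a[1] < b[0]:
        return b[0] - a[1] - 1
    return a[0] - b[1] - 1


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) on closed-interval base counts.

    The standard symmetric criterion for calling two CNV calls the same
    event; 0.0 when the intervals are disjoint.  Callers are responsible
    for only comparing intervals on the same chromosome.
    """
    inter = overlap_length(a, b)
    if inter == 0:
        return 0.0
    len_a = a[1] - a[0] + 1
    len_b = b[1] - b[0] + 1
    return min(inter / len_a, inter / len_b)


def union_coverage(
    span: tuple[int, int], intervals: Iterable[tuple[int, int]]
) -> float:
    """Fraction of ``span`` covered by the union of ``intervals``.

    Sweep-line union of the intervals clipped to the span; bases covered by
    several intervals count once.
    """
    lo, hi = span
    span_len = hi - lo + 1
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if s <= hi and e >= lo
    )
    covered = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in clipped:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered / span_len


def merge_intervals(
    intervals: Sequence[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Union of closed intervals, merging pairs separated by <= ``gap`` bases."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + gap + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
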