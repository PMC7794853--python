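"""Closed-interval calendar-date algebra.

Drug coverage, enrollment continuity and concomitancy are all day-set
computations on closed intervals of calendar dates: a fill dispensed on
day *d* with a supply of *s* days covers days ``d .. d+s-1`` inclusive.
Episode construction bridges refill gaps of at most ``gap`` uncovered
days, the operational reading of "consecutive days" of use.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class DateInterval:
    """A closed interval of calendar dates; both endpoints are covered days."""

    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    @property
    def length(self) -> int:
        """Number of covered days, ``end - start + 1``."""
        return (self.end - self.start).days + 1

    def contains(self, day: datetime.date) -> bool:
        return self.start <= day <= self.end

    def intersects(self, other: "DateInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersection(self, other: "DateInterval") -> "DateInterval | None":
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return DateInterval(lo, hi) if lo <= hi else None


def merge_with_gap(intervals: Iterable[DateInterval], gap: int) -> list[DateInterval]:
    """Merge intervals, bridging runs of at most ``gap`` uncovered days.

    Two intervals are joined iff the count of uncovered days between them
    (``next.start - prev.end - 1``) is <= ``gap``.  Input may overlap and
    be unsorted; output is sorted and disjoint, separated by > ``gap``
    uncovered days.  ``gap=0`` is the classical union of overlapping or
    abutting intervals.
    """
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    ivs = sorted(intervals)
    if not ivs:
        return []
    out: list[DateInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        uncovered = (iv.start - cur_end).days - 1
        if uncovered <= gap:
            if iv.end > cur_end:
                cur_end = iv.end
        else:
            out.append(DateInterval(cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    out.append(DateInterval(cur_start, cur_end))
    return out


def intersect(a: Sequence[DateInterval], b: Sequence[DateInterval]) -> list[DateInterval]:
    """Intersection of two disjoint sorted interval lists (day-set semantics)."""
    out: list[DateInterval] = []
    i = j = 0
    a = sorted(a)
    b = sorted(b)
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo <= hi:
            out.append(DateInterval(lo, hi))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return out


def total_days(intervals: Iterable[DateInterval]) -> int:
    """Size of the union of covered days (no gap bridging)."""
    return sum(iv.length for iv in merge_with_gap(intervals, 0))


def clip(intervals: Iterable[DateInterval], period: DateInterval) -> list[DateInterval]:
    """Restrict intervals to the days inside ``period``."""
    out = []
    for iv in intervals:
        x = iv.intersection(period)
        if x is not None:
            out.append(x)
    return out


def covers_every_day(intervals: Iterable[DateInterval], window: DateInterval) -> bool:
    """True iff the union of ``intervals`` covers every day of ``window``."""
    merged = merge_with_gap(clip(intervals, window), 0)
    return len(merged) == 1 and merged[0].start == window.start and merged[0].end == window.end


def year_interval(year: int) -> DateInterval:
    return DateInterval(datetime.date(year, 1, 1), datetime.date(year, 12, 31))
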