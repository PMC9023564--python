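"""Half-open interval arithmetic on a single chromosome.

All intervals are 0-based half-open ``(start, end)`` tuples with
``start < end``. Functions return merged, sorted, non-overlapping lists.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Portions of ``a`` not covered by ``b``."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def contains_point(merged: Sequence[Interval], x: float) -> bool:
    """Membership test against an already merged, sorted interval list."""
    if not merged:
        return False
    i = bisect_right([s for s, _ in merged], x) - 1
    return i >= 0 and x < merged[i][1]


def sample_point(merged: Sequence[Interval], rng) -> int:
    """Uniform random integer position within a merged interval list."""
    if not merged:
        raise ValueError("cannot sample from an empty interval set")
    lengths = [e - s for s, e in merged]
    total = sum(lengths)
    r = int(rng.integers(0, total))
    for (s, e), ln in zip(merged, lengths):
        if r < ln:
            return s + r
        r -= ln
    return merged[-1][1] - 1  # unreachable


def nearest_interval(merged: Sequence[Interval], x: float) -> Interval:
    """The interval whose boundary is closest to position ``x``."""
    if not merged:
        raise ValueError("no intervals to choose from")
    best, best_d = merged[0], float("inf")
    for s, e in merged:
        d = 0.0 if s <= x < e else min(abs(x - s), abs(x - e))
        if d < best_d:
            best, best_d = (s, e), d
    return best
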