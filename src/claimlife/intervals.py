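"""Half-open interval algebra at day resolution.

Every calendar quantity in this package -- dispensing coverage, follow-up
windows, age bands -- is a set of half-open intervals ``[start, end)``
measured in whole days.  The set operations here are the workhorse behind
exposure-episode construction (grace-window bridging) and person-time
splitting, so they are written once, kept tiny, and property-tested against
brute-force day enumeration.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]
IntervalList = List[Interval]


def normalize(intervals: Iterable[Interval]) -> IntervalList:
    """Canonical form: empty intervals dropped, overlapping or touching
    intervals merged, result sorted by start."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: IntervalList = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def merge_with_grace(intervals: Iterable[Interval], grace: int) -> IntervalList:
    """Merge intervals whose gap does not exceed ``grace`` days.

    A successor starting at most ``grace`` days after the running end is
    bridged into the current episode, and the bridged gap counts as covered.
    ``grace=0`` reduces to :func:`normalize`.
    """
    if grace < 0:
        raise ValueError("grace must be non-negative")
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: IntervalList = []
    for s, e in ivs:
        if out and s <= out[-1][1] + grace:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalList:
    return normalize(list(a) + list(b))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalList:
    """Day-level intersection of two interval sets."""
    xa, xb = normalize(a), normalize(b)
    out: IntervalList = []
    i = j = 0
    while i < len(xa) and j < len(xb):
        s = max(xa[i][0], xb[j][0])
        e = min(xa[i][1], xb[j][1])
        if e > s:
            out.append((s, e))
        if xa[i][1] <= xb[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> IntervalList:
    """Days in ``a`` not in ``b``."""
    xa, xb = normalize(a), normalize(b)
    out: IntervalList = []
    j = 0
    for s, e in xa:
        cur = s
        while j < len(xb) and xb[j][1] <= cur:
            j += 1
        k = j
        while k < len(xb) and xb[k][0] < e:
            bs, be = xb[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> IntervalList:
    """Restrict an interval set to the window ``[lo, hi)``."""
    return intersect(intervals, [(lo, hi)])


def total_days(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in normalize(intervals))
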