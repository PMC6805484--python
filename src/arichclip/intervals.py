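"""Half-open interval arithmetic on (start, end) tuples.

All genomic coordinates in this package are 0-based, half-open. GTF input
(1-based, closed) is converted at the parsing boundary and nowhere else.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, non-overlapping list.

    Adjacent (book-ended) intervals are coalesced.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Positions in union(a) but not in union(b)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
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


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    a = merge_intervals(a)
    b = merge_intervals(b)
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


def overlaps(iv: Interval, intervals: Iterable[Interval]) -> bool:
    s, e = iv
    return any(s < ie and is_ < e for is_, ie in intervals)


def truncate_from_5prime(
    intervals: Sequence[Interval], strand: str, max_len: int
) -> list[Interval]:
    """Keep the first ``max_len`` nt of a merged interval chain, walking in
    transcript (5'→3') direction: left→right on '+', right→left on '-'."""
    ivs = merge_intervals(intervals)
    out: list[Interval] = []
    remaining = max_len
    ordered = ivs if strand == "+" else list(reversed(ivs))
    for s, e in ordered:
        if remaining <= 0:
            break
        ln = e - s
        if ln <= remaining:
            out.append((s, e))
            remaining -= ln
        else:
            if strand == "+":
                out.append((s, s + remaining))
            else:
                out.append((e - remaining, e))
            remaining = 0
    return merge_intervals(out)


def clip_at_3prime_boundary(
    intervals: Sequence[Interval], strand: str, boundary: int
) -> list[Interval]:
    """Strand-aware clip: on '+' keep positions < boundary, on '-' keep
    positions >= boundary."""
    ivs = merge_intervals(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if strand == "+":
            if s < boundary:
                out.append((s, min(e, boundary)))
        else:
            if e > boundary:
                out.append((max(s, boundary), e))
    return out
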