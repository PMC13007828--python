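"""Closed-interval arithmetic on sorted lists of (start, end) tuples."""

from __future__ import annotations

Interval = tuple[float, float]


def normalize(intervals: list[Interval]) -> list[Interval]:
    """Sort, drop empty intervals, and merge overlapping/touching ones."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b. Removal is closed: touching endpoints are cut."""
    a = normalize(a)
    b = normalize(b)
    out: list[Interval] = []
    for s, e in a:
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
    a = normalize(a)
    b = normalize(b)
    out: list[Interval] = []
    for s, e in a:
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                out.append((lo, hi))
    return normalize(out)


def pad(intervals: list[Interval], pad_s: float) -> list[Interval]:
    return normalize([(s - pad_s, e + pad_s) for s, e in intervals])


def total(intervals: list[Interval]) -> float:
    return sum(e - s for s, e in normalize(intervals))
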