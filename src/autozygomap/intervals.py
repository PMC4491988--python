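"""Interval algebra on 0-based half-open genomic intervals.

An interval set is a dict mapping chromosome name to an (k, 2) int64
array of [start, end) rows, kept sorted and pairwise disjoint. All
physical coordinates inside the package are 0-based half-open (BED
convention); 1-based VCF positions are converted at the io boundary.
"""

from __future__ import annotations

import numpy as np

IntervalSet = dict[str, np.ndarray]


def _as_array(ivs) -> np.ndarray:
    arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
    return arr


def normalize(ivs: IntervalSet) -> IntervalSet:
    """Sort, drop empty intervals and merge overlapping/adjacent ones."""
    out: IntervalSet = {}
    for chrom, arr in ivs.items():
        arr = _as_array(arr)
        arr = arr[arr[:, 1] > arr[:, 0]]
        if arr.size == 0:
            continue
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def total_length(ivs: IntervalSet) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in ivs.values()))


def intersect_two(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out: IntervalSet = {}
    for chrom in a:
        if chrom not in b:
            continue
        xa, xb = _as_array(a[chrom]), _as_array(b[chrom])
        rows = []
        i = j = 0
        while i < len(xa) and j < len(xb):
            s = max(xa[i, 0], xb[j, 0])
            e = min(xa[i, 1], xb[j, 1])
            if s < e:
                rows.append((s, e))
            if xa[i, 1] <= xb[j, 1]:
                i += 1
            else:
                j += 1
        if rows:
            out[chrom] = np.array(rows, dtype=np.int64)
    return out


def intersect_many(interval_sets: list[IntervalSet]) -> IntervalSet:
    """Intersection of one or more interval sets (commutative, associative)."""
    if not interval_sets:
        raise ValueError("intersect_many requires a non-empty list")
    result = normalize(interval_sets[0])
    for ivs in interval_sets[1:]:
        result = intersect_two(result, normalize(ivs))
    return result


def subtract(minuend: IntervalSet, subtrahend: IntervalSet) -> IntervalSet:
    """Bases in ``minuend`` and not in ``subtrahend``, as disjoint sorted rows."""
    minuend = normalize(minuend)
    subtrahend = normalize(subtrahend)
    out: IntervalSet = {}
    for chrom, arr in minuend.items():
        cuts = subtrahend.get(chrom)
        if cuts is None or len(cuts) == 0:
            out[chrom] = arr.copy()
            continue
        rows = []
        for s, e in arr:
            cur = s
            for cs, ce in cuts:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    rows.append((cur, cs))
                cur = max(cur, ce)
                if cur >= e:
                    break
            if cur < e:
                rows.append((cur, e))
        if rows:
            out[chrom] = np.array(rows, dtype=np.int64)
    return out


def union_two(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    merged: IntervalSet = {}
    for chrom in set(a) | set(b):
        parts = []
        if chrom in a:
            parts.append(_as_array(a[chrom]))
        if chrom in b:
            parts.append(_as_array(b[chrom]))
        merged[chrom] = np.vstack(parts)
    return normalize(merged)


def contains_point(ivs: IntervalSet, chrom: str, pos0: int) -> bool:
    """Membership of a 0-based position in the interval set."""
    arr = ivs.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
    return i >= 0 and pos0 < arr[i, 1]


def points_in(ivs: IntervalSet, chrom: str, pos0: np.ndarray) -> np.ndarray:
    """Vectorized membership test for an array of 0-based positions."""
    pos0 = np.asarray(pos0, dtype=np.int64)
    arr = ivs.get(chrom)
    if arr is None or len(arr) == 0:
        return np.zeros(pos0.shape, dtype=bool)
    i = np.searchsorted(arr[:, 0], pos0, side="right") - 1
    ok = i >= 0
    res = np.zeros(pos0.shape, dtype=bool)
    res[ok] = pos0[ok] < arr[i[ok], 1]
    return res
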