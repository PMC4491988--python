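"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles
(path-counting, exhaustive window enumeration, per-base membership,
flat predicates) without reusing the package's algorithms.
"""

from __future__ import annotations

import numpy as np

from autozygomap.genome import HET, MISSING
from autozygomap.pedigree import Pedigree


# ---------------------------------------------------------------------------
# Wright's path-counting inbreeding coefficient


def _ascending_paths(ped: Pedigree, start: str, target: str) -> list[list[str]]:
    """All parent-directed paths from ``start`` up to ``target``."""
    out: list[list[str]] = []

    def walk(node: str, path: list[str]):
        if node == target:
            out.append(path + [node])
            return
        ind = ped.members[node]
        for parent in (ind.father, ind.mother):
            if parent is not None:
                walk(parent, path + [node])

    walk(start, [])
    return out


def _ancestors(ped: Pedigree, iid: str) -> set[str]:
    seen = set()
    stack = [iid]
    while stack:
        ind = ped.members[stack.pop()]
        for parent in (ind.father, ind.mother):
            if parent is not None and parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen | {iid}


def wright_inbreeding(ped: Pedigree, iid: str) -> float:
    """F via Wright's path counting: sum over common ancestors A and
    node-disjoint path pairs of (1/2)^(n1+n2+1) * (1 + F_A)."""
    ind = ped.members[iid]
    if ind.is_founder:
        return 0.0
    total = 0.0
    common = _ancestors(ped, ind.father) & _ancestors(ped, ind.mother)
    for anc in common:
        fa = wright_inbreeding(ped, anc)
        for p1 in _ascending_paths(ped, ind.father, anc):
            for p2 in _ascending_paths(ped, ind.mother, anc):
                if set(p1) & set(p2) != {anc}:
                    continue
                n_edges = (len(p1) - 1) + (len(p2) - 1)
                total += 0.5 ** (n_edges + 1) * (1.0 + fa)
    return total


# ---------------------------------------------------------------------------
# exhaustive maximal-run ROH oracle


def brute_force_roh(codes, positions, params) -> set[tuple[int, int]]:
    """All bases covered by qualifying maximal tolerant runs, as merged
    0-based half-open intervals, via O(n^2) window enumeration and
    per-base union."""
    codes = np.asarray(codes)
    pos = np.asarray(positions)
    n = codes.size

    def tolerant(l, r):  # noqa: E741
        window = codes[l : r + 1]
        if np.any(np.diff(pos[l : r + 1]) > params.max_gap_bp):
            return False
        return (
            int(np.sum(window == HET)) <= params.max_het
            and int(np.sum(window == MISSING)) <= params.max_missing
        )

    covered: set[int] = set()  # in units of bp/RESOLUTION below
    spans = []
    for l in range(n):  # noqa: E741
        for r in range(l, n):
            if not tolerant(l, r):
                continue
            if l > 0 and tolerant(l - 1, r):
                continue
            if r < n - 1 and tolerant(l, r + 1):
                continue
            start, end = int(pos[l] - 1), int(pos[r])
            if end - start > params.min_length_bp and (r - l + 1) >= params.min_markers:
                spans.append((start, end))
    # merge by sorting (the spans are few)
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return {(s, e) for s, e in merged}


# ---------------------------------------------------------------------------
# per-base membership interval oracle


def bases(ivs: dict, chrom: str) -> set[int]:
    arr = ivs.get(chrom)
    if arr is None:
        return set()
    out: set[int] = set()
    for s, e in np.asarray(arr).reshape(-1, 2):
        out.update(range(int(s), int(e)))
    return out


def set_to_intervals(base_set: set[int]) -> set[tuple[int, int]]:
    if not base_set:
        return set()
    xs = sorted(base_set)
    out = []
    start = prev = xs[0]
    for x in xs[1:]:
        if x != prev + 1:
            out.append((start, prev + 1))
            start = x
        prev = x
    out.append((start, prev + 1))
    return set(out)


# ---------------------------------------------------------------------------
# flat-predicate filter oracle


def flat_filter(variants, interval_set, config) -> list:
    """The five filter rules written as one flat predicate."""
    out = []
    for v in variants:
        pop = max(v.af_pop.values(), default=0.0)
        inh = v.af_inhouse or 0.0
        if config.inhouse_mode == "absence":
            freq_ok = pop <= config.max_af and inh == 0.0
        else:
            freq_ok = pop <= config.max_af and inh <= config.max_af
        coding_ok = v.csq in config.coding_csq
        hom_ok = v.zygosity == "hom"
        arr = interval_set.get(v.chrom)
        pos0 = v.pos - 1
        roh_ok = arr is not None and any(s <= pos0 < e for s, e in np.asarray(arr))
        if v.csq in ("stopgain", "frameshift", "splice-site"):
            patho_ok = True
        elif v.csq in ("missense", "inframe-indel"):
            patho_ok = (
                v.polyphen is not None
                and v.sift is not None
                and v.conservation is not None
                and v.polyphen >= config.pp2_min
                and v.sift <= config.sift_max
                and v.conservation >= config.cons_min
            )
        else:
            patho_ok = False
        if freq_ok and coding_ok and hom_ok and roh_ok and patho_ok:
            out.append(v)
    return out
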