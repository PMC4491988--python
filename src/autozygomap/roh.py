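"""Runs-of-homozygosity calling and the per-sample autozygome.

In the offspring of consanguineous unions, long stretches of homozygous
genotype calls mark segments that are homozygous by descent (HBD).  The
autozygome — the totality of such segments — is delineated here as runs
of homozygosity (ROH) longer than 2 Mb, with small tolerances for
genotyping error (heterozygous calls) and missing calls.

The run definition is maximal-run-with-tolerances: a run is a contiguous
block of markers containing at most ``max_het`` heterozygous and
``max_missing`` missing calls, not bridging an inter-marker gap larger
than ``max_gap_bp``, and extendable by no further marker on either side
without violating a tolerance.  Qualifying runs (physical length
strictly greater than ``min_length_bp`` and at least ``min_markers``
markers) are unioned into the autozygome; overlapping qualifying runs
(possible when a tolerated het call sits near a run boundary) therefore
merge into a single interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .errors import PanelError
from .genome import HET, MISSING, GenotypeMatrix, MarkerPanel


@dataclass
class RohParams:
    """Tolerances and thresholds for ROH calling."""

    min_length_bp: int = 2_000_000
    min_markers: int = 50
    max_het: int = 1
    max_missing: int = 5
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        for name in ("min_markers", "max_het", "max_missing", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RohInterval:
    """One called run: 0-based half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    n_markers: int
    sample: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Autozygome:
    """Per-sample set of ROH intervals, disjoint and sorted per chromosome."""

    sample: str
    rohs: list[RohInterval] = field(default_factory=list)

    def interval_set(self) -> iv.IntervalSet:
        out: dict[str, list] = {}
        for r in self.rohs:
            out.setdefault(r.chrom, []).append((r.start, r.end))
        return iv.normalize({c: np.array(v) for c, v in out.items()})

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.rohs)

    def __len__(self) -> int:
        return len(self.rohs)


def _maximal_runs(codes: np.ndarray, params: RohParams) -> list[tuple[int, int]]:
    """Maximal tolerant runs over one gap-free marker block.

    Two-pointer sweep: R(l) = furthest right end of a tolerant window
    starting at l; R is non-decreasing, and a window [l, R(l)] is maximal
    iff l is the block start or R(l-1) < R(l).
    """
    n = codes.size
    het = np.concatenate(([0], np.cumsum(codes == HET))).tolist()
    mis = np.concatenate(([0], np.cumsum(codes == MISSING))).tolist()
    max_het, max_mis = params.max_het, params.max_missing

    runs = []
    r = -1
    prev_r = -1
    for l in range(n):  # noqa: E741
        if r < l - 1:
            r = l - 1
        while (
            r + 1 < n
            and het[r + 2] - het[l] <= max_het
            and mis[r + 2] - mis[l] <= max_mis
        ):
            r += 1
        if r >= l and (l == 0 or r > prev_r):
            runs.append((l, r))
        prev_r = r
    return runs


def call_roh(
    genotypes: GenotypeMatrix,
    panel: MarkerPanel,
    sample: str,
    params: RohParams | None = None,
) -> Autozygome:
    """Call ROH for one sample and assemble its autozygome.

    Runs are computed per chromosome within gap-bounded marker blocks,
    converted to physical intervals spanning first to last marker of the
    run (0-based half-open), filtered by the strict length threshold and
    minimum marker support, and unioned.
    """
    params = params or RohParams()
    out: list[RohInterval] = []
    for chrom in genotypes.data:
        pos = panel.require_chrom(chrom)
        if chrom not in genotypes.panel.positions or not np.array_equal(
            genotypes.panel.positions[chrom], pos
        ):
            raise PanelError(f"panel and genotype matrix disagree on chromosome {chrom!r}")
        codes = genotypes.calls(sample, chrom)
        # split markers into blocks at gaps exceeding max_gap_bp
        gap_breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
        blocks = np.split(np.arange(pos.size), gap_breaks)
        kept: list[tuple[int, int]] = []
        for block in blocks:
            if block.size == 0:
                continue
            off = block[0]
            for l, r in _maximal_runs(codes[block], params):  # noqa: E741
                i, j = off + l, off + r
                start, end = int(pos[i] - 1), int(pos[j])
                if end - start > params.min_length_bp and (j - i + 1) >= params.min_markers:
                    kept.append((start, end))
        merged = iv.normalize({chrom: np.array(kept)}) if kept else {}
        for s, e in merged.get(chrom, []):
            nmark = int(np.searchsorted(pos, e, "right") - np.searchsorted(pos, s + 1, "left"))
            out.append(RohInterval(chrom, int(s), int(e), nmark, sample))
    return Autozygome(sample=sample, rohs=out)


def intersect_autozygomes(autozygomes: list[Autozygome]) -> iv.IntervalSet:
    """Per-chromosome intersection of one or more autozygomes."""
    if not autozygomes:
        raise ValueError("intersect_autozygomes requires a non-empty list")
    return iv.intersect_many([a.interval_set() for a in autozygomes])


def subtract_autozygome(minuend: iv.IntervalSet, subtrahend: iv.IntervalSet) -> iv.IntervalSet:
    """Exclusion mapping: bases of ``minuend`` not in ``subtrahend``."""
    return iv.subtract(minuend, subtrahend)


def variant_in_autozygome(chrom: str, pos_1based: int, autozygome: Autozygome | iv.IntervalSet) -> bool:
    """True iff a 1-based variant position falls inside the autozygome."""
    if pos_1based < 1:
        raise ValueError("variant position must be >= 1")
    ivs = autozygome.interval_set() if isinstance(autozygome, Autozygome) else autozygome
    return iv.contains_point(ivs, chrom, pos_1based - 1)
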