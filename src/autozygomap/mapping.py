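"""Cross-family locus mapping and founder-mutation detection.

Under a fully penetrant, rare recessive model, an affected offspring of
a consanguineous union is homozygous by descent (HBD) at the causal
locus with probability 1, while at an unlinked locus it is HBD with
probability F (its inbreeding coefficient).  The per-affected evidence
for linkage at a tested position is therefore the likelihood ratio
1 / F when the position lies in the affected's autozygome, and 0 when it
does not (the locus is excluded).  Summing log10 contributions over
affecteds within and across families gives a LOD-style score with
genome-wide maximum bounded by sum(log10(1 / F)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .errors import MappingError, NotHomozygousError
from .genome import GenotypeMatrix, MarkerPanel, MISSING
from .prioritize import VariantRecord
from .roh import Autozygome


@dataclass
class AffectedEvidence:
    """One affected individual's mapping inputs."""

    sample: str
    autozygome: Autozygome
    inbreeding: float
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.inbreeding < 1.0:
            raise MappingError("inbreeding coefficient must be in [0, 1)")


@dataclass
class FamilyEvidence:
    """Per-family evidence: affected individuals with retained variants."""

    family_id: str
    affecteds: list[AffectedEvidence]


@dataclass
class LocusScore:
    chrom: str
    pos: int
    lod: float  # log10 units; -inf where any affected excludes the locus
    per_family: dict[str, float] = field(default_factory=dict)


@dataclass
class Peak:
    """Maximal run of marker positions with score >= threshold."""

    chrom: str
    start: int  # 0-based half-open, spanning first to last qualifying marker
    end: int
    peak_lod: float
    peak_pos: int  # 1-based position of the maximum


#: Display floor for -infinity exclusions in plots/reports; peak calling
#: keeps true exclusion semantics.
LOD_FLOOR = -10.0


def clamp_lod(lod: float, floor: float = LOD_FLOOR) -> float:
    """Clamp an exclusion score for display; -inf becomes ``floor``."""
    return max(lod, floor)


def max_attainable_lod(families: list[FamilyEvidence]) -> float:
    return sum(
        math.log10(1.0 / a.inbreeding) for f in families for a in f.affecteds
    )


def hbd_lod(families: list[FamilyEvidence], chrom: str, pos_1based: int) -> LocusScore:
    """HBD likelihood-ratio score at one position, summed over families.

    Each affected contributes log10(1 / F) if the position lies in its
    autozygome and -infinity otherwise.
    """
    total = 0.0
    per_family: dict[str, float] = {}
    for fam in families:
        fam_score = 0.0
        for aff in fam.affecteds:
            if aff.inbreeding == 0.0:
                raise MappingError(
                    f"affected {aff.sample!r} has F = 0; the HBD score requires "
                    "a consanguineous parent pair"
                )
            if iv.contains_point(aff.autozygome.interval_set(), chrom, pos_1based - 1):
                fam_score += math.log10(1.0 / aff.inbreeding)
            else:
                fam_score = float("-inf")
                break
        per_family[fam.family_id] = fam_score
        total += fam_score
    return LocusScore(chrom=chrom, pos=pos_1based, lod=total, per_family=per_family)


def score_markers(families: list[FamilyEvidence], panel: MarkerPanel) -> dict[str, np.ndarray]:
    """Vectorized HBD-LOD over every marker position; -inf where excluded."""
    scores: dict[str, np.ndarray] = {}
    for chrom, pos in panel.positions.items():
        total = np.zeros(pos.size)
        for fam in families:
            for aff in fam.affecteds:
                if aff.inbreeding == 0.0:
                    raise MappingError(f"affected {aff.sample!r} has F = 0")
                hbd = iv.points_in(aff.autozygome.interval_set(), chrom, pos - 1)
                contrib = np.where(hbd, math.log10(1.0 / aff.inbreeding), -np.inf)
                total = total + contrib
        scores[chrom] = total
    return scores


def scan_genome(
    families: list[FamilyEvidence], panel: MarkerPanel, threshold: float = 3.0
) -> list[Peak]:
    """Evaluate the HBD-LOD at every marker and return peaks >= threshold."""
    if not math.isfinite(threshold):
        raise MappingError("threshold must be finite")
    peaks: list[Peak] = []
    scores = score_markers(families, panel)
    for chrom, pos in panel.positions.items():
        s = scores[chrom]
        above = s >= threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = [0] if above[0] else []
        starts += [int(e) + 1 for e in edges if not above[e]]
        ends = [int(e) for e in edges if above[e]]
        if above[-1]:
            ends.append(pos.size - 1)
        for i, j in zip(starts, ends):
            k = i + int(np.argmax(s[i : j + 1]))
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(pos[i] - 1),
                    end=int(pos[j]),
                    peak_lod=float(s[k]),
                    peak_pos=int(pos[k]),
                )
            )
    return peaks


@dataclass
class SharedVariant:
    """A retained variant carried by several families (putative founder allele)."""

    key: tuple[str, int, str, str]
    gene: str | None
    families: list[str]
    records: list[VariantRecord]

    @property
    def n_families(self) -> int:
        return len(self.families)


def find_shared_variants(
    families: list[FamilyEvidence], min_families: int = 2
) -> list[SharedVariant]:
    """Group retained variants identical by (chrom, pos, ref, alt) across families."""
    if min_families < 1:
        raise ValueError("min_families must be >= 1")
    groups: dict[tuple, dict[str, VariantRecord]] = {}
    for fam in families:
        for aff in fam.affecteds:
            for v in aff.variants:
                groups.setdefault(v.key, {}).setdefault(fam.family_id, v)
    out = []
    for key, carriers in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if len(carriers) >= min_families:
            recs = list(carriers.values())
            out.append(
                SharedVariant(
                    key=key,
                    gene=recs[0].gene,
                    families=sorted(carriers),
                    records=recs,
                )
            )
    return out


def shared_haplotype_span(
    genotypes: GenotypeMatrix,
    panel: MarkerPanel,
    chrom: str,
    pos_1based: int,
    carriers: list[str],
    max_missing: int = 5,
) -> tuple[int, int]:
    """Maximal interval of identical homozygous genotypes around a variant.

    All carrier samples must be homozygous at the focal position (else
    :class:`NotHomozygousError`).  The span extends marker by marker in
    both directions while every carrier is homozygous for the same call;
    markers at which any carrier has a missing call are tolerated, at most
    ``max_missing`` per flank.  Returns the 0-based half-open interval.
    A long shared span supports a founder origin of the allele.
    """
    pos = panel.require_chrom(chrom)
    calls = np.vstack([genotypes.calls(s, chrom) for s in carriers])
    focal = int(np.searchsorted(pos, pos_1based))
    if focal >= pos.size or pos[focal] != pos_1based:
        focal = int(np.searchsorted(pos, pos_1based)) - 1  # nearest marker at/left
        if focal < 0:
            raise MappingError("no marker at or before the focal position")
    col = calls[:, focal]
    if np.any((col != 0) & (col != 2)):
        raise NotHomozygousError(
            f"carrier not homozygous at the focal marker {chrom}:{int(pos[focal])}"
        )

    def concordant(j: int) -> tuple[bool, bool]:
        """(is concordant homozygous, has missing call) for marker j."""
        c = calls[:, j]
        miss = bool(np.any(c == MISSING))
        obs = c[c != MISSING]
        if obs.size == 0:
            return True, True
        ok = bool(np.all(obs == obs[0]) and obs[0] in (0, 2))
        return ok, miss

    left = right = focal
    used = 0
    j = focal - 1
    while j >= 0:
        ok, miss = concordant(j)
        if not ok or (miss and used >= max_missing):
            break
        used += int(miss)
        left = j
        j -= 1
    used = 0
    j = focal + 1
    while j < pos.size:
        ok, miss = concordant(j)
        if not ok or (miss and used >= max_missing):
            break
        used += int(miss)
        right = j
        j += 1
    return int(pos[left] - 1), int(pos[right])
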