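"""Gene-dropping simulator for consanguineous families.

Founders receive two haplotypes each; every meiosis recombines the
parental haplotype pair under the Haldane model (crossover count Poisson
in genetic length, positions uniform, no interference) and transmits one
recombinant haplotype.  Each haplotype is represented as a mosaic of
founder-haplotype labels, so identity by descent is exact: an individual
is autozygous wherever its two mosaics carry the same label.

On top of the dropped haplotypes the simulator synthesizes array-style
genotype calls (founder allele frequencies Beta-distributed per marker),
injects missing calls, and emits an annotated exome-like variant set per
affected individual containing one planted fully penetrant recessive
causal variant riding on a single founder haplotype, plus background
variants with a configurable frequency spectrum, consequence mix and
heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import intervals as iv
from .errors import PanelError, RetryLimitError, SimulationError
from .genome import DEFAULT_GENOME, GenotypeMatrix, MarkerPanel
from .pedigree import Pedigree
from .prioritize import VariantRecord

Hap = tuple[np.ndarray, np.ndarray]  # (breakpoints incl. 0 and L, segment labels)

_NUCS = np.array(list("ACGT"))

#: Default consequence mix of background variants (exome-like call set:
#: coding plus near-gene/UTR/intronic calls captured by exome kits).
DEFAULT_CSQ_PROBS = {
    "non-coding": 0.50,
    "synonymous": 0.20,
    "missense": 0.25,
    "inframe-indel": 0.01,
    "splice-site": 0.01,
    "frameshift": 0.015,
    "stopgain": 0.015,
}


@dataclass
class PlantedVariant:
    """Specification of the planted recessive causal allele."""

    gene: str = "THSD1"
    chrom: str = "13"
    pos: int = 53_000_000
    ref: str = "G"
    alt: str = "A"
    csq: str = "missense"
    polyphen: float = 0.999
    sift: float = 0.0
    conservation: float = 3.0
    transcript: str = "NM_018676"
    protein_change: str = "p.C206Y"


@dataclass
class SimParams:
    """All knobs of the simulator; a fixed seed gives identical output."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    recomb_rate_per_mb: float = 0.01  # expected crossovers per Mb (1 cM/Mb)
    founder_af_beta: tuple[float, float] = (2.0, 2.0)
    founder_af_range: tuple[float, float] | None = None  # uniform override of the Beta
    marker_spacing_bp: int = 30_000
    missing_rate: float = 0.005
    planted: PlantedVariant = field(default_factory=PlantedVariant)
    background_n: int = 1000
    background_common_frac: float = 0.8  # fraction with frequency above the 0.1% cutoff
    background_het_frac: float = 0.95  # fraction heterozygous in each carrier
    background_novel_frac: float = 0.5  # of the rare fraction: absent from databases
    csq_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CSQ_PROBS))
    n_inhouse_exomes: int = 560
    max_retries: int = 10_000

    def __post_init__(self):
        if self.recomb_rate_per_mb < 0 or self.missing_rate < 0 or self.missing_rate > 1:
            raise ValueError("rates must be non-negative, probabilities in [0, 1]")
        for frac in (self.background_common_frac, self.background_het_frac, self.background_novel_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("background fractions must be in [0, 1]")
        total = sum(self.csq_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("csq_probs must sum to 1")


# ---------------------------------------------------------------------------
# haplotype dropping


def _slice_hap(hap: Hap, a: int, b: int) -> tuple[list[int], list[int]]:
    """Breakpoints (interior only) and labels of ``hap`` restricted to [a, b)."""
    breaks, labels = hap
    i = int(np.searchsorted(breaks, a, side="right")) - 1
    j = int(np.searchsorted(breaks, b, side="left"))
    inner = [int(x) for x in breaks[i + 1 : j]]
    return inner, [int(x) for x in labels[i:j]]


def _meiosis(h0: Hap, h1: Hap, length: int, rate_per_mb: float, rng) -> Hap:
    """One recombinant gamete from the parental haplotype pair."""
    lam = length / 1e6 * rate_per_mb
    k = int(rng.poisson(lam))
    if k:
        xpts = np.unique(rng.integers(1, length, size=k))
    else:
        xpts = np.empty(0, dtype=np.int64)
    cur = int(rng.integers(0, 2))
    cuts = [0, *[int(x) for x in xpts], length]
    out_breaks: list[int] = [0]
    out_labels: list[int] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if a >= b:
            continue
        inner, labels = _slice_hap(h0 if cur == 0 else h1, a, b)
        for br, lab in zip([*inner, b], labels):
            if out_labels and out_labels[-1] == lab:
                out_breaks[-1] = br  # merge with previous equal-label segment
            else:
                out_labels.append(lab)
                out_breaks.append(br)
        cur ^= 1
    return np.array(out_breaks, dtype=np.int64), np.array(out_labels, dtype=np.int64)


def drop_haplotypes(
    pedigree: Pedigree,
    chrom_lengths: dict[str, int],
    rate_per_mb: float,
    rng,
) -> dict[str, tuple[dict[str, Hap], dict[str, Hap]]]:
    """Drop founder haplotypes through the pedigree for the given chromosomes.

    Returns per individual a (paternal, maternal) pair of per-chromosome
    mosaics.  Founder haplotype labels are ``2 * f`` and ``2 * f + 1``
    where ``f`` indexes founders in pedigree order.
    """
    founders = pedigree.founders
    fidx = {iid: i for i, iid in enumerate(founders)}
    mosaics: dict[str, tuple[dict[str, Hap], dict[str, Hap]]] = {}
    for iid in pedigree.topological_order():
        ind = pedigree.members[iid]
        pat: dict[str, Hap] = {}
        mat: dict[str, Hap] = {}
        for chrom, length in chrom_lengths.items():
            if ind.is_founder:
                f = fidx[iid]
                pat[chrom] = (np.array([0, length]), np.array([2 * f]))
                mat[chrom] = (np.array([0, length]), np.array([2 * f + 1]))
            else:
                fh = mosaics[ind.father]
                mh = mosaics[ind.mother]
                pat[chrom] = _meiosis(fh[0][chrom], fh[1][chrom], length, rate_per_mb, rng)
                mat[chrom] = _meiosis(mh[0][chrom], mh[1][chrom], length, rate_per_mb, rng)
        mosaics[iid] = (pat, mat)
    return mosaics


def _ibd_chrom(pat: Hap, mat: Hap) -> list[tuple[int, int]]:
    """Segments of one chromosome where the two mosaics share a label."""
    b1, l1 = pat
    b2, l2 = mat
    out: list[tuple[int, int]] = []
    i = j = 0
    cur = 0
    end = int(b1[-1])
    while cur < end:
        nxt = min(int(b1[i + 1]), int(b2[j + 1]))
        if l1[i] == l2[j]:
            if out and out[-1][1] == cur:
                out[-1] = (out[-1][0], nxt)
            else:
                out.append((cur, nxt))
        if int(b1[i + 1]) == nxt:
            i += 1
        if int(b2[j + 1]) == nxt:
            j += 1
        cur = nxt
    return out


def true_ibd(mosaic: tuple[dict[str, Hap], dict[str, Hap]]) -> iv.IntervalSet:
    """True autozygous (HBD) segments of one individual."""
    pat, mat = mosaic
    out = {}
    for chrom in pat:
        segs = _ibd_chrom(pat[chrom], mat[chrom])
        if segs:
            out[chrom] = np.array(segs, dtype=np.int64)
    return out


def hap_label_at(hap: Hap, pos0: int) -> int:
    """Founder-haplotype label carried by ``hap`` at 0-based position."""
    breaks, labels = hap
    i = int(np.searchsorted(breaks, pos0, side="right")) - 1
    return int(labels[i])


# ---------------------------------------------------------------------------
# genotype synthesis


def _founder_layers(
    panel: MarkerPanel,
    n_haps: int,
    beta: tuple[float, float],
    rng,
    af_range: tuple[float, float] | None = None,
):
    """Per-marker alt-allele frequencies and founder haplotype alleles.

    Frequencies are Beta(``beta``) by default; ``af_range`` switches to a
    uniform draw on a fixed interval (emulating an array whose SNPs were
    ascertained to be common).
    """
    freqs: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    for chrom, pos in panel.positions.items():
        if af_range is not None:
            p = rng.uniform(af_range[0], af_range[1], size=pos.size)
        else:
            p = rng.beta(beta[0], beta[1], size=pos.size)
        freqs[chrom] = p
        alleles[chrom] = (rng.random((n_haps, pos.size)) < p).astype(np.uint8)
    return freqs, alleles


def synthesize_genotypes(
    mosaics,
    panel: MarkerPanel,
    founder_alleles: dict[str, np.ndarray],
    missing_rate: float,
    rng,
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Genotype calls for ``samples`` from their haplotype mosaics."""
    samples = list(samples) if samples is not None else list(mosaics)
    data: dict[str, np.ndarray] = {}
    for chrom, pos in panel.positions.items():
        pos0 = pos - 1
        block = np.empty((len(samples), pos.size), dtype=np.int8)
        for si, sample in enumerate(samples):
            geno = np.zeros(pos.size, dtype=np.int8)
            for hap in mosaics[sample]:
                breaks, labels = hap[chrom]
                idx = np.searchsorted(breaks, pos0, side="right") - 1
                geno += founder_alleles[chrom][labels[idx], np.arange(pos.size)]
            block[si] = geno
        if missing_rate > 0:
            block[rng.random(block.shape) < missing_rate] = -1
        data[chrom] = block
    return GenotypeMatrix(samples=samples, panel=panel, data=data)


@dataclass
class GeneDropResult:
    """Everything one gene-drop run produced (truth included)."""

    pedigree: Pedigree
    panel: MarkerPanel
    genotypes: GenotypeMatrix | None
    mosaics: dict
    ibd: dict[str, iv.IntervalSet]  # per-sample true autozygome
    founder_freqs: dict[str, np.ndarray] | None = None
    founder_alleles: dict[str, np.ndarray] | None = None

    def ibd_fraction(self, sample: str, chrom_lengths: dict[str, int]) -> float:
        return iv.total_length(self.ibd[sample]) / sum(chrom_lengths.values())


def gene_drop(
    pedigree: Pedigree,
    panel: MarkerPanel | None,
    params: SimParams,
    rng=None,
    genotype_samples: list[str] | None = None,
) -> GeneDropResult:
    """Drop haplotypes and (if a panel is given) synthesize genotype calls.

    With ``panel=None`` only the haplotype mosaics and true-IBD labels are
    produced, which is sufficient for autozygosity calibration work.
    """
    if panel is not None:
        for chrom in panel.chroms:
            if chrom not in params.chrom_lengths:
                raise PanelError(f"panel chromosome {chrom!r} not in simulated genome")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    mosaics = drop_haplotypes(pedigree, params.chrom_lengths, params.recomb_rate_per_mb, rng)
    ibd = {iid: true_ibd(m) for iid, m in mosaics.items()}
    genotypes = freqs = alleles = None
    if panel is not None:
        n_haps = 2 * len(pedigree.founders)
        freqs, alleles = _founder_layers(
            panel, n_haps, params.founder_af_beta, rng, params.founder_af_range
        )
        genotypes = synthesize_genotypes(
            mosaics, panel, alleles, params.missing_rate, rng, genotype_samples
        )
    return GeneDropResult(pedigree, panel, genotypes, mosaics, ibd, freqs, alleles)


# ---------------------------------------------------------------------------
# variant planting


def _draw_background(pedigree: Pedigree, params: SimParams, rng) -> list[VariantRecord]:
    """Family-level background variant annotations (zygosity filled later)."""
    n = params.background_n
    if n == 0:
        return []
    chroms = list(params.chrom_lengths)
    lengths = np.array([params.chrom_lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[ci]).astype(np.int64) + 1
    common = rng.random(n) < params.background_common_frac
    af = np.where(
        common,
        rng.uniform(0.002, 0.5, size=n),
        np.where(
            rng.random(n) < params.background_novel_frac,
            0.0,
            rng.uniform(1e-5, 0.001, size=n),
        ),
    )
    two_n = 2 * params.n_inhouse_exomes
    af_inhouse = rng.binomial(two_n, af) / two_n
    csq_names = list(params.csq_probs)
    csq = rng.choice(len(csq_names), size=n, p=[params.csq_probs[c] for c in csq_names])
    pp2 = rng.random(n)
    sift = rng.random(n)
    cons = rng.normal(0.0, 1.0, size=n)
    refalt = rng.integers(0, 4, size=(n, 2))
    refalt[:, 1] = (refalt[:, 0] + 1 + refalt[:, 1] % 3) % 4  # force ref != alt
    records = []
    for k in range(n):
        c = csq_names[int(csq[k])]
        scored = c in ("missense", "inframe-indel")
        records.append(
            VariantRecord(
                chrom=chroms[int(ci[k])],
                pos=int(pos[k]),
                ref=str(_NUCS[refalt[k, 0]]),
                alt=str(_NUCS[refalt[k, 1]]),
                zygosity="het",
                csq=c,
                af_pop={"POP": float(af[k])} if af[k] > 0 else {},
                af_inhouse=float(af_inhouse[k]),
                polyphen=float(pp2[k]) if scored else None,
                sift=float(sift[k]) if scored else None,
                conservation=float(cons[k]) if c != "non-coding" else None,
                gene=f"BG{k:04d}",
            )
        )
    return records


def _causal_record(spec: PlantedVariant, zygosity: str) -> VariantRecord:
    return VariantRecord(
        chrom=spec.chrom,
        pos=spec.pos,
        ref=spec.ref,
        alt=spec.alt,
        zygosity=zygosity,
        csq=spec.csq,
        af_pop={},
        af_inhouse=0.0,
        polyphen=spec.polyphen,
        sift=spec.sift,
        conservation=spec.conservation,
        gene=spec.gene,
        transcript=spec.transcript,
        protein_change=spec.protein_change,
    )


def plant_causal_variant(
    drop: GeneDropResult, params: SimParams, rng
) -> dict[str, list[VariantRecord]]:
    """Emit annotated variant sets per affected individual.

    The causal allele is attached to the founder haplotype for which all
    affected individuals are autozygous at the planted position; it is
    therefore homozygous in every affected and absent or heterozygous in
    everyone else.  Raises :class:`SimulationError` if the affecteds are
    not autozygous for a common founder haplotype there (the caller is
    expected to re-simulate; see :func:`simulate_family`).
    """
    spec = params.planted
    if spec.chrom not in params.chrom_lengths:
        raise PanelError(f"planted chromosome {spec.chrom!r} not in simulated genome")
    pos0 = spec.pos - 1
    affected = drop.pedigree.affected
    if not affected:
        raise SimulationError("pedigree has no affected individuals")
    labels = set()
    for iid in affected:
        pat, mat = drop.mosaics[iid]
        lp = hap_label_at(pat[spec.chrom], pos0)
        lm = hap_label_at(mat[spec.chrom], pos0)
        if lp != lm:
            raise SimulationError(f"affected {iid!r} not autozygous at the planted position")
        labels.add(lp)
    if len(labels) != 1:
        raise SimulationError("affecteds autozygous for different founder haplotypes")
    causal_label = labels.pop()

    background = _draw_background(drop.pedigree, params, rng)
    out: dict[str, list[VariantRecord]] = {}
    chrom_order = {c: i for i, c in enumerate(params.chrom_lengths)}
    for iid in affected:
        pat, mat = drop.mosaics[iid]
        dose = int(hap_label_at(pat[spec.chrom], pos0) == causal_label) + int(
            hap_label_at(mat[spec.chrom], pos0) == causal_label
        )
        recs = [_causal_record(spec, "hom" if dose == 2 else "het")]
        for r in background:
            zyg = "het" if rng.random() < params.background_het_frac else "hom"
            recs.append(replace(r, zygosity=zyg))
        recs.sort(key=lambda v: (chrom_order.get(v.chrom, 99), v.pos))
        out[iid] = recs
    return out


@dataclass
class FamilySim:
    """One simulated family: gene-drop truth plus annotated variant sets."""

    drop: GeneDropResult
    variants: dict[str, list[VariantRecord]]
    params: SimParams
    n_rejected: int = 0

    @property
    def pedigree(self) -> Pedigree:
        return self.drop.pedigree


def simulate_family(
    pedigree: Pedigree,
    params: SimParams,
    panel: MarkerPanel | None = None,
    genotype_samples: list[str] | None = None,
    rng=None,
) -> FamilySim:
    """Simulate one family conditioned on affected autozygosity at the locus.

    Rejection sampling re-draws the planted variant's chromosome until all
    affected individuals are autozygous for the same founder haplotype at
    the planted position (chromosomes segregate independently under the
    Haldane model, so only that chromosome needs re-drawing); the retry
    cap raises :class:`RetryLimitError`.  The remaining chromosomes are
    then dropped once and genotypes/variants synthesized.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    spec = params.planted
    if spec.chrom not in params.chrom_lengths:
        raise PanelError(f"planted chromosome {spec.chrom!r} not in simulated genome")
    focal_genome = {spec.chrom: params.chrom_lengths[spec.chrom]}
    pos0 = spec.pos - 1
    affected = pedigree.affected
    if not affected:
        raise SimulationError("pedigree has no affected individuals")

    n_rejected = 0
    for _ in range(params.max_retries):
        focal = drop_haplotypes(pedigree, focal_genome, params.recomb_rate_per_mb, rng)
        labels = set()
        for iid in affected:
            pat, mat = focal[iid]
            lp = hap_label_at(pat[spec.chrom], pos0)
            lm = hap_label_at(mat[spec.chrom], pos0)
            labels.update((lp, lm))
        if len(labels) == 1:
            break
        n_rejected += 1
    else:
        raise RetryLimitError(
            f"no accepted configuration in {params.max_retries} attempts"
        )

    rest_genome = {c: L for c, L in params.chrom_lengths.items() if c != spec.chrom}
    rest = drop_haplotypes(pedigree, rest_genome, params.recomb_rate_per_mb, rng)
    mosaics = {}
    for iid in pedigree.members:
        pat = {spec.chrom: focal[iid][0][spec.chrom], **rest[iid][0]}
        mat = {spec.chrom: focal[iid][1][spec.chrom], **rest[iid][1]}
        # restore genome chromosome order for reproducible downstream output
        pat = {c: pat[c] for c in params.chrom_lengths}
        mat = {c: mat[c] for c in params.chrom_lengths}
        mosaics[iid] = (pat, mat)

    ibd = {iid: true_ibd(m) for iid, m in mosaics.items()}
    genotypes = freqs = alleles = None
    if panel is not None:
        n_haps = 2 * len(pedigree.founders)
        freqs, alleles = _founder_layers(
            panel, n_haps, params.founder_af_beta, rng, params.founder_af_range
        )
        genotypes = synthesize_genotypes(
            mosaics, panel, alleles, params.missing_rate, rng, genotype_samples
        )
    drop = GeneDropResult(pedigree, panel, genotypes, mosaics, ibd, freqs, alleles)
    variants = plant_causal_variant(drop, params, rng)
    return FamilySim(drop=drop, variants=variants, params=params, n_rejected=n_rejected)
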