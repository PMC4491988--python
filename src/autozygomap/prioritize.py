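"""Variant filter cascade and pathogenicity classification.

The cascade reduces an annotated exome variant list to likely causal
candidates for a fully penetrant recessive lethal phenotype: a variant
must be novel or very rare (maximum frequency over all population
sources and the in-house cohort at most 0.1%), coding or splicing,
homozygous, inside the affected individual's autozygome, and predicted
pathogenic.  Pathogenicity is likely if the variant is loss-of-function
(stopgain / frameshift / splice-site), or, for missense and in-frame
indels, if it removes a conserved residue and both in-silico predictors
agree (PolyPhen at least ``pp2_min``, SIFT at most ``sift_max``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import AutozygomapError
from .roh import Autozygome, variant_in_autozygome

logger = logging.getLogger(__name__)

LOF = "lof"
DAMAGING_MISSENSE = "damaging-missense"
BENIGN_OR_UNKNOWN = "benign-or-unknown"

LOF_CLASSES = frozenset({"stopgain", "frameshift", "splice-site"})
MISSENSE_CLASSES = frozenset({"missense", "inframe-indel"})
CONSEQUENCE_CLASSES = (
    "stopgain", "frameshift", "splice-site", "missense",
    "inframe-indel", "synonymous", "non-coding",
)

#: Genes with an established link to lethal non-immune hydrops fetalis in
#: severe presentations (mucopolysaccharidosis VII, galactosialidosis,
#: nemaline myopathy, fetal akinesia).
DEFAULT_KNOWN_GENES = frozenset({"GUSB", "CTSA", "NEB", "CHRNA1"})

KNOWN_CAUSE = "known-cause"
NOVEL_CANDIDATE = "novel-candidate"

FILTER_NAMES = ("frequency", "consequence", "zygosity", "autozygome", "pathogenicity")


@dataclass
class VariantRecord:
    """One annotated sequence variant (1-based position, per-allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # 'hom' | 'het' | 'missing'
    csq: str
    af_pop: dict[str, float] = field(default_factory=dict)
    af_inhouse: float | None = None
    polyphen: float | None = None
    sift: float | None = None
    conservation: float | None = None
    gene: str | None = None
    transcript: str | None = None
    protein_change: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")
        if self.zygosity not in ("hom", "het", "missing"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.csq not in CONSEQUENCE_CLASSES:
            raise ValueError(f"invalid consequence class {self.csq!r}")
        for f in (*self.af_pop.values(), self.af_inhouse):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must be in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def max_frequency(self) -> float:
        """Maximum over population sources and in-house cohort; absent = 0."""
        freqs = list(self.af_pop.values())
        if self.af_inhouse is not None:
            freqs.append(self.af_inhouse)
        return max(freqs, default=0.0)

    @property
    def is_novel(self) -> bool:
        return self.max_frequency() == 0.0


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults documented per field)."""

    max_af: float = 0.001  # novel or very low frequency (0.1%)
    pp2_min: float = 0.9
    sift_max: float = 0.05
    cons_min: float = 1.2816  # 90th percentile of the N(0,1) synthetic score
    coding_csq: frozenset = frozenset(
        {"stopgain", "frameshift", "splice-site", "missense", "inframe-indel", "synonymous"}
    )
    known_genes: frozenset = DEFAULT_KNOWN_GENES
    inhouse_mode: str = "threshold"  # 'threshold' | 'absence'

    def __post_init__(self):
        if not 0.0 <= self.max_af <= 1.0:
            raise ValueError("max_af must be in [0, 1]")
        if not 0.0 <= self.pp2_min <= 1.0 or not 0.0 <= self.sift_max <= 1.0:
            raise ValueError("PolyPhen/SIFT thresholds must be in [0, 1]")
        if self.inhouse_mode not in ("threshold", "absence"):
            raise ValueError("inhouse_mode must be 'threshold' or 'absence'")


@dataclass
class FilterTrace:
    """Ordered per-filter verdicts for one variant."""

    variant: VariantRecord
    verdicts: list[tuple[str, bool]]

    @property
    def retained(self) -> bool:
        return all(ok for _, ok in self.verdicts)

    @property
    def first_failed(self) -> str | None:
        for name, ok in self.verdicts:
            if not ok:
                return name
        return None


def classify_pathogenic(variant: VariantRecord, config: FilterConfig | None = None) -> str:
    """Classify a variant as lof / damaging-missense / benign-or-unknown.

    Loss-of-function classes are pathogenic unconditionally.  Missense and
    in-frame indels require conservation and both predictors; missing
    scores fail closed to benign-or-unknown with a logged warning.
    """
    config = config or FilterConfig()
    if variant.csq in LOF_CLASSES:
        return LOF
    if variant.csq in MISSENSE_CLASSES:
        scores = (variant.polyphen, variant.sift, variant.conservation)
        if any(s is None for s in scores):
            logger.warning(
                "missense variant %s:%d %s lacks in-silico scores; treated as benign-or-unknown",
                variant.chrom, variant.pos, variant.gene or "",
            )
            return BENIGN_OR_UNKNOWN
        if (
            variant.conservation >= config.cons_min
            and variant.polyphen >= config.pp2_min
            and variant.sift <= config.sift_max
        ):
            return DAMAGING_MISSENSE
    return BENIGN_OR_UNKNOWN


def _passes_frequency(variant: VariantRecord, config: FilterConfig) -> bool:
    pop_max = max(variant.af_pop.values(), default=0.0)
    if pop_max > config.max_af:
        return False
    inhouse = variant.af_inhouse or 0.0
    if config.inhouse_mode == "absence":
        return inhouse == 0.0
    return inhouse <= config.max_af


def filter_variants(
    variants: list[VariantRecord],
    autozygome: Autozygome | dict,
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Apply the five-filter cascade; returns retained variants and traces.

    All five verdicts are evaluated for every variant (the retained set is
    therefore independent of filter order); a variant is retained iff all
    pass.
    """
    config = config or FilterConfig()
    retained: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    for v in variants:
        verdicts = [
            ("frequency", _passes_frequency(v, config)),
            ("consequence", v.csq in config.coding_csq),
            ("zygosity", v.zygosity == "hom"),
            ("autozygome", variant_in_autozygome(v.chrom, v.pos, autozygome)),
            ("pathogenicity", classify_pathogenic(v, config) != BENIGN_OR_UNKNOWN),
        ]
        trace = FilterTrace(variant=v, verdicts=verdicts)
        traces.append(trace)
        if trace.retained:
            retained.append(v)
    return retained, traces


def truncation_fraction(protein_length: int, stop_codon_position: int) -> float:
    """Fraction of the protein lost to a premature stop codon."""
    if not 1 <= stop_codon_position <= protein_length:
        raise ValueError(
            f"stop position {stop_codon_position} outside 1..{protein_length}"
        )
    return (protein_length - stop_codon_position + 1) / protein_length


def label_known_gene(
    variant: VariantRecord, known_gene_list=DEFAULT_KNOWN_GENES
) -> str:
    """Label a candidate as a known phenotype gene or a novel candidate."""
    if variant.gene is None:
        raise AutozygomapError("variant has no gene symbol")
    return KNOWN_CAUSE if variant.gene in known_gene_list else NOVEL_CANDIDATE
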