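"""Bundled worked example: a 19-family lethal-NIHF exome cohort.

The packaged table carries the single candidate variant that survived
exome filtering in each of 19 consanguineous families with recurrent
lethal non-immune hydrops fetalis (one family retained no variant).
Gene symbols, transcripts, HGVS changes and PolyPhen/SIFT scores are as
published; genomic chrom/pos/ref/alt are synthetic placeholders assigned
deterministically per distinct cDNA change (identical change, identical
coordinates), which is the only property cross-family founder-variant
grouping relies on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mapping import AffectedEvidence, FamilyEvidence
from .prioritize import VariantRecord
from .roh import Autozygome

#: Nominal inbreeding coefficient assigned to cohort probands (all families
#: are consanguineous; first-cousin unions are the most common design).
COHORT_F = 0.0625


def load_nihf_cohort() -> pd.DataFrame:
    """The cohort table as a DataFrame (one row per family)."""
    with resources.files("autozygomap.data").joinpath("nihf_cohort.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def cohort_families() -> list[FamilyEvidence]:
    """Cohort as mapping-ready evidence, one proband per family.

    Probands carry an empty autozygome placeholder (array data are not
    bundled) and the nominal first-cousin F; families whose filtering
    retained no variant contribute an empty variant list.
    """
    df = load_nihf_cohort()
    out = []
    for row in df.itertuples(index=False):
        variants = []
        if isinstance(row.gene, str) and row.gene:
            variants.append(
                VariantRecord(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    zygosity="hom",
                    csq=row.csq,
                    polyphen=None if pd.isna(row.polyphen) else float(row.polyphen),
                    sift=None if pd.isna(row.sift) else float(row.sift),
                    gene=row.gene,
                    transcript=row.transcript,
                    protein_change=row.protein,
                )
            )
        proband = AffectedEvidence(
            sample=f"{row.family}_P",
            autozygome=Autozygome(sample=f"{row.family}_P"),
            inbreeding=COHORT_F,
            variants=variants,
        )
        out.append(FamilyEvidence(family_id=row.family, affecteds=[proband]))
    return out
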