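"""Readers and writers for the formats the pipeline touches.

Formats:

* **VCF 4.2** (via pysam) with the INFO keys ``AF_POP`` (population
  allele frequency), ``AF_INHOUSE`` (in-house cohort frequency),
  ``CSQ_CLASS`` (consequence class), ``PP2``/``SIFT``/``CONS``
  (in-silico scores), ``GENE``/``TRANSCRIPT``/``PCHANGE``; one sample
  column carrying GT. Multi-allelic records are decomposed to one
  :class:`~autozygomap.prioritize.VariantRecord` per alternate allele.
* **PED**: 6 columns (family, individual, father, mother, sex,
  phenotype), tab- or space-separated, ``0`` for unknown parent,
  phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown.
* **genotype TSV dialect**: a PLINK-style ``.map`` file (chrom, marker
  id, genetic position 0, bp) plus a TSV of calls with columns
  ``chrom``, ``pos`` and one column per sample (0/1/2/-1).
* **BED4**: chrom, 0-based start, half-open end, sample/name.

VCF positions are 1-based; all interval output is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import intervals as ivmod
from .errors import PedParseError, VcfParseError
from .genome import GenotypeMatrix, MarkerPanel
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree
from .prioritize import VariantRecord
from .roh import Autozygome, RohInterval

logger = logging.getLogger(__name__)

_INFO_FIELDS = [
    ("AF_POP", "A", "Float", "Maximum population allele frequency"),
    ("AF_INHOUSE", "A", "Float", "In-house cohort allele frequency"),
    ("CSQ_CLASS", "A", "String", "Consequence class"),
    ("PP2", "A", "Float", "PolyPhen-2 score"),
    ("SIFT", "A", "Float", "SIFT score"),
    ("CONS", "A", "Float", "Conservation score"),
    ("GENE", "A", "String", "Gene symbol"),
    ("TRANSCRIPT", "A", "String", "Transcript id"),
    ("PCHANGE", "A", "String", "Protein change"),
]

_PHENO_TO_STATUS = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_STATUS_TO_PHENO = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(sample: str, contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    return header


def write_annotated_vcf(
    records: list[VariantRecord],
    path: str | Path,
    sample: str,
    contigs: dict[str, int],
) -> None:
    """Write one sample's annotated variants as uncompressed VCF 4.2."""
    header = _vcf_header(sample, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in records:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.af_pop:
                rec.info["AF_POP"] = (max(v.af_pop.values()),)
            if v.af_inhouse is not None:
                rec.info["AF_INHOUSE"] = (v.af_inhouse,)
            rec.info["CSQ_CLASS"] = (v.csq,)
            if v.polyphen is not None:
                rec.info["PP2"] = (v.polyphen,)
            if v.sift is not None:
                rec.info["SIFT"] = (v.sift,)
            if v.conservation is not None:
                rec.info["CONS"] = (v.conservation,)
            if v.gene:
                rec.info["GENE"] = (v.gene,)
            if v.transcript:
                rec.info["TRANSCRIPT"] = (v.transcript,)
            if v.protein_change:
                rec.info["PCHANGE"] = (v.protein_change,)
            gt = {"hom": (1, 1), "het": (0, 1), "missing": (None, None)}[v.zygosity]
            rec.samples[sample]["GT"] = gt
            vcf.write(rec)


def _prescan_vcf(path: str | Path) -> None:
    """Cheap structural check so parse errors can name a line number."""
    with open(path) as fh:
        n_fixed = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                raise VcfParseError("empty line", lineno)
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_fixed = len(line.split("\t"))
                if n_fixed < 8:
                    raise VcfParseError("truncated #CHROM header", lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 8 or (n_fixed is not None and len(fields) != n_fixed):
                raise VcfParseError("wrong number of fields", lineno)
            if not fields[1].isdigit():
                raise VcfParseError(f"non-numeric POS {fields[1]!r}", lineno)


def _info_scalar(rec, key: str, alt_index: int):
    try:
        val = rec.info.get(key)
    except (KeyError, ValueError):  # key not defined in this header
        return None
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[alt_index] if alt_index < len(val) else val[0]
    return val


def read_annotated_vcf(path: str | Path) -> list[VariantRecord]:
    """Read an annotated VCF into VariantRecords (one per alternate allele).

    Missing INFO annotations stay absent (``None``), except frequencies,
    which default to 0 with a logged notice (absence from the databases is
    treated as novelty).  Zygosity comes from the first sample's GT.
    """
    _prescan_vcf(path)
    out: list[VariantRecord] = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts):
                    af_pop = _info_scalar(rec, "AF_POP", ai)
                    af_inh = _info_scalar(rec, "AF_INHOUSE", ai)
                    if af_pop is None and af_inh is None:
                        logger.info(
                            "variant %s:%d has no frequency annotation; treated as novel",
                            rec.contig, rec.pos,
                        )
                    csq = _info_scalar(rec, "CSQ_CLASS", ai) or "non-coding"
                    zyg = "missing"
                    if samples:
                        gt = rec.samples[samples[0]].get("GT")
                        if gt and None not in gt:
                            n_alt = sum(1 for g in gt if g == ai + 1)
                            zyg = "hom" if n_alt == len(gt) else ("het" if n_alt else "missing")
                    out.append(
                        VariantRecord(
                            chrom=rec.contig,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            zygosity=zyg,
                            csq=str(csq),
                            af_pop={"POP": float(af_pop)} if af_pop is not None else {},
                            af_inhouse=float(af_inh) if af_inh is not None else 0.0,
                            polyphen=_maybe_float(_info_scalar(rec, "PP2", ai)),
                            sift=_maybe_float(_info_scalar(rec, "SIFT", ai)),
                            conservation=_maybe_float(_info_scalar(rec, "CONS", ai)),
                            gene=_maybe_str(_info_scalar(rec, "GENE", ai)),
                            transcript=_maybe_str(_info_scalar(rec, "TRANSCRIPT", ai)),
                            protein_change=_maybe_str(_info_scalar(rec, "PCHANGE", ai)),
                        )
                    )
    except VcfParseError:
        raise
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"malformed VCF {path}: {exc}") from exc
    return out


def _maybe_float(x):
    return None if x is None else float(x)


def _maybe_str(x):
    return None if x is None else str(x)


# ---------------------------------------------------------------------------
# PED


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and validate a 6-column PED file (single family)."""
    individuals = []
    family_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedParseError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            fid, iid, father, mother, sex, pheno = fields[:6]
            family_ids.add(fid)
            status = _PHENO_TO_STATUS.get(pheno, UNKNOWN)
            individuals.append(
                Individual(
                    iid=iid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=int(sex),
                    status=status,
                )
            )
    family_id = sorted(family_ids)[0] if family_ids else "FAM"
    return Pedigree(individuals, family_id=family_id)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iid in pedigree.topological_order():
            ind = pedigree.members[iid]
            fh.write(
                "\t".join(
                    (
                        pedigree.family_id,
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        str(ind.sex),
                        _STATUS_TO_PHENO[ind.status],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# marker panel / genotype TSV dialect


def write_map(panel: MarkerPanel, path: str | Path) -> None:
    """PLINK-style .map: chrom, marker id, genetic position (0), bp."""
    with open(path, "w") as fh:
        for chrom, pos in panel.positions.items():
            for p in pos:
                fh.write(f"{chrom}\t{chrom}:{p}\t0\t{p}\n")


def read_map(path: str | Path) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", names=["chrom", "marker", "cm", "pos"], dtype={"chrom": str})
    positions = {
        str(chrom): grp["pos"].to_numpy(dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return MarkerPanel(positions)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    parts = []
    for chrom, pos in genotypes.panel.positions.items():
        block = pd.DataFrame(
            genotypes.data[chrom].T, columns=genotypes.samples
        )
        block.insert(0, "chrom", chrom)
        block.insert(1, "pos", pos)
        parts.append(block)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path, panel: MarkerPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    data = {}
    for chrom, pos in panel.positions.items():
        grp = df[df["chrom"] == chrom]
        if not np.array_equal(grp["pos"].to_numpy(), pos):
            raise PedParseError(f"genotype TSV positions disagree with panel on {chrom!r}")
        data[chrom] = grp[samples].to_numpy(dtype=np.int8).T
    return GenotypeMatrix(samples=samples, panel=panel, data=data)


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: ivmod.IntervalSet | list[RohInterval], path: str | Path, name: str = ".") -> None:
    """Write intervals (or called ROH) as BED4."""
    with open(path, "w") as fh:
        if isinstance(intervals, dict):
            for chrom, arr in intervals.items():
                for s, e in arr:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
        else:
            for r in intervals:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample}\n")


def read_bed(path: str | Path) -> dict[str, ivmod.IntervalSet]:
    """Read BED4 into interval sets grouped by the name column."""
    by_name: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, *rest = line.split()
            name = rest[0] if rest else "."
            by_name.setdefault(name, {}).setdefault(chrom, []).append(
                (int(start), int(end))
            )
    return {
        name: ivmod.normalize({c: np.array(v) for c, v in ivs.items()})
        for name, ivs in by_name.items()
    }


def autozygome_from_bed(path: str | Path, sample: str) -> Autozygome:
    ivs = read_bed(path).get(sample, {})
    rohs = [
        RohInterval(chrom, int(s), int(e), n_markers=0, sample=sample)
        for chrom, arr in ivs.items()
        for s, e in arr
    ]
    return Autozygome(sample=sample, rohs=rohs)


def write_roh_summary(autozygomes: list[Autozygome], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "n_markers": r.n_markers,
        }
        for az in autozygomes
        for r in az.rohs
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "length", "n_markers"]).to_csv(
        path, sep="\t", index=False
    )
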