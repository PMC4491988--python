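"""End-to-end orchestration: simulate, call ROH, filter, map, report.

The discovery pipeline mirrors the study workflow per family: delineate
each affected's autozygome from array genotypes, restrict the annotated
exome to novel/very-rare, coding, homozygous, autozygous, predicted-
pathogenic variants, and label candidates against the known-gene list;
then across families: group identical retained variants (putative
founder alleles) and scan the genome for the HBD-LOD linkage peak.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .errors import ConfigError, PipelineStageError
from .genome import MarkerPanel
from .mapping import (
    AffectedEvidence,
    FamilyEvidence,
    Peak,
    SharedVariant,
    find_shared_variants,
    scan_genome,
)
from .pedigree import Pedigree, build_consanguineous_pedigree
from .prioritize import (
    FilterConfig,
    classify_pathogenic,
    filter_variants,
    label_known_gene,
)
from .roh import Autozygome, RohParams, call_roh, intersect_autozygomes
from .simulate import SimParams, simulate_family

logger = logging.getLogger(__name__)

__version__ = "1.0.0"


@dataclass
class FamilyInputs:
    """Paths for one family's inputs."""

    family_id: str
    ped: str
    genotypes: str
    vcfs: dict[str, str]  # affected sample id -> annotated VCF


@dataclass
class PipelineConfig:
    panel_map: str
    families: list[FamilyInputs]
    out_dir: str
    roh: RohParams = field(default_factory=RohParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    lod_threshold: float = 3.0
    min_shared_families: int = 2
    autozygome_mode: str = "proband"  # 'proband' | 'intersect'
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.autozygome_mode not in ("proband", "intersect"):
            raise ConfigError("autozygome_mode must be 'proband' or 'intersect'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def _p(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        try:
            families = [
                FamilyInputs(
                    family_id=f["id"],
                    ped=_p(f["ped"]),
                    genotypes=_p(f["genotypes"]),
                    vcfs={s: _p(v) for s, v in f["vcfs"].items()},
                )
                for f in raw["families"]
            ]
            cfg = cls(
                panel_map=_p(raw["panel_map"]),
                families=families,
                out_dir=_p(raw["out_dir"]),
                roh=RohParams(**raw.get("roh", {})),
                filter=FilterConfig(**raw.get("filter", {})),
                lod_threshold=float(raw.get("lod_threshold", 3.0)),
                min_shared_families=int(raw.get("min_shared_families", 2)),
                autozygome_mode=raw.get("autozygome_mode", "proband"),
                seed=int(raw.get("seed", 0)),
                verbosity=raw.get("verbosity", "INFO"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc
        for fi in cfg.families:
            for p in (fi.ped, fi.genotypes, *fi.vcfs.values()):
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
        if not Path(cfg.panel_map).exists():
            raise ConfigError(f"input file not found: {cfg.panel_map}")
        return cfg


@dataclass
class CandidateRow:
    family: str
    sample: str
    gene: str | None
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_change: str | None
    classification: str
    relevance: str  # known-cause | novel-candidate


@dataclass
class CandidateReport:
    """Structured pipeline result mirroring the per-family candidate table."""

    families: dict[str, list[CandidateRow]]
    shared: list[SharedVariant]
    peaks: list[Peak]
    stage_counts: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "families": {
                fid: [dataclasses.asdict(r) for r in rows]
                for fid, rows in self.families.items()
            },
            "shared_variants": [
                {
                    "chrom": s.key[0],
                    "pos": s.key[1],
                    "ref": s.key[2],
                    "alt": s.key[3],
                    "gene": s.gene,
                    "families": s.families,
                    "n_families": s.n_families,
                }
                for s in self.shared
            ],
            "peaks": [dataclasses.asdict(p) for p in self.peaks],
            "stage_counts": self.stage_counts,
        }


def _family_autozygome(
    sample: str, autozygomes: dict[str, Autozygome], mode: str
) -> Autozygome | dict:
    if mode == "proband" or len(autozygomes) == 1:
        return autozygomes[sample]
    return intersect_autozygomes(list(autozygomes.values()))


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    """Execute the full discovery pipeline and write all outputs.

    Per family: ROH calling per affected -> autozygome (single proband or
    intersection per config) -> variant filter cascade -> known-gene
    labeling.  Across families: founder-variant grouping and the genome-
    wide HBD-LOD scan.  Outputs (BED, TSVs, filtered VCFs, JSON report,
    run manifest) go to ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        panel = aio.read_map(config.panel_map)
    except Exception as exc:
        raise PipelineStageError("read-panel", f"{config.panel_map}: {exc}") from exc

    evidence: list[FamilyEvidence] = []
    report_rows: dict[str, list[CandidateRow]] = {}
    stage_counts: dict[str, dict[str, int]] = {}
    all_autozygomes: list[Autozygome] = []
    contigs = {c: int(panel.positions[c][-1]) + 1 for c in panel.chroms}

    for fam in config.families:
        try:
            pedigree = aio.read_pedigree(fam.ped)
        except Exception as exc:
            raise PipelineStageError("read-pedigree", f"{fam.ped}: {exc}") from exc
        try:
            genotypes = aio.read_genotypes_tsv(fam.genotypes, panel)
        except Exception as exc:
            raise PipelineStageError("read-genotypes", f"{fam.genotypes}: {exc}") from exc

        autozygomes: dict[str, Autozygome] = {}
        for sample in fam.vcfs:
            try:
                autozygomes[sample] = call_roh(genotypes, panel, sample, config.roh)
            except Exception as exc:
                raise PipelineStageError("roh-calling", f"{fam.family_id}/{sample}: {exc}") from exc
        all_autozygomes.extend(autozygomes.values())

        affecteds = []
        rows: list[CandidateRow] = []
        for sample, vcf_path in fam.vcfs.items():
            try:
                variants = aio.read_annotated_vcf(vcf_path)
            except Exception as exc:
                raise PipelineStageError("read-vcf", f"{vcf_path}: {exc}") from exc
            az = _family_autozygome(sample, autozygomes, config.autozygome_mode)
            retained, traces = filter_variants(variants, az, config.filter)
            counts = {"input": len(variants)}
            for name in ("frequency", "consequence", "zygosity", "autozygome", "pathogenicity"):
                counts[name] = sum(
                    1 for t in traces if dict(t.verdicts)[name]
                )
            counts["retained"] = len(retained)
            stage_counts[f"{fam.family_id}/{sample}"] = counts
            logger.info("%s/%s: %s", fam.family_id, sample, counts)

            trace_rows = [
                {
                    "chrom": t.variant.chrom,
                    "pos": t.variant.pos,
                    "ref": t.variant.ref,
                    "alt": t.variant.alt,
                    **{name: int(ok) for name, ok in t.verdicts},
                    "retained": int(t.retained),
                    "first_failed": t.first_failed or "",
                }
                for t in traces
            ]
            pd.DataFrame(trace_rows).to_csv(
                out_dir / f"{fam.family_id}.{sample}.trace.tsv", sep="\t", index=False
            )
            aio.write_annotated_vcf(
                retained, out_dir / f"{fam.family_id}.{sample}.filtered.vcf", sample, contigs
            )
            for v in retained:
                rows.append(
                    CandidateRow(
                        family=fam.family_id,
                        sample=sample,
                        gene=v.gene,
                        chrom=v.chrom,
                        pos=v.pos,
                        ref=v.ref,
                        alt=v.alt,
                        protein_change=v.protein_change,
                        classification=classify_pathogenic(v, config.filter),
                        relevance=label_known_gene(v, config.filter.known_genes)
                        if v.gene
                        else "novel-candidate",
                    )
                )
            inbreeding = pedigree.inbreeding(sample)
            affecteds.append(
                AffectedEvidence(
                    sample=sample,
                    autozygome=autozygomes[sample],
                    inbreeding=inbreeding,
                    variants=retained,
                )
            )
        evidence.append(FamilyEvidence(family_id=fam.family_id, affecteds=affecteds))
        report_rows[fam.family_id] = rows

    try:
        shared = find_shared_variants(evidence, min_families=config.min_shared_families)
        peaks = scan_genome(evidence, panel, threshold=config.lod_threshold)
    except Exception as exc:
        raise PipelineStageError("cross-family-mapping", str(exc)) from exc

    report = CandidateReport(
        families=report_rows, shared=shared, peaks=peaks, stage_counts=stage_counts
    )
    _write_outputs(report, all_autozygomes, config, out_dir)
    return report


def _config_hash(config: PipelineConfig) -> str:
    # fingerprint of the analytic parameters only: two runs of the same
    # analysis agree regardless of where inputs/outputs live on disk
    blob = {
        "roh": dataclasses.asdict(config.roh),
        "filter": {
            k: sorted(v) if isinstance(v, frozenset) else v
            for k, v in dataclasses.asdict(config.filter).items()
        },
        "lod_threshold": config.lod_threshold,
        "min_shared_families": config.min_shared_families,
        "autozygome_mode": config.autozygome_mode,
        "seed": config.seed,
        "families": sorted(f.family_id for f in config.families),
    }
    return hashlib.sha256(
        json.dumps(blob, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_outputs(report, autozygomes, config, out_dir: Path) -> None:
    aio.write_bed(
        [r for az in autozygomes for r in az.rohs], out_dir / "roh.bed"
    )
    aio.write_roh_summary(autozygomes, out_dir / "roh_summary.tsv")
    cand = [dataclasses.asdict(r) for rows in report.families.values() for r in rows]
    pd.DataFrame(
        cand,
        columns=["family", "sample", "gene", "chrom", "pos", "ref", "alt",
                 "protein_change", "classification", "relevance"],
    ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": s.key[0], "pos": s.key[1], "ref": s.key[2], "alt": s.key[3],
                "gene": s.gene, "n_families": s.n_families,
                "families": ",".join(s.families),
            }
            for s in report.shared
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "n_families", "families"],
    ).to_csv(out_dir / "shared_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(p) for p in report.peaks],
        columns=["chrom", "start", "end", "peak_lod", "peak_pos"],
    ).to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    manifest = {
        "package": "autozygomap",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "stage_counts": report.stage_counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort simulation (the `simulate` entry point)


@dataclass
class CohortSimConfig:
    """Configuration of a simulated multi-family study cohort."""

    n_families: int = 3
    union_type: str = "first-cousin"
    n_affected_children: int = 2
    n_sequenced_affected: int = 1
    params: SimParams = field(default_factory=SimParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("params", {})
        planted = sim_raw.pop("planted", None)
        params = SimParams(**sim_raw)
        if planted:
            from .simulate import PlantedVariant

            params.planted = PlantedVariant(**planted)
        return cls(**raw, params=params)


def simulate_cohort(config: CohortSimConfig, out_dir: str | Path) -> list[Path]:
    """Simulate a cohort sharing one planted founder allele; write all files.

    Per family ``i`` (seeded ``seed + i``): PED, genotype TSV for the
    sequenced affecteds, one annotated VCF per sequenced affected, a
    truth BED of true-IBD segments and a truth TSV of the planted
    variant.  A shared .map file describes the marker panel.  Returns the
    list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = MarkerPanel.uniform(config.params.chrom_lengths, config.params.marker_spacing_bp)
    written = []
    map_path = out_dir / "panel.map"
    aio.write_map(panel, map_path)
    written.append(map_path)
    contigs = dict(config.params.chrom_lengths)
    families = []
    for i in range(config.n_families):
        fid = f"FAM{i + 1}"
        pedigree = build_consanguineous_pedigree(
            config.union_type, config.n_affected_children, family_id=fid
        )
        params = dataclasses.replace(config.params, seed=int(config.params.seed) + i)
        sequenced = pedigree.affected[: config.n_sequenced_affected]
        fam = simulate_family(pedigree, params, panel=panel, genotype_samples=sequenced)
        ped_path = out_dir / f"{fid}.ped"
        aio.write_pedigree(pedigree, ped_path)
        geno_path = out_dir / f"{fid}.genotypes.tsv"
        aio.write_genotypes_tsv(fam.drop.genotypes, geno_path)
        vcfs = {}
        for sample in sequenced:
            vcf_path = out_dir / f"{fid}.{sample}.vcf"
            aio.write_annotated_vcf(fam.variants[sample], vcf_path, sample, contigs)
            vcfs[sample] = str(vcf_path)
            written.append(vcf_path)
        truth_bed = out_dir / f"{fid}.true_ibd.bed"
        with open(truth_bed, "w") as fh:
            for sample in pedigree.topological_order():
                for chrom, arr in fam.drop.ibd[sample].items():
                    for s, e in arr:
                        fh.write(f"{chrom}\t{s}\t{e}\t{sample}\n")
        spec = params.planted
        truth_tsv = out_dir / f"{fid}.planted.tsv"
        with open(truth_tsv, "w") as fh:
            fh.write("family\tgene\tchrom\tpos\tref\talt\tcsq\n")
            fh.write(
                f"{fid}\t{spec.gene}\t{spec.chrom}\t{spec.pos}\t{spec.ref}\t{spec.alt}\t{spec.csq}\n"
            )
        written.extend([ped_path, geno_path, truth_bed, truth_tsv])
        # paths in cohort.yaml are relative to the yaml itself, so the
        # simulated cohort directory can be moved or renamed freely
        families.append(
            {
                "id": fid,
                "ped": ped_path.name,
                "genotypes": geno_path.name,
                "vcfs": {s: Path(v).name for s, v in vcfs.items()},
            }
        )
    cohort_yaml = out_dir / "cohort.yaml"
    with open(cohort_yaml, "w") as fh:
        yaml.safe_dump(
            {
                "panel_map": map_path.name,
                "families": families,
                "out_dir": "results",
                "seed": int(config.params.seed),
            },
            fh,
            sort_keys=True,
        )
    written.append(cohort_yaml)
    return written
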