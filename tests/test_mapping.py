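import math

import numpy as np
import pytest

from autozygomap.errors import MappingError, NotHomozygousError
from autozygomap.genome import GenotypeMatrix, MarkerPanel
from autozygomap.mapping import (
    AffectedEvidence,
    FamilyEvidence,
    find_shared_variants,
    hbd_lod,
    max_attainable_lod,
    scan_genome,
    shared_haplotype_span,
)
from autozygomap.pedigree import build_consanguineous_pedigree
from autozygomap.prioritize import VariantRecord
from autozygomap.roh import Autozygome, RohInterval, call_roh
from autozygomap.simulate import SimParams, gene_drop


def make_autozygome(sample, intervals):
    return Autozygome(
        sample=sample,
        rohs=[RohInterval(c, s, e, 0, sample) for c, s, e in intervals],
    )


def family(fid, sample, intervals, f=1 / 16, variants=()):
    return FamilyEvidence(
        family_id=fid,
        affecteds=[
            AffectedEvidence(
                sample=sample,
                autozygome=make_autozygome(sample, intervals),
                inbreeding=f,
                variants=list(variants),
            )
        ],
    )


class TestHbdLod:
    def test_single_first_cousin_affected_scores_log10_16(self):
        fam = family("F1", "P1", [("13", 50_000_000, 60_000_000)])
        score = hbd_lod([fam], "13", 53_000_000)
        assert score.lod == pytest.approx(math.log10(16), rel=1e-12)

    def test_two_families_scores_are_additive(self):
        fams = [
            family("F1", "P1", [("13", 50_000_000, 60_000_000)]),
            family("F2", "P2", [("13", 45_000_000, 55_000_000)]),
        ]
        score = hbd_lod(fams, "13", 53_000_000)
        assert score.lod == pytest.approx(2 * math.log10(16), rel=1e-12)
        assert score.per_family["F1"] == pytest.approx(math.log10(16), rel=1e-12)

    def test_non_hbd_affected_excludes_the_locus(self):
        fams = [
            family("F1", "P1", [("13", 50_000_000, 60_000_000)]),
            family("F2", "P2", [("1", 10_000_000, 20_000_000)]),
        ]
        assert hbd_lod(fams, "13", 53_000_000).lod == -math.inf

    def test_exclusion_scores_clamp_for_display_only(self):
        from autozygomap.mapping import clamp_lod

        assert clamp_lod(-math.inf) == -10.0
        assert clamp_lod(1.2) == 1.2

    def test_zero_inbreeding_is_rejected(self):
        with pytest.raises(MappingError):
            hbd_lod([family("F1", "P1", [("1", 0, 1_000_000)], f=0.0)], "1", 500)

    def test_double_first_cousin_contributes_log10_8(self):
        fam = family("F1", "P1", [("2", 0, 10_000_000)], f=1 / 8)
        assert hbd_lod([fam], "2", 5_000_000).lod == pytest.approx(math.log10(8))


class TestScanGenome:
    def panel(self):
        return MarkerPanel.uniform({"1": 60_000_000, "13": 60_000_000}, 1_000_000)

    def test_threshold_above_attainable_bound_gives_no_peaks(self):
        fams = [family("F1", "P1", [("13", 10_000_000, 30_000_000)])]
        bound = max_attainable_lod(fams)
        assert scan_genome(fams, self.panel(), threshold=bound + 0.1) == []

    def test_single_first_cousin_family_cannot_reach_lod_3(self):
        fams = [family("F1", "P1", [("13", 10_000_000, 30_000_000)])]
        assert scan_genome(fams, self.panel(), threshold=3.0) == []

    def test_shared_hbd_region_forms_a_single_peak_containing_locus(self):
        fams = [
            family("F1", "P1", [("13", 10_000_000, 30_000_000)]),
            family("F2", "P2", [("13", 20_000_000, 40_000_000)]),
        ]
        peaks = scan_genome(fams, self.panel(), threshold=2.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.chrom == "13"
        assert p.start >= 20_000_000 - 1 and p.end <= 30_000_000
        assert p.peak_lod == pytest.approx(2 * math.log10(16))
        assert p.start < 25_000_000 - 1 < p.end  # locus inside the peak

    def test_genomewide_maximum_respects_upper_bound(self):
        rng = np.random.default_rng(4)
        fams = []
        for k in range(3):
            s = int(rng.integers(0, 50_000_000))
            fams.append(family(f"F{k}", f"P{k}", [("1", s, s + 10_000_000)]))
        scores = [
            hbd_lod(fams, "1", int(p)).lod
            for p in self.panel().positions["1"]
        ]
        finite = [s for s in scores if s > -math.inf]
        assert all(s <= max_attainable_lod(fams) + 1e-12 for s in finite)


class TestSharedVariants:
    def variant(self, fid, pos=617, gene="THSD1"):
        return VariantRecord(
            chrom="13", pos=pos, ref="G", alt="A", zygosity="hom",
            csq="missense", gene=gene,
        )

    def test_identical_variant_in_three_families_is_reported_once(self):
        fams = [
            family(f"F{k}", f"P{k}", [], variants=[self.variant(k)]) for k in range(3)
        ]
        shared = find_shared_variants(fams, min_families=2)
        assert len(shared) == 1
        assert shared[0].n_families == 3
        assert shared[0].gene == "THSD1"

    def test_disjoint_variants_yield_empty_report(self):
        fams = [
            family(f"F{k}", f"P{k}", [], variants=[self.variant(k, pos=100 + k)])
            for k in range(3)
        ]
        assert find_shared_variants(fams, min_families=2) == []

    def test_min_families_one_reports_every_variant(self):
        fams = [
            family(f"F{k}", f"P{k}", [], variants=[self.variant(k, pos=100 + k)])
            for k in range(3)
        ]
        assert len(find_shared_variants(fams, min_families=1)) == 3


def test_hbd_probability_at_unlinked_position_estimates_f():
    """Monte-Carlo validation of the score denominator: the fraction of
    gene-drop replicates in which a first-cousin offspring is HBD at a
    fixed position estimates F = 1/16."""
    ped = build_consanguineous_pedigree("first-cousin", 1)
    params = SimParams(seed=0, chrom_lengths={"1": 200_000_000})
    rng = np.random.default_rng(31)
    from autozygomap import intervals as iv

    n = 400
    hits = sum(
        iv.contains_point(gene_drop(ped, None, params, rng=rng).ibd["C1"], "1", 100_000_000)
        for _ in range(n)
    )
    p_hat = hits / n
    se = math.sqrt(1 / 16 * 15 / 16 / n)
    assert abs(p_hat - 1 / 16) < 3 * se


class TestSharedHaplotypeSpan:
    def build(self, calls):
        pos = np.arange(1, len(calls[0]) + 1) * 1_000_000
        panel = MarkerPanel({"13": pos})
        gmat = GenotypeMatrix(
            samples=[f"S{i}" for i in range(len(calls))],
            panel=panel,
            data={"13": np.asarray(calls, dtype=np.int8)},
        )
        return gmat, panel, pos

    def test_identical_flanks_extend_to_first_discordance(self):
        # markers 0..10; focal at index 5; discordance at indices 0 and 10
        row_a = [1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 0]
        row_b = [0, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        gmat, panel, pos = self.build([row_a, row_b])
        span = shared_haplotype_span(gmat, panel, "13", int(pos[5]), ["S0", "S1"])
        assert span == (int(pos[1] - 1), int(pos[9]))

    def test_discordant_immediate_flanks_cover_focal_marker_only(self):
        row_a = [2, 0, 2, 0, 2]
        row_b = [2, 2, 2, 2, 2]
        gmat, panel, pos = self.build([row_a, row_b])
        span = shared_haplotype_span(gmat, panel, "13", int(pos[2]), ["S0", "S1"])
        assert span == (int(pos[2] - 1), int(pos[2]))

    def test_single_carrier_span_matches_its_roh(self):
        row = [1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 1]
        gmat, panel, pos = self.build([row])
        span = shared_haplotype_span(gmat, panel, "13", int(pos[5]), ["S0"])
        from autozygomap.roh import RohParams

        az = call_roh(gmat, panel, "S0", RohParams(min_markers=5, max_het=0))
        assert len(az) == 1
        assert span == (az.rohs[0].start, az.rohs[0].end)

    def test_non_homozygous_carrier_is_rejected(self):
        row_a = [2, 2, 1, 2, 2]
        row_b = [2, 2, 2, 2, 2]
        gmat, panel, pos = self.build([row_a, row_b])
        with pytest.raises(NotHomozygousError):
            shared_haplotype_span(gmat, panel, "13", int(pos[2]), ["S0", "S1"])

    def test_missing_calls_are_tolerated_up_to_limit(self):
        row_a = [2, -1, 2, 2, 2, -1, 2]
        row_b = [2, 2, 2, 2, 2, 2, 2]
        gmat, panel, pos = self.build([row_a, row_b])
        wide = shared_haplotype_span(gmat, panel, "13", int(pos[3]), ["S0", "S1"], max_missing=2)
        assert wide == (int(pos[0] - 1), int(pos[6]))
        narrow = shared_haplotype_span(gmat, panel, "13", int(pos[3]), ["S0", "S1"], max_missing=0)
        assert narrow == (int(pos[2] - 1), int(pos[4]))
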