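import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autozygomap import intervals as iv
from autozygomap.errors import PanelError, SampleNotFoundError
from autozygomap.genome import GenotypeMatrix, MarkerPanel
from autozygomap.pedigree import build_consanguineous_pedigree
from autozygomap.roh import (
    RohParams,
    call_roh,
    intersect_autozygomes,
    subtract_autozygome,
    variant_in_autozygome,
)
from autozygomap.simulate import SimParams, gene_drop
from conftest import matrix_from_codes
from oracles import bases, brute_force_roh, set_to_intervals


def intervals_of(az):
    return {(r.chrom, r.start, r.end) for r in az.rohs}


def test_fully_homozygous_chromosome_is_one_run():
    pos = np.arange(1, 201) * 50_000  # 200 markers spanning 10 Mb
    gmat, panel = matrix_from_codes([2] * 200, pos)
    az = call_roh(gmat, panel, "S1")
    assert intervals_of(az) == {("1", int(pos[0] - 1), int(pos[-1]))}
    assert az.rohs[0].n_markers == 200


def test_alternating_heterozygous_calls_yield_empty_autozygome():
    pos = np.arange(1, 201) * 50_000
    codes = [2, 1] * 100
    gmat, panel = matrix_from_codes(codes, pos)
    assert len(call_roh(gmat, panel, "S1")) == 0


def test_interior_het_tolerance_splits_or_keeps_run():
    # 3 Mb homozygous run (200 markers at 15 kb) with one central het
    pos = np.arange(1, 201) * 15_000
    codes = np.full(200, 2, dtype=np.int8)
    codes[100] = 1
    gmat, panel = matrix_from_codes(codes, pos)
    tolerant = call_roh(gmat, panel, "S1", RohParams(max_het=1))
    assert intervals_of(tolerant) == {("1", int(pos[0] - 1), int(pos[-1]))}
    strict = call_roh(gmat, panel, "S1", RohParams(max_het=0))
    assert len(strict) == 0  # both sub-runs < 2 Mb
    # oracle agreement for both tolerance settings
    for params in (RohParams(max_het=1), RohParams(max_het=0)):
        got = {(r.start, r.end) for r in call_roh(gmat, panel, "S1", params).rohs}
        assert got == brute_force_roh(codes, pos, params)


def test_run_shorter_than_two_megabases_is_excluded():
    pos = np.arange(1, 101) * 15_000  # 100 markers spanning 1.5 Mb
    gmat, panel = matrix_from_codes([0] * 100, pos)
    assert len(call_roh(gmat, panel, "S1")) == 0


def test_exactly_two_megabases_is_excluded_by_strict_threshold():
    # length == threshold must not pass (strictly greater required)
    pos = np.array([1] + [1 + k * 20_000 for k in range(1, 100)] + [2_000_000])
    codes = [2] * len(pos)
    gmat, panel = matrix_from_codes(codes, pos)
    params = RohParams(min_markers=10)
    assert len(call_roh(gmat, panel, "S1", params)) == 0


def test_large_marker_gaps_break_runs():
    # two 3 Mb homozygous blocks separated by a 5 Mb assay desert
    left = np.arange(1, 101) * 30_000
    right = left + 8_000_000
    pos = np.concatenate([left, right])
    gmat, panel = matrix_from_codes([2] * 200, pos)
    az = call_roh(gmat, panel, "S1", RohParams(min_markers=50))
    assert intervals_of(az) == {
        ("1", int(left[0] - 1), int(left[-1])),
        ("1", int(right[0] - 1), int(right[-1])),
    }


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.data())
def test_call_roh_equals_bruteforce_enumeration(data):
    n = data.draw(st.integers(min_value=2, max_value=60))
    codes = np.array(
        data.draw(st.lists(st.sampled_from([0, 1, 2, -1]), min_size=n, max_size=n)),
        dtype=np.int8,
    )
    gaps = np.array(
        data.draw(
            st.lists(
                st.integers(min_value=1_000, max_value=400_000), min_size=n - 1, max_size=n - 1
            )
        )
    )
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)])
    params = RohParams(
        min_length_bp=data.draw(st.sampled_from([100_000, 500_000, 2_000_000])),
        min_markers=data.draw(st.integers(min_value=1, max_value=10)),
        max_het=data.draw(st.integers(min_value=0, max_value=3)),
        max_missing=data.draw(st.integers(min_value=0, max_value=3)),
        max_gap_bp=data.draw(st.sampled_from([150_000, 1_000_000])),
    )
    gmat, panel = matrix_from_codes(codes, pos)
    got = {(r.start, r.end) for r in call_roh(gmat, panel, "S1", params).rohs}
    assert got == brute_force_roh(codes, pos, params)


def test_recovery_of_true_ibd_segments_by_called_roh():
    """On gene-drop output with a common-MAF panel, long true-IBD segments
    are recovered by called ROH and, with zero het tolerance, no long
    called run falls wholly outside true IBD."""
    ped = build_consanguineous_pedigree("first-cousin", 1)
    genome = {"1": 150_000_000, "2": 150_000_000}
    params = SimParams(
        seed=13,
        chrom_lengths=genome,
        founder_af_range=(0.2, 0.8),
        missing_rate=0.005,
    )
    panel = MarkerPanel.uniform(genome, 30_000)
    rng = np.random.default_rng(77)
    long_total = 0
    long_recovered = 0
    stray = 0
    for _ in range(15):
        res = gene_drop(ped, panel, params, rng=rng, genotype_samples=["C1"])
        truth = res.ibd["C1"]
        az = call_roh(res.genotypes, panel, "C1", RohParams(max_het=0))
        called = az.interval_set()
        for chrom, arr in truth.items():
            for s, e in arr:
                if e - s <= 4_000_000:
                    continue
                long_total += 1
                overlap = iv.total_length(
                    iv.intersect_two({chrom: np.array([[s, e]])}, called)
                )
                if overlap >= 0.8 * (e - s):
                    long_recovered += 1
        for r in az.rohs:
            if r.length > 2_000_000:
                overlap = iv.total_length(
                    iv.intersect_two({r.chrom: np.array([[r.start, r.end]])}, truth)
                )
                if overlap == 0:
                    stray += 1
    assert long_total > 0
    assert long_recovered >= 0.9 * long_total
    assert stray == 0


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.data())
def test_interval_algebra_matches_per_base_oracle(data):
    def draw_set(label):
        n = data.draw(st.integers(min_value=0, max_value=6), label=f"{label}_n")
        rows = []
        for k in range(n):
            s = data.draw(st.integers(min_value=0, max_value=9_000), label=f"{label}{k}s")
            e = data.draw(st.integers(min_value=s + 1, max_value=10_000), label=f"{label}{k}e")
            rows.append((s, e))
        return iv.normalize({"1": np.array(rows)}) if rows else {}

    a, b = draw_set("a"), draw_set("b")
    inter = iv.intersect_many([a, b])
    assert set_to_intervals(bases(a, "1") & bases(b, "1")) == {
        tuple(r) for r in inter.get("1", np.empty((0, 2)))
    }
    diff = iv.subtract(a, b)
    assert set_to_intervals(bases(a, "1") - bases(b, "1")) == {
        tuple(r) for r in diff.get("1", np.empty((0, 2)))
    }
    # outputs disjoint and sorted
    for res in (inter, diff):
        for arr in res.values():
            assert np.all(arr[:, 1] > arr[:, 0])
            assert np.all(arr[1:, 0] >= arr[:-1, 1])


def test_autozygome_intersection_identities(fc_pedigree, small_params, small_panel):
    res = gene_drop(fc_pedigree, small_panel, small_params)
    az = call_roh(res.genotypes, small_panel, "C1")
    same = intersect_autozygomes([az, az])
    assert {c: a.tolist() for c, a in same.items()} == {
        c: a.tolist() for c, a in az.interval_set().items()
    }
    x = az.interval_set()
    minus_empty = subtract_autozygome(x, {})
    assert {c: a.tolist() for c, a in minus_empty.items()} == {
        c: a.tolist() for c, a in x.items()
    }
    assert subtract_autozygome(x, x) == {}
    with pytest.raises(ValueError):
        intersect_autozygomes([])


def test_variant_position_boundary_conventions():
    pos = np.arange(1, 201) * 50_000
    gmat, panel = matrix_from_codes([2] * 200, pos)
    az = call_roh(gmat, panel, "S1")
    start, end = az.rohs[0].start, az.rohs[0].end
    assert variant_in_autozygome("1", start + 1, az)  # 1-based position at start
    assert variant_in_autozygome("1", end, az)  # last base inside half-open end
    assert not variant_in_autozygome("1", end + 1, az)
    with pytest.raises(ValueError):
        variant_in_autozygome("1", 0, az)


def test_missing_sample_and_panel_mismatch_raise(small_panel):
    pos = np.arange(1, 201) * 50_000
    gmat, panel = matrix_from_codes([2] * 200, pos)
    with pytest.raises(SampleNotFoundError):
        call_roh(gmat, panel, "nobody")
    with pytest.raises(PanelError):
        call_roh(gmat, MarkerPanel({"1": pos * 2}), "S1")
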