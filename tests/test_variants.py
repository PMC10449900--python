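import numpy as np
import pytest

from conftest import seeded, small_sim_config
from dropwgs import variants
from dropwgs.models import VariantCall
from oracles import merge_clusters_oracle, somatic_snv_oracle


def snv(pos, ref="A", alt="T", sample="s", contig="chr1"):
    return VariantCall(contig, pos, pos + 1, ref, alt, "SNV", sample_id=sample)


def sv(svtype, start, length, sample="s", precise=True, contig="chr1"):
    end = start if svtype == "INS" else start + length
    svlen = -length if svtype == "DEL" else length
    return VariantCall(contig, start, end, "N", f"<{svtype}>", svtype,
                       svlen=svlen, precise=precise, sample_id=sample)


# -- normalization ------------------------------------------------------------


def test_trim_alleles():
    v = VariantCall("chr1", 10, 13, "ATT", "TTT", "INDEL")
    t = variants.trim_alleles(v)
    assert (t.start, t.ref, t.alt, t.svtype) == (10, "A", "T", "SNV")
    v2 = VariantCall("chr1", 5, 8, "CAA", "CA", "INDEL")
    t2 = variants.trim_alleles(v2)
    assert (t2.start, t2.ref, t2.alt) == (5, "CA", "C")


def test_left_align_is_canonical_within_a_run():
    #            0123456789
    reference = "GGAAAAATCGT"
    # two equivalent representations of "delete one A from the run"
    v1 = VariantCall("chr1", 5, 7, "AA", "A", "INDEL")
    v2 = VariantCall("chr1", 3, 5, "AA", "A", "INDEL")
    s1 = variants.left_align(v1, reference)
    s2 = variants.left_align(v2, reference)
    assert s1 == s2
    assert s1.start == 2  # leftmost position of the A-run
    # idempotence
    assert variants.left_align(s1, reference) == s1


def test_unnormalized_input_warns_and_normalizes():
    messy = VariantCall("chr1", 10, 13, "ATT", "TTT", "INDEL")
    with pytest.warns(UserWarning, match="auto-normalized"):
        res = variants.evaluate_snvs([messy], [snv(10)])
    assert res.tp == 1 and res.fp == 0


# -- SNV evaluation -----------------------------------------------------------


def test_identical_sets_perfect_scores():
    calls = [snv(i * 10) for i in range(20)]
    res = variants.evaluate_snvs(calls, calls)
    assert (res.tp, res.fp, res.fn) == (20, 0, 0)
    assert res.precision == 1.0 and res.sensitivity == 1.0


def test_disjoint_sets_zero_tp():
    res = variants.evaluate_snvs([snv(1)], [snv(2)])
    assert res.tp == 0 and res.precision == 0.0 and res.sensitivity == 0.0
    assert variants.intersect_snvs([snv(1)], [snv(2)]) == []


def test_allele_identity_required():
    assert variants.intersect_snvs([snv(5, alt="T")], [snv(5, alt="G")]) == []
    assert len(variants.intersect_snvs([snv(5)], [snv(5)])) == 1


# -- somatic SNV filter -------------------------------------------------------


def test_somatic_filter_rules():
    shared = snv(100)
    only_one = snv(200)
    in_bulk = snv(300)
    in_other = snv(400)
    indel = VariantCall("chr1", 500, 502, "AT", "A", "INDEL")
    masked = snv(600)
    cells = {
        "A": [
            [shared, only_one, in_bulk, in_other, indel, masked],
            [shared, in_bulk, in_other, indel, masked],
        ],
        "B": [[in_other], [snv(999)]],
    }
    out = variants.somatic_snv_filter(cells, bulk=[in_bulk],
                                      repeat_mask=[("chr1", 590, 610)])
    kept = {(v.start, clone) for v, clone in out}
    assert kept == {(100, "A")}


def test_somatic_filter_small_clone_warns():
    cells = {"A": [[snv(1)]], "B": [[snv(2)], [snv(2)]]}
    with pytest.warns(UserWarning, match="<2 cells"):
        out = variants.somatic_snv_filter(cells, bulk=[])
    assert {(v.start, c) for v, c in out} == {(2, "B")}


def test_somatic_filter_matches_set_logic_oracle_random():
    rng = seeded(42)
    for trial in range(20):
        cells = {"A": [[], [], []], "B": [[], [], []]}
        bulk = []
        mask = [("chr1", 5000, 6000)]
        for pos in range(0, 8000, 97):
            v = snv(pos, alt="G")
            for clone in ("A", "B"):
                for i in range(3):
                    if rng.random() < 0.4:
                        cells[clone][i].append(v)
            if rng.random() < 0.2:
                bulk.append(v)
        got = variants.somatic_snv_filter(cells, bulk, mask)
        want = somatic_snv_oracle(cells, bulk, mask)
        assert [(v.site_key(), c) for v, c in got] == [
            (v.site_key(), c) for v, c in want
        ]


# -- SV merging ---------------------------------------------------------------


def test_merge_both_thresholds_met():
    a = sv("DEL", 1000, 2000, "s1")
    b = sv("DEL", 1150, 2000, "s2")  # 150 bp apart, >80% reciprocal overlap
    df = variants.merge_svs([[a], [b]])
    assert len(df) == 1
    assert bool(df.iloc[0]["in_s1"]) and bool(df.iloc[0]["in_s2"])
    assert df.iloc[0]["n_samples"] == 2


def test_no_merge_when_too_far():
    a = sv("DEL", 1000, 2000, "s1")
    b = sv("DEL", 1500, 2000, "s2")  # 500 bp apart
    df = variants.merge_svs([[a], [b]])
    assert len(df) == 2


def test_no_merge_across_types():
    a = sv("DEL", 1000, 500, "s1")
    b = sv("DUP", 1000, 500, "s2")
    assert len(variants.merge_svs([[a], [b]])) == 2


def test_insertion_length_ratio_rule():
    a = sv("INS", 1000, 300, "s1")
    b = sv("INS", 1050, 250, "s2")  # ratio 0.83 >= 0.10 -> merged
    c = sv("INS", 1050, 20, "s3")   # ratio 0.066 < 0.10 -> separate
    df = variants.merge_svs([[a], [b], [c]])
    assert len(df) == 2


def test_merge_precise_flag_and_svlen_median():
    a = sv("DEL", 1000, 2000, "s1", precise=True)
    b = sv("DEL", 1100, 1900, "s2", precise=False)
    df = variants.merge_svs([[a], [b]])
    assert len(df) == 1
    assert not df.iloc[0]["precise"]
    assert df.iloc[0]["svlen"] == 1950


def _random_svs(rng, n, n_samples=4):
    calls = []
    centers = rng.integers(0, 40_000, size=max(4, n // 6))
    for i in range(n):
        svtype = ["DEL", "INS", "DUP", "INV"][int(rng.integers(0, 4))]
        center = int(centers[int(rng.integers(0, len(centers)))])
        start = max(0, center + int(rng.integers(-400, 400)))
        length = int(rng.integers(50, 3000))
        calls.append(sv(svtype, start, length, f"s{int(rng.integers(0, n_samples))}"))
    return calls


def test_merge_matches_transitive_closure_oracle():
    for seed in range(25):
        rng = seeded(100, seed)
        calls = _random_svs(rng, 50)
        df = variants.merge_svs([calls])
        got = frozenset(frozenset(m) for m in df["members"])
        want = merge_clusters_oracle(calls)
        assert got == want


def test_merge_order_invariance():
    rng = seeded(101)
    calls = _random_svs(rng, 40)
    df1 = variants.merge_svs([calls])
    perm = rng.permutation(len(calls)).tolist()
    permuted = [calls[i] for i in perm]
    df2 = variants.merge_svs([permuted])
    got1 = frozenset(
        frozenset((calls[i].svtype, calls[i].contig, calls[i].start,
                   calls[i].svlen, calls[i].sample_id) for i in m)
        for m in df1["members"]
    )
    got2 = frozenset(
        frozenset((permuted[i].svtype, permuted[i].contig, permuted[i].start,
                   permuted[i].svlen, permuted[i].sample_id) for i in m)
        for m in df2["members"]
    )
    assert got1 == got2


# -- SV truth evaluation ------------------------------------------------------


def test_sv_eval_cell_equals_bulk():
    calls = [sv("DEL", 1000, 500, "cell"), sv("INV", 9000, 700, "cell")]
    bulk = [sv("DEL", 1000, 500, "bulk"), sv("INV", 9000, 700, "bulk")]
    res = variants.sv_true_positives(calls, bulk, cell_sample="cell")
    assert res.precision == 1.0 and res.sensitivity == 1.0
    assert res.per_type["DEL"].precision == 1.0


def test_sv_eval_fp_only():
    calls = [sv("INV", 50_000, 600, "cell")]
    bulk = [sv("DEL", 1000, 500, "bulk")]
    res = variants.sv_true_positives(calls, bulk, cell_sample="cell")
    assert res.tp == 0
    assert res.per_type["INV"].precision == 0.0
    assert res.per_type["DEL"].sensitivity == 0.0


def test_sv_eval_inv_heavy_false_calls_near_zero_precision():
    rng = seeded(7)
    bulk = [sv("INV", int(p), 500, "bulk") for p in range(10_000, 12_000, 1000)]
    false_inv = [
        sv("INV", int(rng.integers(100_000, 5_000_000)), int(rng.integers(50, 3000)),
           "cell")
        for _ in range(40)
    ]
    res = variants.sv_true_positives(false_inv, bulk, cell_sample="cell")
    assert res.per_type["INV"].precision <= 0.05


# -- somatic SV filter --------------------------------------------------------


def _merged_for_cells(event_by_sample):
    sets = [
        [sv(t, s, ln, sample, precise=pr) for t, s, ln, pr in evs]
        for sample, evs in event_by_sample.items()
    ]
    return variants.merge_svs(sets)


def test_somatic_sv_filter_retains_clone_specific_precise():
    ev = ("DEL", 10_000, 800, True)
    merged = _merged_for_cells({
        "bulk": [], "a1": [], "a2": [], "b1": [ev], "b2": [ev], "b3": [],
    })
    out = variants.somatic_sv_filter(
        merged, {"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]}
    )
    assert len(out) == 1
    assert out.iloc[0]["clone"] == "B"


def test_somatic_sv_filter_removes_imprecise_and_bulk():
    imprecise = ("DEL", 10_000, 800, False)
    merged = _merged_for_cells({
        "bulk": [], "a1": [], "a2": [], "b1": [imprecise], "b2": [imprecise],
    })
    out = variants.somatic_sv_filter(merged, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
    assert len(out) == 0
    in_bulk = ("DUP", 5_000, 400, True)
    merged = _merged_for_cells({
        "bulk": [in_bulk], "a1": [in_bulk], "a2": [in_bulk], "b1": [], "b2": [],
    })
    out = variants.somatic_sv_filter(merged, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
    assert len(out) == 0


def test_somatic_sv_filter_no_planted_events_empty():
    merged = variants.merge_svs([[]])
    out = variants.somatic_sv_filter(merged, {"A": ["a1", "a2"]})
    assert len(out) == 0
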