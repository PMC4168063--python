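"""TIR-pair resolution, TSD calling, structural classification and per-copy
feature annotation."""

import numpy as np
import pytest

from tirkit._seq import random_dna, revcomp
from tirkit.annotate import (
    ElementCopy,
    annotate_nested_tes,
    call_tsd,
    check_tpase_motifs,
    classify_structure,
    detect_tir_pair,
    find_at_rich_segments,
    find_longest_orf,
    find_tandem_repeats,
)
from tirkit.simulate import DegradationSpec, plant_copy


# ---------------------------------------------------------------------------
# TIR pair detection
# ---------------------------------------------------------------------------

def _plant_clean(template, group, rng, contig_len=30_000, strand="+",
                 tsd="AAACCCG"):
    # a TSD without self-reverse-complementarity, so flank-vs-flank arm
    # alignment cannot creep through the duplication
    degr = DegradationSpec(substitution_rate=0, indel_rate=0,
                           nested_te_prob=0, tir_tandem_expansion_prob=0)
    contig = random_dna(rng, contig_len)
    return plant_copy(contig, template, group, degr, tsd,
                      contig_len // 2, rng, strand=strand)


class TestDetectTirPair:
    def test_undegraded_group_a_copy(self, template, rng):
        contig, rec = _plant_clean(template, "A", rng)
        pair = detect_tir_pair(contig, (rec.start + 40, rec.end - 40))
        assert pair is not None
        assert abs(pair.lengths[0] - 765) <= 2
        assert abs(pair.lengths[1] - 757) <= 2
        assert pair.percent_identity >= 0.99

    def test_group_f_has_no_inverted_pair(self, template, rng):
        contig, rec = _plant_clean(template, "F", rng)
        pair = detect_tir_pair(contig, (rec.start, rec.end))
        assert pair is None

    def test_perfect_60bp_inverted_repeat_matches_exhaustive_scan(self, rng):
        arm = random_dna(rng, 60)
        insert = arm + random_dna(rng, 880) + revcomp(arm)
        contig = random_dna(rng, 500) + insert + random_dna(rng, 500)
        pair = detect_tir_pair(contig, (500, 500 + len(insert)),
                               max_flank=100, min_tir_len=30)
        assert pair is not None
        # a local aligner may append a couple of chance matches at arm ends
        assert 60 <= pair.lengths[0] <= 63 and 60 <= pair.lengths[1] <= 63
        assert pair.percent_identity >= 0.95
        assert pair.tir5_span[0] <= 500 and pair.tir5_span[1] >= 560
        assert pair.tir3_span[0] <= 1440 and pair.tir3_span[1] >= 1500
        # oracle: longest common substring of the insert and its reverse
        # complement, by dynamic programming
        assert _longest_inverted_repeat(insert) == 60

    def test_mirror_symmetry_under_reverse_complement(self, template, rng):
        contig, rec = _plant_clean(template, "A", rng)
        pair = detect_tir_pair(contig, (rec.start + 40, rec.end - 40))
        rc = revcomp(contig)
        n = len(contig)
        span_rc = (n - rec.end + 40, n - rec.start - 40)
        pair_rc = detect_tir_pair(rc, span_rc)
        assert pair_rc is not None
        assert pair_rc.tir5_span == (n - pair.tir3_span[1], n - pair.tir3_span[0])
        assert pair_rc.tir3_span == (n - pair.tir5_span[1], n - pair.tir5_span[0])

    def test_span_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            detect_tir_pair("ACGT" * 100, (0, 1000))


def _longest_inverted_repeat(seq: str) -> int:
    """O(n^2) oracle: longest exact common substring of seq and revcomp(seq)."""
    import numpy as np
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    best = 0
    prev = np.zeros(len(b), dtype=np.int32)
    for i in range(len(a)):
        cur = np.zeros(len(b), dtype=np.int32)
        match = a[i] == b
        cur[0] = match[0]
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        best = max(best, int(cur.max()))
        prev = cur
    return best


# ---------------------------------------------------------------------------
# TSD calling
# ---------------------------------------------------------------------------

class TestCallTsd:
    def _embed(self, left, right, rng, elem_len=300):
        pre = random_dna(rng, 100)
        elem = random_dna(rng, elem_len)
        post = random_dna(rng, 100)
        contig = pre + left + elem + right + post
        s = 100 + len(left)
        return contig, (s, s + elem_len)

    def test_exact_7bp_duplication(self, rng):
        contig, span = self._embed("GTATTAC", "GTATTAC", rng)
        call, status = call_tsd(contig, span)
        assert status == "ok"
        assert call.length == 7 and call.identical
        assert call.left_seq == call.right_seq == "GTATTAC"

    def test_imperfect_8bp_duplication(self, rng):
        contig, span = self._embed("CGCTAGCC", "GGCTAGCG", rng)
        call, status = call_tsd(contig, span, max_mismatch=2)
        assert status == "ok"
        assert call.length == 8 and call.mismatches == 2 and not call.identical
        assert (call.left_seq, call.right_seq) == ("CGCTAGCC", "GGCTAGCG")

    def test_exact_preferred_over_inexact(self, rng):
        # an exact 7 wins even though an inexact 6 is also present
        contig, span = self._embed("AGTATTAC", "GTATTACT", rng)
        call, _ = call_tsd(contig, span, max_mismatch=1)
        assert call.length == 7 and call.identical
        assert call.left_seq == "GTATTAC"

    def test_inexact_8_preferred_over_inexact_7(self, rng):
        contig, span = self._embed("AGCCTAGG", "TGCCTAGG", rng)
        call, _ = call_tsd(contig, span, max_mismatch=1)
        assert call.length == 8 and call.mismatches == 1

    def test_random_flanks_match_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            contig = random_dna(rng, 400)
            span = (150, 250)
            call, status = call_tsd(contig, span)
            expected = _brute_force_tsd(contig, span)
            if expected is None:
                assert call is None and status == "no_match"
            else:
                assert call is not None
                assert (call.length, call.mismatches) == expected

    def test_edge_signal(self, rng):
        contig = random_dna(rng, 200)
        call, status = call_tsd(contig, (3, 100))
        assert call is None and status == "edge"


def _brute_force_tsd(contig, span, max_len=8, min_len=5, max_mismatch=1):
    s, e = span
    exact = []
    inexact = []
    for k in range(max_len, min_len - 1, -1):
        mism = sum(a != b for a, b in zip(contig[s - k:s], contig[e:e + k]))
        if mism == 0:
            exact.append((k, 0))
        elif mism <= max_mismatch:
            inexact.append((k, mism))
    if exact:
        return exact[0]
    if inexact:
        return inexact[0]
    return None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _copy(n_tirs, coverage):
    c = ElementCopy(copy_id="c", contig="c1", span=(0, 1000), strand="+")
    if n_tirs == 2:
        from tirkit.annotate import TIRPair
        c.tir_pair = TIRPair((0, 100), (900, 1000), (100, 100), 1.0, ("", ""))
    elif n_tirs == 1:
        c.single_tir_span = (0, 100)
    c.tpase_coverage = coverage
    return c


@pytest.mark.parametrize("n_tirs,coverage,expected", [
    (2, 1.0, "A"),
    (2, 0.96, "A"),
    (2, 0.5, "B"),
    (2, 0.0, "D"),
    (2, 0.03, "D"),        # trace coverage from the TIR/ORF overlap
    (1, 0.3, "C"),
    (1, 0.0, "E"),
    (0, 0.4, "F"),
])
def test_classification_rule(n_tirs, coverage, expected):
    assert classify_structure(_copy(n_tirs, coverage), 2646) == expected


def test_classification_rejects_empty_copy():
    with pytest.raises(ValueError):
        classify_structure(_copy(0, 0.0), 2646)


def test_classification_recovery_on_simulation(matched):
    """Per-group recall against simulator truth on the shared fixture."""
    from collections import defaultdict
    per_group = defaultdict(lambda: [0, 0])
    for t, m in matched:
        if len(m) == 1:
            per_group[t.group][0] += int(m.iloc[0].group == t.group)
            per_group[t.group][1] += 1
    for g, (ok, n) in per_group.items():
        assert ok / n >= 0.9, f"group {g}: {ok}/{n}"


# ---------------------------------------------------------------------------
# tandem repeats, AT-rich, nested TEs
# ---------------------------------------------------------------------------

class TestTandemRepeats:
    def test_140bp_unit_times_9(self, rng):
        unit = random_dna(rng, 140)
        regions = find_tandem_repeats(unit * 9)
        assert len(regions) == 1
        (span, period, copies) = regions[0]
        assert period == 140
        assert copies == 9.0
        assert span == (0, 1260)

    def test_random_sequence_has_none(self, rng):
        assert find_tandem_repeats(random_dna(rng, 1000)) == []

    def test_degraded_50bp_unit_matches_lag_scan(self):
        rng = np.random.default_rng(8)
        unit = random_dna(rng, 50)
        seq = list(unit * 4)
        for i in rng.choice(len(seq), size=4, replace=False):   # 2% subs
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        seq = "".join(seq)
        regions = find_tandem_repeats(seq)
        assert len(regions) == 1
        (span, period, copies) = regions[0]
        assert abs(period - 50) <= 2
        assert 3.5 <= copies <= 4.5
        # oracle: direct lag scan confirms high identity at the reported lag
        arr = np.frombuffer(seq.encode(), np.uint8)
        ident = (arr[:-period] == arr[period:]).mean()
        assert ident >= 0.8

    def test_short_input_empty(self):
        assert find_tandem_repeats("ACGT") == []


class TestAtRich:
    def test_embedded_at_segment_recovered(self, rng):
        at = "".join(("A", "T")[int(x)] for x in rng.integers(0, 2, 136))
        gc = "".join(("G", "C")[int(x)] for x in rng.integers(0, 2, 400))
        contig = gc + at + gc
        spans = find_at_rich_segments(contig)
        assert len(spans) == 1
        a, b = spans[0]
        assert b - a == 136
        assert (a, b) == (400, 536)

    def test_all_gc_empty(self):
        assert find_at_rich_segments("GC" * 200) == []

    def test_reported_spans_verify_by_recount(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 10_000, gc=0.5)
        for a, b in find_at_rich_segments(seq, window=100, at_frac=0.8):
            window = seq[a:b]
            at = sum(c in "AT" for c in window)
            assert at / len(window) >= 0.7   # merged span stays AT-dominated

    def test_template_tirs_contain_at_rich_segments(self, template):
        spans = find_at_rich_segments(template.sequence)
        # the planted ~137-bp AT-rich stretches sit inside each arm
        assert any(a < 765 and b - a >= 100 for a, b in spans)
        assert any(a >= 3629 and b - a >= 100 for a, b in spans)


class TestNestedTes:
    def test_planted_decoy_inside(self, template, decoys, rng):
        degr = DegradationSpec(substitution_rate=0, indel_rate=0,
                               nested_te_prob=1.0, tir_tandem_expansion_prob=0)
        contig = random_dna(rng, 20_000)
        contig, rec = plant_copy(contig, template, "A", degr, "GTATTAC",
                                 10_000, rng, decoys=decoys)
        anns = annotate_nested_tes(contig, (rec.start, rec.end), decoys)
        inside = [a for a in anns if a.placement == "inside"]
        assert len(inside) == 1
        truth = rec.nested_insertion_spans[0]
        assert inside[0].te_label == truth[2]
        assert abs(inside[0].span[0] - (rec.start + truth[0])) <= 5
        assert abs(inside[0].span[1] - (rec.start + truth[1])) <= 5

    def test_no_decoys_planted_means_empty(self, template, decoys, rng):
        contig, rec = _plant_clean(template, "A", rng)
        assert annotate_nested_tes(contig, (rec.start, rec.end), decoys) == []

    def test_decoy_outside_tsd_is_flanking(self, template, decoys, rng):
        contig, rec = _plant_clean(template, "A", rng)
        decoy = decoys["decoy_Mar"]
        # insert immediately left of the left TSD copy
        cut = rec.start - 7
        contig2 = contig[:cut] + decoy + contig[cut:]
        span = (rec.start + len(decoy), rec.end + len(decoy))
        anns = annotate_nested_tes(contig2, span, decoys, flank=500)
        flanking = [a for a in anns if a.placement == "flanking"]
        assert len(flanking) == 1 and flanking[0].te_label == "decoy_Mar"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_nested_tes("ACGT" * 100, (0, 100), {})


# ---------------------------------------------------------------------------
# ORFs and motifs
# ---------------------------------------------------------------------------

class TestOrf:
    def test_stop_free_insert_gives_905_residues(self, rng):
        # codon pool chosen so every minus-strand frame accumulates stops
        codons = ("GAA", "GCT", "TTA", "CAT", "TCA", "ATT")
        body = "".join(codons[int(i)] for i in rng.integers(0, 6, 905))
        seq = random_dna(rng, 99) + "TAA" + body + "TAG" + random_dna(rng, 99)
        orf = find_longest_orf(seq)
        assert orf.strand == "+"
        assert len(orf.protein) == 905
        assert orf.span == (102, 102 + 2715)

    def test_all_stops_gives_none(self):
        # 40 tandem stops: the minus strand reads as leucines but stays
        # below the 50-codon floor
        assert find_longest_orf("TAA" * 40) is None

    def test_acg_start_flagged_noncanonical(self, template):
        orf = find_longest_orf(template.sequence, allow_noncanonical_start=True)
        assert orf.start_codon == "ACG"
        assert not orf.canonical_start

    def test_canonical_mode_starts_at_atg(self, rng):
        body = "ACG" + "ATG" + "".join("GCT" for _ in range(100))
        seq = "TAA" + body + "TAA"
        orf = find_longest_orf(seq, allow_noncanonical_start=False, min_codons=50)
        assert orf.start_codon == "ATG"
        assert orf.span[0] == 6


class TestTpaseMotifs:
    def _protein(self):
        from tirkit.annotate import CATALYTIC_RESIDUES, THAP_RESIDUES
        aa = ["A"] * 700
        for pos, res in {**THAP_RESIDUES, **CATALYTIC_RESIDUES}.items():
            aa[pos - 1] = res
        return "".join(aa)

    def test_constructed_positive(self):
        report = check_tpase_motifs(self._protein())
        assert report.all_conserved

    def test_single_mutation_detected(self):
        p = list(self._protein())
        p[326] = "A"                          # D327 -> A
        report = check_tpase_motifs("".join(p))
        assert not report.all_conserved
        assert report.mismatches == [327]

    def test_short_protein_flags_missing(self):
        report = check_tpase_motifs(self._protein()[:100])
        assert not report.all_conserved
        assert report.catalytic_residues[642][1] is None
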