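"""Synthetic-genome generator: templates, insertion sites, planting, whole
genomes."""

import numpy as np
import pytest

from tirkit._seq import revcomp
from tirkit.annotate import check_tpase_motifs, find_longest_orf
from tirkit.simulate import (
    DegradationSpec,
    InsertionModel,
    SyntheticGenomeSpec,
    build_subfamily_templates,
    default_insertion_model,
    plant_copy,
    sample_insertion_site,
    sample_site_sequence,
    segment_p_distance,
    simulate_genome,
    simulate_subfamily_alignment,
)

BASES = "ACGT"


class TestTemplate:
    def test_reference_layout(self, template):
        assert len(template.sequence) == 4386
        assert template.tir5_span == (0, 765)
        assert template.tir3_span == (3629, 4386)
        assert template.orf_span == (983, 3698)
        assert (template.orf_span[1] - template.orf_span[0]) % 3 == 0

    def test_arms_are_inverted_repeats(self, template):
        # identity >= 95% between the 5' arm and the reverse complement of
        # the 3' arm, over the aligned (mapped) positions
        rc = revcomp(template.tir3)
        mapped = [(i, 756 - j) for i, j in enumerate(template.tir_map) if j >= 0]
        matches = sum(template.tir5[i] == rc[k] for i, k in mapped)
        assert matches / len(mapped) >= 0.95

    def test_orf_is_longest_and_noncanonical(self, template):
        orf = find_longest_orf(template.sequence)
        assert orf.span == template.orf_span
        assert orf.strand == "+"
        assert len(orf.protein) == 905
        assert orf.start_codon == "ACG" and not orf.canonical_start

    def test_tpase_motifs_conserved(self, template):
        orf = find_longest_orf(template.sequence)
        report = check_tpase_motifs(orf.protein)
        assert report.all_conserved
        assert report.mismatches == []


class TestSubfamilyTemplates:
    def test_zero_divergence_identity(self, template):
        v, w = build_subfamily_templates(template, 0.0, 0.0, seed=1)
        assert v.sequence == w.sequence == template.sequence

    def test_realized_divergence_in_band(self, template):
        v, w = build_subfamily_templates(template, 0.24, 0.136, seed=1)
        d_tp = segment_p_distance(v.orf, w.orf)
        assert 0.192 <= d_tp <= 0.288        # +-20% relative of 0.24
        d_t5 = segment_p_distance(v.tir5, w.tir5)
        d_t3 = segment_p_distance(v.tir3, w.tir3)
        assert 0.109 <= d_t5 <= 0.163
        assert 0.109 <= d_t3 <= 0.163

    def test_lengths_preserved(self, template):
        v, w = build_subfamily_templates(template, 0.3, 0.1, seed=2)
        assert len(v.sequence) == len(w.sequence) == 4386

    def test_internal_tir_identity_survives_divergence(self, template):
        # mirrored substitutions keep each subfamily's own arms near-identical
        v, _ = build_subfamily_templates(template, 0.24, 0.136, seed=1)
        rc = revcomp(v.tir3)
        mapped = [(i, 756 - j) for i, j in enumerate(v.tir_map) if j >= 0]
        matches = sum(v.tir5[i] == rc[k] for i, k in mapped)
        assert matches / len(mapped) >= 0.95

    def test_saturating_divergence_rejected(self, template):
        with pytest.raises(ValueError):
            build_subfamily_templates(template, 0.8, 0.1, seed=1)


class TestInsertionModel:
    def test_modal_core_is_consensus(self):
        model = default_insertion_model()
        assert model.modal_sequence()[4:11] == "GTATTAC"

    def test_all_mass_profile_yields_consensus_tsd(self, rng):
        prof = np.zeros((15, 4))
        for i, c in enumerate("TAANGTATTACNTTA".replace("N", "A")):
            prof[i, BASES.index(c)] = 1.0
        model = InsertionModel(profile=prof, consensus="NAANGTATTACNTTN",
                               tsd_length_weights={7: 1.0})
        contig = "C" * 500
        _, pos, tsd = sample_insertion_site(contig, model, rng)
        assert tsd == "GTATTAC"
        assert 100 <= pos <= 500 - 100 - 15

    def test_forced_tsd_length_8(self, rng):
        model = default_insertion_model(tsd8_weight=1.0)
        _, _, tsd = sample_insertion_site("G" * 1000, model, rng)
        assert len(tsd) == 8

    def test_contig_too_short(self, rng):
        with pytest.raises(ValueError):
            sample_insertion_site("A" * 150, default_insertion_model(), rng)

    def test_modal_bases_recovered_over_many_draws(self):
        # per-position modal base over a large sample equals the profile mode
        rng = np.random.default_rng(7)
        model = default_insertion_model()
        counts = np.zeros((15, 4), int)
        for _ in range(4000):
            site = sample_site_sequence(model, rng)
            for i, b in enumerate(site):
                counts[i, BASES.index(b)] += 1
        modal = "".join(BASES[i] for i in counts.argmax(axis=1))
        expected = model.modal_sequence()
        # N positions are AT-symmetric: mode there is a coin flip, skip them
        for i, c in enumerate(model.consensus):
            if c != "N":
                assert modal[i] == expected[i]

    def test_frequency_profile_recovered(self):
        # empirical per-position frequencies converge to the model profile
        rng = np.random.default_rng(11)
        model = default_insertion_model()
        counts = np.zeros((15, 4))
        n = 2000
        for _ in range(n):
            site = sample_site_sequence(model, rng)
            for i, b in enumerate(site):
                counts[i, BASES.index(b)] += 1
        assert np.abs(counts / n - model.profile).max() < 0.05


class TestPlanting:
    def test_group_f_has_no_tirs(self, template, rng):
        degr = DegradationSpec(substitution_rate=0, indel_rate=0,
                               nested_te_prob=0, tir_tandem_expansion_prob=0)
        contig = "ACGT" * 2500
        _, rec = plant_copy(contig, template, "F", degr, "GTATTAC", 500, rng)
        assert rec.tir_lengths == (0, 0)

    def test_group_a_length_bookkeeping(self, template, rng):
        degr = DegradationSpec(substitution_rate=0, indel_rate=0,
                               nested_te_prob=0, tir_tandem_expansion_prob=0)
        contig = "ACGT" * 2500
        new, rec = plant_copy(contig, template, "A", degr, "GTATTAC", 500, rng)
        assert len(new) - len(contig) == 4386 + 7
        assert rec.end - rec.start == 4386

    def test_tsd_flanks_identical_at_planting(self, template, rng):
        degr = DegradationSpec(substitution_rate=0.05)
        contig = "GATTACA" * 2000
        new, rec = plant_copy(contig, template, "B", degr, "GTATTAC", 900, rng)
        k = len(rec.tsd_sequence)
        assert new[rec.start - k:rec.start] == rec.tsd_sequence
        assert new[rec.end:rec.end + k] == rec.tsd_sequence

    def test_tandem_expansion_creates_array(self, template):
        rng = np.random.default_rng(3)
        degr = DegradationSpec(substitution_rate=0, indel_rate=0,
                               nested_te_prob=0, tir_tandem_expansion_prob=1.0)
        contig = "ACGT" * 3000
        new, rec = plant_copy(contig, template, "D", degr, "GTATTAC", 500, rng)
        base_len = 765 + (983 - 765) + 757
        grown = (rec.end - rec.start) - base_len
        assert grown >= 2 * 140          # at least two extra ~140-bp units
        assert grown % 140 == 0

    def test_unknown_group_rejected(self, template, rng):
        with pytest.raises(ValueError):
            plant_copy("A" * 1000, template, "Z", DegradationSpec(), "GTATTAC", 100, rng)


class TestSimulateGenome:
    def _spec(self, **kw):
        base = dict(n_copies=6, seed=4, contig_lengths=(120_000,),
                    degradation=DegradationSpec(substitution_rate=0.02))
        base.update(kw)
        return SyntheticGenomeSpec(**base)

    def test_no_copies_means_pure_background(self):
        contigs, truth = simulate_genome(self._spec(n_copies=0))
        assert truth.empty
        assert len(contigs["contig_1"]) == 120_000

    def test_deterministic_given_seed(self):
        a = simulate_genome(self._spec())
        b = simulate_genome(self._spec())
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_different_seed_differs(self):
        a = simulate_genome(self._spec())
        b = simulate_genome(self._spec(seed=8))
        assert a[0] != b[0]

    def test_length_conservation(self):
        contigs, truth = simulate_genome(self._spec())
        extra = sum(t.end - t.start + len(t.tsd) for _, t in truth.iterrows())
        # flanking decoy insertions also add length
        flank = sum(int(s.split("-")[1]) - int(s.split(":")[1].split("-")[0])
                    for f in truth.flanking if f for s in f.split(";"))
        assert len(contigs["contig_1"]) == 120_000 + extra + flank

    def test_truth_tsd_invariant(self):
        contigs, truth = simulate_genome(self._spec())
        c = contigs["contig_1"]
        for _, t in truth.iterrows():
            k = len(t.tsd)
            assert c[t.start - k:t.start] == t.tsd == c[t.end:t.end + k]

    def test_group_counts_override(self):
        spec = self._spec(n_copies=6, group_counts={g: 1 for g in "ABCDEF"},
                          contig_lengths=(200_000,))
        _, truth = simulate_genome(spec)
        assert sorted(truth.group) == list("ABCDEF")

    def test_group_draw_matches_seeded_multinomial(self):
        spec = self._spec(n_copies=50, contig_lengths=(2_000_000,), seed=3)
        _, truth = simulate_genome(spec)
        # reproduce the seeded group draw with an independent generator
        gs = sorted(spec.degradation.group_weights)
        w = np.array([spec.degradation.group_weights[g] for g in gs])
        expected = [gs[i] for i in np.random.default_rng(3).choice(
            len(gs), size=50, p=w / w.sum())]
        assert sorted(truth.group) == sorted(expected)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(self._spec(n_copies=40, contig_lengths=(120_000,)))

    def test_min_spacing_respected(self):
        _, truth = simulate_genome(self._spec(n_copies=8, contig_lengths=(400_000,)))
        starts = sorted(truth.start)
        gaps = np.diff(starts)
        # spacing is enforced on the background; insertions only widen gaps
        assert (gaps >= 6000).all()


class TestSubfamilyAlignmentSimulator:
    def test_realized_divergence_near_targets(self):
        from tirkit.divergence import AlignedSet, p_distance_matrix
        labels, seqs, truth = simulate_subfamily_alignment(seed=2)
        dm = p_distance_matrix(AlignedSet(labels=labels, sequences=seqs))
        idx = {lab: i for i, lab in enumerate(labels)}
        v = [idx[l] for l in labels if truth[l] == "V"]
        w = [idx[l] for l in labels if truth[l] == "W"]
        within_v = np.mean([dm.matrix[a, b] for a in v for b in v if a < b])
        between = np.mean([dm.matrix[a, b] for a in v for b in w])
        assert abs(within_v - 0.047) < 0.015
        assert abs(between - 0.24) < 0.03
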