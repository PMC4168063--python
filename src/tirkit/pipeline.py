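"""End-to-end annotation: scan -> merge -> TIR/TSD resolution -> grouping ->
motif inference, plus the aggregate report.

The query library pairs a TIR segment and the TPase-coding segment (ORF minus
its 3'-TIR overlap) from each available template; searching both strands with
the 5' TIR alone already covers both arms, since the arms are reverse
complements of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .annotate import (
    ElementCopy,
    TIRPair,
    annotate_nested_tes,
    call_tsd,
    classify_structure,
    detect_tir_pair,
    find_at_rich_segments,
    find_tandem_repeats,
    pin_terminus,
    refine_boundaries_by_tsd,
)
from .detect import CandidateCopy, SeedHit, find_seed_hits, merge_hits, query_kind
from .io import PipelineConfig, percent
from .motif import (
    MotifProfile,
    PalindromeReport,
    TSMWindow,
    build_tsm_windows,
    consensus_profile,
    detect_palindrome,
    hairpin_score,
    HairpinReport,
)
from .simulate import ElementTemplate, default_templates


def build_query_library(templates: Sequence[ElementTemplate]) -> dict[str, str]:
    """TIR + TPase query segments per template."""
    queries: dict[str, str] = {}
    for t in templates:
        queries[f"{t.id}_TIR"] = t.tir5
        tp_start = t.orf_span[0]
        tp_end = min(t.orf_span[1], t.tir3_span[0])
        queries[f"{t.id}_TPase"] = t.sequence[tp_start:tp_end]
    return queries


@dataclass
class AnnotationResult:
    copies: list[ElementCopy]
    hits: list[SeedHit]
    candidates: list[CandidateCopy]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _merge_intervals(spans: list[tuple[int, int]], slop: int = 0) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1] + slop:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _expected_terminal(cand: CandidateCopy, queries: Mapping[str, str],
                       k: int = 20) -> str | None:
    """Terminal ``k``-mer of the best-matching TIR query.

    Both element termini read as this word (left) or its reverse complement
    (right) in genome orientation, because the two arms are themselves
    near-reverse-complements of each other.
    """
    tir_hits = [h for h in cand.member_hits if query_kind(h.query_id) == "tir"]
    if not tir_hits:
        return None
    best = max(tir_hits, key=lambda h: h.identity)
    return queries[best.query_id][:k]


def _tpase_coverage(members: Sequence[SeedHit], queries: Mapping[str, str]) -> float:
    per_query: dict[str, list[tuple[int, int]]] = {}
    for h in members:
        if query_kind(h.query_id) == "tpase":
            per_query.setdefault(h.query_id, []).append(h.query_span)
    best = 0.0
    for qid, spans in per_query.items():
        covered = sum(e - s for s, e in _merge_intervals(spans))
        best = max(best, covered / len(queries[qid]))
    return min(1.0, best)


def annotate_candidate(contig_seq: str, cand: CandidateCopy, queries: Mapping[str, str],
                       config: PipelineConfig, copy_id: str,
                       te_library: Mapping[str, str] | None = None,
                       preferred_motif: str | None = None) -> ElementCopy | None:
    """Resolve one candidate into an annotated copy (None when it is neither
    TIR- nor TPase-bearing)."""
    tir_hits = [h for h in cand.member_hits if query_kind(h.query_id) == "tir"]
    tir_loci = _merge_intervals([(h.start, h.end) for h in tir_hits], slop=30)

    tir_pair: TIRPair | None = None
    single_tir = None
    # Hit extents anchor the element boundaries: the query arms end exactly at
    # the element termini, so hit ends cannot overrun into the flank, whereas
    # the flank-vs-flank arm alignment can creep through the (palindromic)
    # target site.  The aligned pair refines arm lengths and identity.
    span = cand.span
    if len(tir_loci) >= 2:
        tir_pair = detect_tir_pair(contig_seq, cand.span,
                                   max_flank=config.tir_max_flank,
                                   min_tir_len=config.min_tir_len,
                                   min_tir_identity=config.min_tir_identity)
        if tir_pair is None:
            # two TIR loci from hits but no alignable pair (e.g. both arms
            # heavily rearranged): fall back to the hit evidence
            first, last = tir_loci[0], tir_loci[-1]
            ident = float(np.mean([h.identity for h in tir_hits]))
            tir_pair = TIRPair(tir5_span=first, tir3_span=last,
                               lengths=(first[1] - first[0], last[1] - last[0]),
                               percent_identity=ident, alignment=("", ""))
    elif len(tir_loci) == 1:
        single_tir = tir_loci[0]

    # pin TIR-adjacent termini on the conserved arm ends before TSD search
    tir_left = tir_pair is not None or (
        single_tir is not None and abs(single_tir[0] - span[0]) <= 50)
    tir_right = tir_pair is not None or (
        single_tir is not None and abs(single_tir[1] - span[1]) <= 50)
    expected_left = _expected_terminal(cand, queries)
    pinned_l = pinned_r = False
    if expected_left is not None:
        if tir_left:
            pos, pinned_l = pin_terminus(contig_seq, span[0], expected_left, "left")
            if pinned_l:
                span = (pos, span[1])
        if tir_right:
            pos, pinned_r = pin_terminus(contig_seq, span[1],
                                         revcomp(expected_left), "right")
            if pinned_r:
                span = (span[0], pos)

    span = refine_boundaries_by_tsd(contig_seq, span,
                                    max_shift=config.boundary_max_shift,
                                    max_len=config.tsd_max_len,
                                    min_len=config.tsd_min_len,
                                    shift_left=(0, -1, 1, -2, 2) if pinned_l else None,
                                    shift_right=(0, -1, 1, -2, 2) if pinned_r else None,
                                    preferred_motif=preferred_motif)
    if tir_pair is not None:
        t5 = (span[0], min(max(tir_pair.tir5_span[1], span[0] + 1), span[1]))
        t3 = (max(min(tir_pair.tir3_span[0], span[1] - 1), t5[1]), span[1])
        tir_pair.tir5_span, tir_pair.tir3_span = t5, t3
        tir_pair.lengths = (t5[1] - t5[0], t3[1] - t3[0])
    if single_tir is not None:
        single_tir = (max(single_tir[0], span[0]), min(single_tir[1], span[1]))
        # a retained arm sits at one element terminus; snap it there
        if abs(single_tir[0] - span[0]) <= 30:
            single_tir = (span[0], single_tir[1])
        if abs(single_tir[1] - span[1]) <= 30:
            single_tir = (single_tir[0], span[1])

    tsd, status = call_tsd(contig_seq, span, flank=config.tsd_flank,
                           max_len=config.tsd_max_len, min_len=config.tsd_min_len,
                           max_mismatch=config.tsd_max_mismatch)

    copy = ElementCopy(
        copy_id=copy_id, contig=cand.contig, span=span, strand=cand.strand,
        tir_pair=tir_pair, single_tir_span=single_tir,
        tpase_spans=[(h.start, h.end) for h in cand.member_hits
                     if query_kind(h.query_id) == "tpase"],
        tpase_coverage=_tpase_coverage(cand.member_hits, queries),
        tsd=tsd, tsd_status=status,
    )
    ref_len = max(len(q) for qid, q in queries.items() if query_kind(qid) == "tpase")
    try:
        copy.group = classify_structure(copy, ref_len,
                                        nearly_complete_frac=config.nearly_complete_frac,
                                        min_tpase_frac=config.min_tpase_frac)
    except ValueError:
        return None

    if te_library:
        anns = annotate_nested_tes(contig_seq, span, dict(te_library),
                                   min_identity=config.min_identity,
                                   min_length=config.min_length)
        copy.nested_insertions = [a for a in anns if a.placement == "inside"]
        copy.flanking_insertions = [a for a in anns if a.placement == "flanking"]

    element = contig_seq[span[0]:span[1]]
    copy.at_rich_segments = [(span[0] + a, span[0] + b) for a, b in
                             find_at_rich_segments(element, window=config.at_window,
                                                   at_frac=config.at_frac)]
    arm_spans = []
    if tir_pair is not None:
        arm_spans = [tir_pair.tir5_span, tir_pair.tir3_span]
    elif single_tir is not None:
        arm_spans = [single_tir]
    for a, b in arm_spans:
        arm = contig_seq[a:b]
        for (ts, te), period, ncop in find_tandem_repeats(
                arm, min_period=config.tr_min_period,
                min_copies=config.tr_min_copies, min_identity=config.tr_min_identity):
            copy.tandem_repeat_regions.append(((a + ts, a + te), period, ncop))
    return copy


def annotate_genome(contigs: Mapping[str, str],
                    queries: Mapping[str, str] | None = None,
                    templates: Sequence[ElementTemplate] | None = None,
                    config: PipelineConfig | None = None,
                    te_library: Mapping[str, str] | None = None) -> AnnotationResult:
    """Full scan-and-annotate over a genome."""
    config = config or PipelineConfig()
    if queries is None:
        templates = templates if templates is not None else default_templates()
        queries = build_query_library(templates)
    hits = find_seed_hits(contigs, queries, min_word=config.min_word,
                          min_identity=config.min_identity,
                          min_length=config.min_length)
    candidates = merge_hits(hits, max_gap=config.merge_max_gap, tir_rule="any")

    def run_pass(motif: str | None) -> tuple[list[ElementCopy], list[tuple[str, str]]]:
        copies: list[ElementCopy] = []
        skipped: list[tuple[str, str]] = []
        for i, cand in enumerate(candidates, start=1):
            copy = annotate_candidate(contigs[cand.contig], cand, queries, config,
                                      copy_id=f"copy_{i}", te_library=te_library,
                                      preferred_motif=motif)
            if copy is None:
                skipped.append((f"candidate_{i}", "neither TIR nor TPase content"))
            else:
                copies.append(copy)
        return copies, skipped

    # First pass calls TSDs from per-copy evidence alone; the family-wide TSD
    # consensus then disambiguates single-copy boundary ties in a second pass.
    copies, skipped = run_pass(None)
    consensus = _tsd_consensus(copies)
    if consensus is not None:
        copies, skipped = run_pass(consensus)
    return AnnotationResult(copies=copies, hits=hits, candidates=candidates,
                            skipped=skipped)


def _tsd_consensus(copies: Sequence[ElementCopy], length: int = 7,
                   min_calls: int = 5) -> str | None:
    """Majority-rule consensus of identical TSD calls of the typical length."""
    seqs = [c.tsd.left_seq for c in copies
            if c.tsd is not None and c.tsd.identical and c.tsd.length == length]
    if len(seqs) < min_calls:
        return None
    cons = []
    for j in range(length):
        col = [s[j] for s in seqs]
        cons.append(max(set(col), key=col.count))
    return "".join(cons)


# ---------------------------------------------------------------------------
# TSM stage
# ---------------------------------------------------------------------------

@dataclass
class TSMResult:
    windows: list[TSMWindow]
    skipped: list[tuple[str, str]]
    profile: MotifProfile | None
    palindrome: PalindromeReport | None
    hairpin: HairpinReport | None

    @property
    def consensus_tsd(self) -> str | None:
        if self.profile is None:
            return None
        a = 50 - 7
        return self.profile.consensus[a:a + 7]


def tsm_stage(copies: Sequence[ElementCopy], contigs: Mapping[str, str],
              config: PipelineConfig | None = None) -> TSMResult:
    """Windows -> profile -> palindrome -> stem-loop for identical-TSD copies."""
    config = config or PipelineConfig()
    windows, skipped = build_tsm_windows(copies, contigs)
    if len(windows) < 2:
        return TSMResult(windows, skipped, None, None, None)
    profile = consensus_profile(windows)
    center = (config.tsm_upstream - 7) + 3   # center of the 7-bp TSD core
    pal = detect_palindrome(profile, center,
                            min_complementarity=config.min_complementarity)
    motif_consensus = profile.consensus[pal.span[0]:pal.span[1]]
    hp = hairpin_score(motif_consensus) if len(motif_consensus) >= 9 else None
    return TSMResult(windows, skipped, profile, pal, hp)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

def summarize_copies(copies: Sequence[ElementCopy]) -> dict:
    """Group counts and the aggregate percentages of the copy table.

    Every percentage is a ratio recomputable from the table itself.
    """
    total = len(copies)
    groups = {g: sum(1 for c in copies if c.group == g) for g in "ABCDEF"}
    n_nested = sum(1 for c in copies if c.nested_insertions)
    n_flanking = sum(1 for c in copies if c.flanking_insertions)
    n_both = sum(1 for c in copies if c.nested_insertions and c.flanking_insertions)
    with_tirs = [c for c in copies if c.n_tirs > 0]
    two_tirs = [c for c in copies if c.n_tirs == 2]
    ident_two = sum(1 for c in two_tirs if c.tsd is not None and c.tsd.identical)
    ident_any = sum(1 for c in with_tirs if c.tsd is not None and c.tsd.identical)
    out = {
        "total_copies": total,
        "group_counts": groups,
        "copies_with_nested_te": n_nested,
        "copies_with_flanking_te": n_flanking,
        "copies_with_both": n_both,
        "tsd_lengths": {},
    }
    for c in copies:
        if c.tsd is not None:
            k = str(c.tsd.length)
            out["tsd_lengths"][k] = out["tsd_lengths"].get(k, 0) + 1
    if total:
        out["percent_nested"] = percent(n_nested, total)
        out["percent_flanking"] = percent(n_flanking, total)
        out["percent_both"] = percent(n_both, total)
    # the identical-TSD share is reported under both defensible denominators
    if two_tirs:
        out["percent_identical_tsd_two_tir"] = percent(ident_two, len(two_tirs))
    if with_tirs:
        out["percent_identical_tsd_any_tir"] = percent(ident_any, len(with_tirs))
    return out
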