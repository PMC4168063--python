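"""Per-copy structural annotation.

Resolves terminal inverted repeats by comparing the upstream flank of a
candidate copy against the reverse complement of its downstream flank (up to
5 kb each side), calls target site duplications from the bases immediately
flanking the element, classifies copies into the six structural groups A-F,
and annotates TIR-internal tandem repeats, nested TEs, AT-rich segments,
ORFs and transposase motif residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Data import CodonTable

from ._seq import revcomp, seq_to_u8
from .detect import CandidateCopy, find_seed_hits

# Expected residues of the reference TPase (1-based protein positions):
# the THAP DNA-binding domain's C2CH zinc-coordinating signature plus four
# invariant residues, and the DDE / D(2)H catalytic motif of P-superfamily
# cut-and-paste transposases.
THAP_RESIDUES = {16: "C", 21: "C", 40: "P", 49: "W", 67: "C", 70: "H", 71: "F", 87: "P"}
CATALYTIC_RESIDUES = {327: "D", 415: "D", 449: "D", 452: "H", 642: "E"}

GROUPS = ("A", "B", "C", "D", "E", "F")

_CODON_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _CODON_TABLE[_stop] = "*"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TIRPair:
    tir5_span: tuple[int, int]
    tir3_span: tuple[int, int]
    lengths: tuple[int, int]
    percent_identity: float       # over aligned columns, indel columns omitted
    alignment: tuple[str, str]

    def __post_init__(self) -> None:
        if self.tir5_span[1] > self.tir3_span[0]:
            raise ValueError("5' TIR must precede 3' TIR on the contig")
        if not 0 <= self.percent_identity <= 1:
            raise ValueError("percent identity must lie in [0, 1]")


@dataclass
class TSDCall:
    left_seq: str
    right_seq: str
    length: int
    mismatches: int

    @property
    def identical(self) -> bool:
        return self.mismatches == 0


@dataclass
class NestedAnnotation:
    span: tuple[int, int]
    te_label: str
    identity: float
    placement: str                # "inside" or "flanking"


@dataclass
class ORFHit:
    span: tuple[int, int]         # 0-based half-open on the forward strand
    strand: str
    protein: str
    start_codon: str

    @property
    def canonical_start(self) -> bool:
        return self.start_codon == "ATG"


@dataclass
class TPaseMotifReport:
    thap_residues: dict[int, tuple[str, str | None]]
    catalytic_residues: dict[int, tuple[str, str | None]]
    start_codon: str | None = None

    @property
    def all_conserved(self) -> bool:
        pairs = list(self.thap_residues.values()) + list(self.catalytic_residues.values())
        return all(obs == exp for exp, obs in pairs)

    @property
    def mismatches(self) -> list[int]:
        out = []
        for d in (self.thap_residues, self.catalytic_residues):
            out += [pos for pos, (exp, obs) in d.items() if obs != exp]
        return sorted(out)


@dataclass
class ElementCopy:
    """One annotated candidate copy."""

    copy_id: str
    contig: str
    span: tuple[int, int]
    strand: str
    tir_pair: TIRPair | None = None
    single_tir_span: tuple[int, int] | None = None
    tpase_spans: list[tuple[int, int]] = field(default_factory=list)
    tpase_coverage: float = 0.0   # covered fraction of the reference TPase segment
    group: str | None = None
    tsd: TSDCall | None = None
    tsd_status: str = "uncalled"
    nested_insertions: list[NestedAnnotation] = field(default_factory=list)
    flanking_insertions: list[NestedAnnotation] = field(default_factory=list)
    at_rich_segments: list[tuple[int, int]] = field(default_factory=list)
    tandem_repeat_regions: list[tuple[tuple[int, int], int, float]] = field(default_factory=list)

    @property
    def n_tirs(self) -> int:
        if self.tir_pair is not None:
            return 2
        return 1 if self.single_tir_span is not None else 0


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------

def _make_aligner(match: int = 1, mismatch: int = -1,
                  gap_open: int = -4, gap_extend: int = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _aligned_strings(alignment) -> tuple[str, str]:
    rows = str(alignment).splitlines()
    # Bio.Align pretty format: target / pipes / query, repeated in blocks
    a_parts, b_parts = [], []
    for i in range(0, len(rows), 4):
        block = rows[i:i + 3]
        if len(block) == 3:
            a_parts.append(block[0].split()[-1] if block[0].split() else "")
            b_parts.append(block[2].split()[-1] if block[2].split() else "")
    return "".join(a_parts), "".join(b_parts)


def _identity_omitting_indels(alignment) -> float:
    c = alignment.counts()
    aligned_cols = c.identities + c.mismatches
    return c.identities / aligned_cols if aligned_cols else 0.0


def _best_local(aligner: Align.PairwiseAligner, a: str, b: str):
    alns = aligner.align(a, b)
    try:
        return alns[0]
    except IndexError:
        return None


# ---------------------------------------------------------------------------
# TIR pair detection
# ---------------------------------------------------------------------------

def detect_tir_pair(contig_sequence: str, candidate: CandidateCopy | tuple[int, int],
                    max_flank: int = 5000, min_tir_len: int = 30,
                    min_tir_identity: float = 0.80,
                    dp_limit: int = 4_000_000) -> TIRPair | None:
    """Find the terminal inverted repeats of a candidate copy.

    The window upstream of the candidate midpoint is locally aligned against
    the reverse complement of the downstream window (each window extends
    ``max_flank`` beyond the candidate span, clipped at contig ends).  The
    best-scoring local inverted match defines the arms; accepted when its
    length reaches ``min_tir_len`` at ``min_tir_identity`` (identity computed
    omitting indel columns).  Above ``dp_limit`` matrix cells, a word-seeded
    pre-localisation narrows both windows before the exact local alignment.
    """
    span = candidate.span if isinstance(candidate, CandidateCopy) else candidate
    s, e = span
    n = len(contig_sequence)
    if e > n or s < 0 or s >= e:
        raise ValueError("candidate span outside contig")
    mid = (s + e) // 2
    ls = max(0, s - max_flank)
    re_ = min(n, e + max_flank)
    left = contig_sequence[ls:mid]
    right_rc = revcomp(contig_sequence[mid:re_])
    if len(left) < min_tir_len or len(right_rc) < min_tir_len:
        return None

    aligner = _make_aligner()
    crop_l = crop_r = (0, 0)
    if len(left) * len(right_rc) <= dp_limit:
        sub_l, sub_r = left, right_rc
        off_l = off_r = 0
    else:
        loc = _seed_localise(left, right_rc)
        if loc is None:
            return None
        (l0, l1), (r0, r1) = loc
        off_l = max(0, l0 - 150)
        off_r = max(0, r0 - 150)
        sub_l = left[off_l:min(len(left), l1 + 150)]
        sub_r = right_rc[off_r:min(len(right_rc), r1 + 150)]

    aln = _best_local(aligner, sub_l, sub_r)
    if aln is None or aln.score <= 0:
        return None
    blocks_a, blocks_b = aln.aligned
    a0, a1 = int(blocks_a[0][0]) + off_l, int(blocks_a[-1][1]) + off_l
    b0, b1 = int(blocks_b[0][0]) + off_r, int(blocks_b[-1][1]) + off_r
    identity = _identity_omitting_indels(aln)
    len5, len3 = a1 - a0, b1 - b0
    if min(len5, len3) < min_tir_len or identity < min_tir_identity:
        return None

    tir5 = (ls + a0, ls + a1)
    tir3 = (re_ - b1, re_ - b0)
    if tir5[1] > tir3[0]:
        return None  # arms overlap: not a terminal inverted pair
    arm_a, arm_b = _aligned_strings(aln)
    return TIRPair(tir5_span=tir5, tir3_span=tir3, lengths=(len5, len3),
                   percent_identity=identity, alignment=(arm_a, arm_b))


def _seed_localise(a: str, b: str, k: int = 12) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Approximate location of the strongest shared region via word seeds."""
    index: dict[str, list[int]] = {}
    for i in range(len(b) - k + 1):
        w = b[i:i + k]
        if "N" not in w:
            index.setdefault(w, []).append(i)
    seeds = []
    for i in range(len(a) - k + 1):
        for j in index.get(a[i:i + k], ()):
            seeds.append((i, j))
    if not seeds:
        return None
    # greedy diagonal chaining; keep the chain with the most seeds
    seeds.sort()
    chains: list[list[tuple[int, int]]] = []
    for i, j in seeds:
        for chain in chains:
            li, lj = chain[-1]
            if 0 <= i - li <= 400 and abs((i - j) - (li - lj)) <= 60:
                chain.append((i, j))
                break
        else:
            chains.append([(i, j)])
    best = max(chains, key=len)
    i0 = min(i for i, _ in best)
    i1 = max(i for i, _ in best) + k
    j0 = min(j for _, j in best)
    j1 = max(j for _, j in best) + k
    return (i0, i1), (j0, j1)


def detect_single_tir(contig_sequence: str, span: tuple[int, int], reference_tir: str,
                      max_flank: int = 200, min_tir_len: int = 30,
                      min_tir_identity: float = 0.80) -> tuple[int, int] | None:
    """Locate one terminal TIR by aligning a reference TIR near the span edges.

    Used when flank-vs-flank comparison finds no inverted pair: a copy may
    still retain a single arm (groups C and E).
    """
    s, e = span
    n = len(contig_sequence)
    window = contig_sequence[max(0, s - max_flank):min(n, e + max_flank)]
    base = max(0, s - max_flank)
    aligner = _make_aligner()
    best = None
    for ref in (reference_tir, revcomp(reference_tir)):
        aln = _best_local(aligner, window, ref)
        if aln is None or aln.score <= 0:
            continue
        blocks_a, _ = aln.aligned
        a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
        identity = _identity_omitting_indels(aln)
        if a1 - a0 >= min_tir_len and identity >= min_tir_identity:
            if best is None or aln.score > best[0]:
                best = (aln.score, (base + a0, base + a1))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# TSD calling
# ---------------------------------------------------------------------------

def call_tsd(contig_sequence: str, span: tuple[int, int], flank: int = 50,
             max_len: int = 8, min_len: int = 5,
             max_mismatch: int = 1) -> tuple[TSDCall | None, str]:
    """Compare the k bases left of the element start against the k bases right
    of the element end, k from ``max_len`` down to ``min_len``.

    Preference order: longest exact duplication first, then longest
    within-``max_mismatch`` duplication.  Returns (call, status); status is
    "edge" when the element sits closer than ``max_len`` to a contig end,
    "no_match" when no acceptable duplication exists.
    """
    s, e = span
    n = len(contig_sequence)
    if s < max_len or e + max_len > n:
        return None, "edge"
    for mism_cap in (0, max_mismatch):
        if mism_cap == max_mismatch == 0:
            break
        for k in range(max_len, min_len - 1, -1):
            left = contig_sequence[s - k:s]
            right = contig_sequence[e:e + k]
            mism = sum(a != b for a, b in zip(left, right))
            if mism <= mism_cap:
                return TSDCall(left, right, k, mism), "ok"
    return None, "no_match"


def pin_terminus(contig_sequence: str, pos: int, expected: str, side: str,
                 max_offset: int = 25, min_match_frac: float = 0.7) -> tuple[int, bool]:
    """Pin an element boundary to the expected terminal sequence of the TIR.

    Element termini are the best-conserved part of the element, so the
    reference arm's outermost bases locate the boundary more precisely than
    an alignment endpoint.  ``expected`` reads left-to-right starting at the
    boundary for ``side='left'``, or ending at it for ``side='right'``.
    Returns (adjusted position, pinned flag); the position is unchanged and
    the flag False when nothing matches acceptably.
    """
    n = len(contig_sequence)
    k = len(expected)
    best: tuple[int, int] | None = None    # (matches, -|offset|)
    best_pos = pos
    for off in sorted(range(-max_offset, max_offset + 1), key=abs):
        p = pos + off
        if side == "left":
            window = contig_sequence[p:p + k] if p >= 0 else ""
        else:
            window = contig_sequence[p - k:p] if p - k >= 0 else ""
        if len(window) < k or p > n:
            continue
        m = sum(a == b for a, b in zip(window, expected))
        if best is None or (m, -abs(off)) > best:
            best = (m, -abs(off))
            best_pos = p
    if best is None or best[0] < min_match_frac * k:
        return pos, False
    return best_pos, True


def refine_boundaries_by_tsd(contig_sequence: str, span: tuple[int, int],
                             max_shift: int = 8, max_len: int = 8,
                             min_len: int = 5, typical_len: int = 7,
                             wide_shift: int = 25,
                             shift_left: tuple[int, ...] | None = None,
                             shift_right: tuple[int, ...] | None = None,
                             preferred_motif: str | None = None,
                             ) -> tuple[int, int]:
    """Nudge element boundaries onto the longest exact terminal duplication.

    Joint TIR+TSD evidence: a substitution in the outermost TIR base makes a
    local alignment stop one base short, which silently shifts the element
    boundary; the intact flanking duplication pins it back.  Both boundaries
    are searched over +-``max_shift`` (restricted by ``shift_left`` /
    ``shift_right`` for termini already pinned on TIR terminal evidence);
    additionally one side at a time is searched out to +-``wide_shift`` for
    duplications of >= ``typical_len`` bp, to rescue badly truncated ends.

    Candidates are scored by duplication length minus total shift.  Within
    the tied top set, preference goes to the family-typical duplication
    length: an off-by-one boundary always presents the nested (k-1)-mer at
    zero shift, and a chance agreement between the element's terminal base
    and the flank presents a (k+1)-mer at one shift — both ties are broken
    correctly by expecting the typical length (and a genuinely longer
    duplication at the anchored boundary still outscores the tie set).
    Boundaries are left untouched when nothing of >= ``min_len`` bp is found.

    ``preferred_motif`` (the genome-wide TSD consensus from a first
    annotation pass) widens the tie set by two score points and prefers the
    candidate whose duplication most resembles the family consensus — the
    family-level evidence that resolves single-copy boundary ambiguities.
    """
    s, e = span
    n = len(contig_sequence)
    small = tuple(sorted(range(-max_shift, max_shift + 1), key=abs))
    left_small = small if shift_left is None else tuple(shift_left)
    right_small = small if shift_right is None else tuple(shift_right)
    wide = tuple(d for d in sorted(range(-wide_shift, wide_shift + 1), key=abs)
                 if abs(d) > max_shift)

    pairs: list[tuple[int, int, int]] = []          # (dl, dr, min_k allowed)
    pairs += [(dl, dr, min_len) for dl in left_small for dr in right_small]
    if shift_left is None:
        pairs += [(dl, dr, typical_len) for dl in wide for dr in right_small]
    if shift_right is None:
        pairs += [(dl, dr, typical_len) for dr in wide for dl in left_small]

    cands: list[tuple[int, int, int, int]] = []     # (k, shift, dl, dr)
    for dl, dr, kmin in pairs:
        ss, ee = s + dl, e + dr
        if ss < max_len or ee + max_len > n or ss >= ee:
            continue
        for k in range(max_len, kmin - 1, -1):
            if contig_sequence[ss - k:ss] == contig_sequence[ee:ee + k]:
                cands.append((k, abs(dl) + abs(dr), dl, dr))
                break
    if not cands:
        return span
    top = max(k - sh for k, sh, _, _ in cands)
    slack = 2 if preferred_motif else 0
    tied = [c for c in cands if c[0] - c[1] >= top - slack]

    def motif_distance(c: tuple[int, int, int, int]) -> int:
        if preferred_motif is None:
            return 0
        k, _, dl, _ = c
        dup = contig_sequence[s + dl - k:s + dl]
        m = len(preferred_motif)
        if k >= m:
            return min(sum(a != b for a, b in zip(dup[i:i + m], preferred_motif))
                       for i in range(k - m + 1))
        return (m - k) + min(sum(a != b for a, b in zip(dup, preferred_motif[i:i + k]))
                             for i in range(m - k + 1))

    # rank by motif resemblance; within the best class keep only candidates
    # not dominated (longer or equal duplication at no larger shift) by
    # another — a genuine longer duplication at the anchored boundary then
    # stands alone, while the remaining incomparable pairs (k at one shift
    # vs k+-1 at the other) resolve to the family-typical length
    best_d = min(motif_distance(c) for c in tied)
    tied = [c for c in tied if motif_distance(c) == best_d]
    front = [c for c in tied
             if not any(o[0] >= c[0] and o[1] <= c[1] and (o[0], -o[1]) > (c[0], -c[1])
                        for o in tied)]
    front.sort(key=lambda c: (c[0] != typical_len, c[1], -c[0]))
    _, _, dl, dr = front[0]
    return s + dl, e + dr


# ---------------------------------------------------------------------------
# structural classification
# ---------------------------------------------------------------------------

def classify_structure(copy: ElementCopy, reference_orf_len: int,
                       nearly_complete_frac: float = 0.95,
                       min_tpase_frac: float = 0.05) -> str:
    """Six-group classification from TIR count and TPase coverage.

    A: two TIRs, TPase coverage >= ``nearly_complete_frac``; B: two TIRs,
    partial TPase; C: one TIR with TPase; D: two TIRs, no TPase; E: one TIR
    only; F: TPase only.  Coverage below ``min_tpase_frac`` counts as absent
    (the reference ORF tail lies inside the 3' TIR, so a trace of apparent
    coverage is expected even in TIR-only copies).
    """
    coverage = copy.tpase_coverage
    if not coverage and copy.tpase_spans and reference_orf_len:
        coverage = min(1.0, sum(b - a for a, b in copy.tpase_spans) / reference_orf_len)
    has_tpase = coverage >= min_tpase_frac
    n_tirs = copy.n_tirs
    if n_tirs == 2:
        if has_tpase:
            return "A" if coverage >= nearly_complete_frac else "B"
        return "D"
    if n_tirs == 1:
        return "C" if has_tpase else "E"
    if has_tpase:
        return "F"
    raise ValueError(f"{copy.copy_id}: neither TIR nor TPase content; not an element copy")


# ---------------------------------------------------------------------------
# tandem repeats, nested TEs, AT-rich segments
# ---------------------------------------------------------------------------

def find_tandem_repeats(sequence: str, min_period: int = 20, min_copies: float = 1.8,
                        min_identity: float = 0.8,
                        max_period: int = 250) -> list[tuple[tuple[int, int], int, float]]:
    """Self-alignment periodicity scan.

    For each lag p, positions where the one-period windowed identity between
    the sequence and itself shifted by p reaches ``min_identity`` are grouped
    into maximal runs; a run spanning >= ``min_copies`` periods is reported as
    ((start, end), period, copy_number).  Smaller periods claim regions first,
    so harmonics of an accepted period are suppressed.
    """
    n = len(sequence)
    if n < 2 * min_period:
        return []
    arr = seq_to_u8(sequence)
    covered = np.zeros(n, dtype=bool)
    out: list[tuple[tuple[int, int], int, float]] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.int32)
        if eq.size < p:
            break
        cs = np.concatenate([[0], np.cumsum(eq)])
        m = (cs[p:] - cs[:-p]) / p          # identity of [i, i+p) vs [i+p, i+2p)
        ok = m >= min_identity
        i = 0
        while i < ok.size:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            span = (i, j + 2 * p)
            copies = (span[1] - span[0]) / p
            if copies >= min_copies:
                overlap = covered[span[0]:span[1]].sum()
                if overlap < 0.5 * (span[1] - span[0]):
                    out.append((span, p, round(copies, 1)))
                    covered[span[0]:span[1]] = True
            i = j + 1
    out.sort(key=lambda r: r[0])
    return out


def annotate_nested_tes(contig_sequence: str, element_span: tuple[int, int],
                        te_library: dict[str, str], min_identity: float = 0.80,
                        min_length: int = 50, flank: int = 200) -> list[NestedAnnotation]:
    """Similarity search of a TE library over the copy region and its flanks.

    Hits falling within the element span (TIR outer edges) are "inside";
    hits beyond the boundaries are "flanking".
    """
    if not te_library:
        raise ValueError("TE library is empty")
    s, e = element_span
    n = len(contig_sequence)
    ws, we = max(0, s - flank), min(n, e + flank)
    region = contig_sequence[ws:we]
    hits = find_seed_hits({"region": region}, te_library,
                          min_identity=min_identity, min_length=min_length)
    out = []
    for h in hits:
        gs, ge = ws + h.start, ws + h.end
        mid = (gs + ge) // 2
        placement = "inside" if s <= mid < e else "flanking"
        out.append(NestedAnnotation(span=(gs, ge), te_label=h.query_id,
                                    identity=h.identity, placement=placement))
    return out


def find_at_rich_segments(sequence: str, window: int = 100,
                          at_frac: float = 0.8) -> list[tuple[int, int]]:
    """Maximal merged runs of sliding windows with AT fraction >= ``at_frac``,
    trimmed so both ends land on an A/T base."""
    n = len(sequence)
    if window > n:
        return []
    is_at = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_at = (is_at == ord("A")) | (is_at == ord("T"))
    cs = np.concatenate([[0], np.cumsum(is_at)])
    frac = (cs[window:] - cs[:-window]) / window
    ok = frac >= at_frac
    spans: list[tuple[int, int]] = []
    i = 0
    while i < ok.size:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < ok.size and ok[j + 1]:
            j += 1
        a, b = i, j + window
        while a < b and not is_at[a]:
            a += 1
        while b > a and not is_at[b - 1]:
            b -= 1
        if b > a:
            spans.append((a, b))
        i = j + 1
    return spans


# ---------------------------------------------------------------------------
# ORFs and TPase motifs
# ---------------------------------------------------------------------------

def _translate(seq: str) -> str:
    aa = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def find_longest_orf(sequence: str, allow_noncanonical_start: bool = True,
                     min_codons: int = 50) -> ORFHit | None:
    """Longest stop-to-stop frame segment over all six frames.

    With ``allow_noncanonical_start`` the reported start is the segment's
    first codon (the reference element opens with ACG rather than ATG);
    otherwise the first ATG within the segment.  Codons containing N
    translate to X and never terminate a segment.
    """
    best: ORFHit | None = None
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            prot = _translate(seq[frame:])
            start = 0
            for part in prot.split("*"):
                if len(part) >= min_codons:
                    a = start
                    if not allow_noncanonical_start:
                        rel = _first_atg(seq, frame, a, len(part))
                        if rel is None:
                            start += len(part) + 1
                            continue
                        a = rel
                        part = part[a - start:]
                    if len(part) >= min_codons and (best is None or len(part) > len(best.protein)):
                        lo = frame + 3 * a
                        hi = frame + 3 * (a + len(part))
                        span = (lo, hi) if strand == "+" else (n - hi, n - lo)
                        best = ORFHit(span=span, strand=strand, protein=part,
                                      start_codon=seq[lo:lo + 3])
                start += len(part) + 1
    return best


def _first_atg(seq: str, frame: int, codon_start: int, n_codons: int) -> int | None:
    for c in range(codon_start, codon_start + n_codons):
        if seq[frame + 3 * c:frame + 3 * c + 3] == "ATG":
            return c
    return None


def check_tpase_motifs(protein: str) -> TPaseMotifReport:
    """Report expected vs observed residues at the THAP and catalytic
    positions; positions beyond the protein's length are flagged missing."""
    def observe(d: dict[int, str]) -> dict[int, tuple[str, str | None]]:
        return {pos: (exp, protein[pos - 1] if pos <= len(protein) else None)
                for pos, exp in d.items()}
    return TPaseMotifReport(thap_residues=observe(THAP_RESIDUES),
                            catalytic_residues=observe(CATALYTIC_RESIDUES),
                            start_codon=None)
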