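"""Synthetic genomes with planted, ground-truthed TIR-transposon copies.

The generator emulates the situation the annotation pipeline is built for: a
Galileo-like cut-and-paste DNA transposon of the P superfamily, ~4.4 kb long,
with ~760-bp terminal inverted repeats (TIRs), an internal transposase (TPase)
ORF whose tail overlaps the 3' TIR by 69 bp, 7-bp (rarely 8-bp) target site
duplications (TSDs) drawn from a palindromic AT-rich 15-bp target site motif
with core consensus GTATTAC, two subfamilies (V and W) diverged in both the
TPase and TIR segments, and copy degradation producing six structural groups:

    A  nearly complete (two TIRs + essentially full TPase segment)
    B  two TIRs + a partial TPase segment
    C  one TIR + a partial TPase segment
    D  two TIRs only (non-TPase spacer between them)
    E  one TIR only
    F  a TPase fragment without TIRs

Every planted copy is emitted in a ground-truth table so detection, boundary
resolution, TSD calling, classification, motif inference and subfamily
clustering can all be scored against what was actually planted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    BASES,
    mutate_indels,
    mutate_substitutions,
    random_dna,
    revcomp,
    substitute_exact,
)

from .annotate import CATALYTIC_RESIDUES, THAP_RESIDUES

GROUPS = ("A", "B", "C", "D", "E", "F")

# One-or-more codons per amino acid (stop codons never used inside the ORF).
_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "TTA", "CTA"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "AGA"],
    "S": ["TCT", "TCA"], "T": ["ACT", "ACC", "ACG"], "V": ["GTT", "GTC"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_AA = sorted(_CODONS)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ElementTemplate:
    """A full-length element used as the source of planted copies.

    ``tir5_span`` starts at template position 0 and ``tir3_span`` ends at the
    last position; the reverse complement of the 3' TIR aligns to the 5' TIR
    at >=95% identity in undegraded templates.  ``tir_map`` maps each 5'-TIR
    position to its aligned 3'-TIR position (-1 for bases present only in the
    5' arm), so subfamily divergence can be applied in a mirrored way that
    preserves the within-element inverted-repeat relationship.
    """

    id: str
    sequence: str
    tir5_span: tuple[int, int]
    tir3_span: tuple[int, int]
    orf_span: tuple[int, int]
    subfamily: str = "W"
    tir_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tir5_span[0] != 0:
            raise ValueError("tir5_span must start at template position 0")
        if self.tir3_span[1] != len(self.sequence):
            raise ValueError("tir3_span must end at the template's last position")
        if (self.orf_span[1] - self.orf_span[0]) % 3 != 0:
            raise ValueError("orf_span length must be a multiple of 3")

    @property
    def tir5(self) -> str:
        return self.sequence[self.tir5_span[0]:self.tir5_span[1]]

    @property
    def tir3(self) -> str:
        return self.sequence[self.tir3_span[0]:self.tir3_span[1]]

    @property
    def orf(self) -> str:
        return self.sequence[self.orf_span[0]:self.orf_span[1]]


@dataclass
class InsertionModel:
    """Per-position model of the 15-bp palindromic target site.

    ``profile`` is a (15, 4) row-stochastic matrix over A,C,G,T.  The modal
    sequence of the central 7 positions is the TSD core consensus (GTATTAC by
    default).  Degenerate (consensus-N) shoulder positions are sampled with
    mirrored Watson-Crick complements at probability
    ``palindrome_correlation`` — a bound protein sees both strands, so real
    target sites are palindromic jointly, not just marginally.  Marginals are
    AT-symmetric, so the per-position frequency profile is preserved.
    ``at_rich_flank_prob`` shapes an AT-rich halo written around the site.
    """

    profile: np.ndarray
    consensus: str = "NAANGTATTACNTTN"
    tsd_length_weights: dict[int, float] = field(default_factory=lambda: {7: 0.975, 8: 0.025})
    at_rich_flank_prob: float = 0.6
    halo: int = 14
    palindrome_correlation: float = 0.9

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (len(self.consensus), 4):
            raise ValueError("profile must be (len(consensus), 4)")
        if not np.allclose(self.profile.sum(axis=1), 1.0):
            raise ValueError("profile rows must sum to 1")
        core = self.modal_sequence()[4:11]
        want = "".join(c for c in self.consensus[4:11])
        if want != core:
            raise ValueError(f"modal central 7-mer {core} != configured consensus {want}")

    def modal_sequence(self) -> str:
        return "".join(BASES[i] for i in self.profile.argmax(axis=1))


def default_insertion_model(core_weight: float = 0.85, n_at: float = 0.40,
                            tsd8_weight: float = 0.025) -> InsertionModel:
    """Profile for the 15-bp site N AAN GTATTAC NTT N (consensus letters get
    ``core_weight``; N positions are AT-rich and symmetric)."""
    consensus = "NAANGTATTACNTTN"
    prof = np.zeros((15, 4))
    for i, c in enumerate(consensus):
        if c == "N":
            prof[i] = [n_at, (1 - 2 * n_at) / 2, (1 - 2 * n_at) / 2, n_at]
        else:
            prof[i] = (1 - core_weight) / 3
            prof[i, BASES.index(c)] = core_weight
    return InsertionModel(profile=prof, consensus=consensus,
                          tsd_length_weights={7: 1 - tsd8_weight, 8: tsd8_weight})


@dataclass
class DegradationSpec:
    """How planted copies decay relative to the template."""

    substitution_rate: float = 0.03
    indel_rate: float = 0.0005
    group_weights: dict[str, float] = field(
        default_factory=lambda: {g: 1 / 6 for g in GROUPS})
    nested_te_prob: float = 0.15
    flanking_te_prob: float = 0.05
    tir_tandem_expansion_prob: float = 0.05
    # fraction of the TPase segment retained by partial copies
    b_keep_range: tuple[float, float] = (0.20, 0.85)
    c_keep_range: tuple[float, float] = (0.20, 0.80)
    f_len_range: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        for p in (self.substitution_rate, self.indel_rate, self.nested_te_prob,
                  self.flanking_te_prob, self.tir_tandem_expansion_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        tot = sum(self.group_weights.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("group_weights must sum to 1")


@dataclass
class GroundTruthRecord:
    copy_id: str
    contig: str
    start: int            # element span, 0-based half-open, TSDs excluded
    end: int
    strand: str
    tsd_sequence: str
    group: str
    subfamily: str
    tir_lengths: tuple[int, int]          # (5' arm, 3' arm); 0 when absent
    nested_insertion_spans: list[tuple[int, int, str]] = field(default_factory=list)
    flanking_insertion_spans: list[tuple[int, int, str]] = field(default_factory=list)


@dataclass
class SyntheticGenomeSpec:
    n_copies: int
    seed: int
    n_contigs: int = 1
    contig_lengths: tuple[int, ...] = (2_000_000,)
    background_gc: float = 0.40
    templates: list[ElementTemplate] | None = None
    insertion_model: InsertionModel | None = None
    degradation: DegradationSpec | None = None
    group_counts: dict[str, int] | None = None
    min_spacing: int = 6000
    decoy_library: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.contig_lengths) != self.n_contigs:
            raise ValueError("contig_lengths must have n_contigs entries")
        if self.group_counts is not None and sum(self.group_counts.values()) != self.n_copies:
            raise ValueError("group_counts must sum to n_copies")


# ---------------------------------------------------------------------------
# reference template construction
# ---------------------------------------------------------------------------

def _at_rich(rng: np.random.Generator, length: int, at: float = 0.92) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return [_AA[i] for i in rng.integers(0, len(_AA), size=length)]


def default_element_template(seed: int = 7, template_id: str = "galileo_ref") -> ElementTemplate:
    """Build the 4386-bp reference element.

    Layout (0-based): 5' TIR [0, 765); spacer [765, 983); TPase ORF
    [983, 3698) encoding a 905-aa protein starting with a non-canonical ACG
    codon and carrying the THAP + DDE/D(2)H residues at their expected
    positions; 3' TIR [3629, 4386), overlapping the ORF tail by 69 bp; an
    AT-rich ~137-bp segment sits inside each TIR.  The 5' TIR is the reverse
    complement of the 3' TIR with 7 substitutions and 8 single-base
    insertions (99% identity omitting indels; 765 vs 757 bp).
    """
    rng = np.random.default_rng(seed)

    aa = _random_protein(rng, 905)
    aa[0] = "T"  # ACG start, Thr
    for pos, res in {**THAP_RESIDUES, **CATALYTIC_RESIDUES}.items():
        aa[pos - 1] = res
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa]
    codons[0] = "ACG"
    orf = "".join(codons)
    assert len(orf) == 2715

    spacer = random_dna(rng, 215, gc=0.45) + "TAA"          # in-frame stop at [980, 983)
    tail = "TAA" + random_dna(rng, 30, gc=0.45) + _at_rich(rng, 137) \
        + random_dna(rng, 688 - 170, gc=0.45)               # [3698, 4386)
    internal = spacer + orf + tail                          # [765, 4386)
    assert len(internal) == 3621

    tir3 = internal[3629 - 765:]                            # [3629, 4386), 757 bp
    rc = revcomp(tir3)
    rc, _ = substitute_exact(rc, 7, rng)                    # ~1% divergence between arms
    ins_pos = np.sort(rng.choice(np.arange(20, 737), size=8, replace=False))
    tir5_chars: list[str] = []
    tir_map: list[int] = []
    k = 0
    for i, base in enumerate(rc):
        while k < 8 and ins_pos[k] == i:
            tir5_chars.append(BASES[rng.integers(4)])
            tir_map.append(-1)
            k += 1
        tir5_chars.append(base)
        tir_map.append(756 - i)  # rc index i aligns to tir3 local index 756-i
    tir5 = "".join(tir5_chars)
    assert len(tir5) == 765

    seq = tir5 + internal
    return ElementTemplate(
        id=template_id, sequence=seq,
        tir5_span=(0, 765), tir3_span=(3629, 4386), orf_span=(983, 3698),
        subfamily="W", tir_map=np.asarray(tir_map),
    )


def segment_p_distance(a: str, b: str) -> float:
    """Direct mismatch fraction over equal-length ungapped strings."""
    if len(a) != len(b):
        raise ValueError("segments must have equal length")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def build_subfamily_templates(base_template: ElementTemplate,
                              tpase_divergence: float,
                              tir_divergence: float,
                              seed: int) -> tuple[ElementTemplate, ElementTemplate]:
    """Derive the V and W subfamily templates from a common ancestor proxy.

    W is the base template; V carries exactly round(d*L) substitutions over
    the TPase span and over the 3' TIR, so the realized p-distance lands on
    target.  TIR substitutions (including those of the ORF tail that lies
    inside the 3' TIR) are mirrored as complements into the aligned 5'-TIR
    positions, preserving each template's internal inverted-repeat identity.
    Substitutions only, so all spans are preserved.
    """
    for d in (tpase_divergence, tir_divergence):
        if not 0 <= d < 0.75:
            raise ValueError("divergence fractions must lie in [0, 0.75) "
                             "(p-distance saturates beyond)")
    rng = np.random.default_rng(seed)
    seq = list(base_template.sequence)
    os_, oe = base_template.orf_span
    t3s, t3e = base_template.tir3_span
    t5s, t5e = base_template.tir5_span

    def _sub_at(pos: int) -> None:
        old = seq[pos]
        choices = [b for b in BASES if b != old]
        seq[pos] = choices[rng.integers(3)]

    # TPase span
    n_tp = int(round(tpase_divergence * (oe - os_)))
    tp_pos = rng.choice(np.arange(os_, oe), size=n_tp, replace=False) if n_tp else np.array([], int)
    for p in tp_pos:
        _sub_at(int(p))

    # 3' TIR: top up to the target count, accounting for overlap with the ORF
    n_t3_target = int(round(tir_divergence * (t3e - t3s)))
    k_overlap = int(np.sum((tp_pos >= t3s) & (tp_pos < t3e)))
    n_extra = max(0, n_t3_target - k_overlap)
    pool = np.arange(max(t3s, oe), t3e)
    t3_extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else np.array([], int)
    for p in t3_extra:
        _sub_at(int(p))

    # mirror every 3'-TIR substitution into the aligned 5'-TIR position
    if base_template.tir_map is not None:
        inv = {int(local3): i for i, local3 in enumerate(base_template.tir_map) if local3 >= 0}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mutated3 = [int(p) for p in np.concatenate([tp_pos, t3_extra]) if t3s <= p < t3e]
        for p in mutated3:
            i5 = inv.get(p - t3s)
            if i5 is not None:
                seq[t5s + i5] = comp[seq[p]]

    # spacer between 5' TIR and ORF drifts at the TIR rate
    n_sp = int(round(tir_divergence * (os_ - t5e)))
    if n_sp:
        for p in rng.choice(np.arange(t5e, os_), size=n_sp, replace=False):
            _sub_at(int(p))

    v = dataclasses.replace(base_template, id=base_template.id + "_V",
                            sequence="".join(seq), subfamily="V")
    w = dataclasses.replace(base_template, id=base_template.id + "_W", subfamily="W")
    return v, w


def simulate_subfamily_alignment(length: int = 433, n_v: int = 13, n_w: int = 13,
                                 within_v: float = 0.047, within_w: float = 0.067,
                                 between: float = 0.24,
                                 seed: int = 0) -> tuple[list[str], list[str], dict[str, str]]:
    """Gap-free aligned copies from two subfamilies with calibrated divergence.

    A star phylogeny per subfamily: each copy carries exactly round(t*L)
    substitutions from its subfamily consensus, t = within/2, so the expected
    within-group mean p-distance is ~``within``; the two consensuses are
    separated so the expected between-group mean is ~``between``.  Returns
    (labels, sequences, true assignment).
    """
    tv, tw = within_v / 2, within_w / 2
    d0 = between - tv - tw
    if d0 < 0:
        raise ValueError("between must exceed the average within divergence")
    rng = np.random.default_rng(seed)
    cons_w = random_dna(rng, length, gc=0.45)
    cons_v, _ = substitute_exact(cons_w, int(round(d0 * length)), rng)
    labels: list[str] = []
    seqs: list[str] = []
    truth: dict[str, str] = {}
    for grp, cons, t, n in (("V", cons_v, tv, n_v), ("W", cons_w, tw, n_w)):
        for i in range(n):
            lab = f"{grp.lower()}{i:02d}"
            s, _ = substitute_exact(cons, int(round(t * length)), rng)
            labels.append(lab)
            seqs.append(s)
            truth[lab] = grp
    return labels, seqs, truth


def default_decoy_library(seed: int = 11) -> dict[str, str]:
    """Small library of unrelated TEs used for nested/flanking insertions."""
    rng = np.random.default_rng(seed)
    return {
        "decoy_Pelement": random_dna(rng, 350, gc=0.42),
        "decoy_Mar": random_dna(rng, 450, gc=0.42),
        "decoy_1360": random_dna(rng, 600, gc=0.42),
    }


# ---------------------------------------------------------------------------
# insertion-site sampling
# ---------------------------------------------------------------------------

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def sample_site_sequence(model: InsertionModel, rng: np.random.Generator) -> str:
    """Draw one 15-bp target site; degenerate shoulder pairs are mirrored."""
    site = [BASES[rng.choice(4, p=model.profile[i])] for i in range(len(model.consensus))]
    n = len(site)
    for i in range(n // 2):
        j = n - 1 - i
        if model.consensus[i] == "N" and model.consensus[j] == "N":
            if rng.random() < model.palindrome_correlation:
                site[j] = _COMP1[site[i]]
    return "".join(site)


def sample_insertion_site(contig_sequence: str, insertion_model: InsertionModel,
                          rng: np.random.Generator,
                          position: int | None = None) -> tuple[str, int, str]:
    """Write a sampled 15-bp target site (plus AT-rich halo) into the contig.

    Returns (modified contig, site start, TSD string).  The TSD is the
    central 7 bp of the site, or 8 bp (core plus one base to its right) with
    probability ``tsd_length_weights[8]``.  Sites sit >=100 bp from contig
    ends.
    """
    n = len(contig_sequence)
    m = len(insertion_model.consensus)
    if n <= 200 + m:
        raise ValueError("contig too short for insertion-site sampling")
    if position is None:
        position = int(rng.integers(100, n - 100 - m + 1))
    site = sample_site_sequence(insertion_model, rng)

    lengths = sorted(insertion_model.tsd_length_weights)
    w = np.array([insertion_model.tsd_length_weights[k] for k in lengths], float)
    tsd_len = int(lengths[rng.choice(len(lengths), p=w / w.sum())])
    tsd = site[4:4 + tsd_len]

    h = insertion_model.halo
    lo = max(0, position - h)
    hi = min(n, position + m + h)
    halo_left = _halo(insertion_model, rng, position - lo)
    halo_right = _halo(insertion_model, rng, hi - (position + m))
    new = contig_sequence[:lo] + halo_left + site + halo_right + contig_sequence[hi:]
    return new, position, tsd


def _halo(model: InsertionModel, rng: np.random.Generator, length: int) -> str:
    out = []
    for _ in range(length):
        if rng.random() < model.at_rich_flank_prob:
            out.append("AT"[rng.integers(2)])
        else:
            out.append("CG"[rng.integers(2)])
    return "".join(out)


# ---------------------------------------------------------------------------
# copy construction and planting
# ---------------------------------------------------------------------------

def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) * rng.random())


def _build_pieces(template: ElementTemplate, group: str,
                  degradation: DegradationSpec,
                  rng: np.random.Generator) -> list[tuple[str, str]]:
    """Group-specific truncation, returned as (sequence, tag) pieces.

    Tags: TIR5, TIR3, INT (non-coding spacer), TPASE (coding segment outside
    the 3' TIR).  Truncation breakpoints are uniform within the eligible span.
    """
    seq = template.sequence
    t5 = template.tir5
    t3 = template.tir3
    spacer = seq[template.tir5_span[1]:template.orf_span[0]]
    core = seq[template.orf_span[0]:template.tir3_span[0]]

    if group == "A":
        return [(t5, "TIR5"), (spacer, "INT"), (core, "TPASE"), (t3, "TIR3")]
    if group == "B":
        keep = _uniform(rng, *degradation.b_keep_range)
        dlen = int(round((1 - keep) * len(core)))
        ds = int(rng.integers(0, len(core) - dlen + 1))
        part = core[:ds] + core[ds + dlen:]
        return [(t5, "TIR5"), (spacer, "INT"), (part, "TPASE"), (t3, "TIR3")]
    if group == "C":
        m = int(round(_uniform(rng, *degradation.c_keep_range) * len(core)))
        m = max(m, 100)
        if rng.random() < 0.5:
            return [(t5, "TIR5"), (spacer, "INT"), (core[:m], "TPASE")]
        return [(core[-m:], "TPASE"), (t3, "TIR3")]
    if group == "D":
        return [(t5, "TIR5"), (spacer, "INT"), (t3, "TIR3")]
    if group == "E":
        return [(t5, "TIR5")] if rng.random() < 0.5 else [(t3, "TIR3")]
    if group == "F":
        lo, hi = degradation.f_len_range
        flen = int(rng.integers(lo, min(hi, len(core)) + 1))
        fs = int(rng.integers(0, len(core) - flen + 1))
        return [(core[fs:fs + flen], "TPASE")]
    raise ValueError(f"unknown structural group {group!r}")


def _expand_tir_tandem(pieces: list[tuple[str, str]], rng: np.random.Generator,
                       unit_len: int = 140) -> list[tuple[str, str]]:
    """Expand one TIR by an internal tandem array of a ~140-bp unit."""
    idx = [i for i, (_, tag) in enumerate(pieces) if tag in ("TIR5", "TIR3")]
    if not idx:
        return pieces
    i = idx[rng.integers(len(idx))]
    s, tag = pieces[i]
    if len(s) < unit_len + 40:
        return pieces
    off = int(rng.integers(20, len(s) - unit_len - 20))
    unit = s[off:off + unit_len]
    n_extra = int(rng.integers(2, 9))
    pieces[i] = (s[:off] + unit * n_extra + s[off:], tag)
    return pieces


def build_insert(template: ElementTemplate, group: str,
                 degradation: DegradationSpec, rng: np.random.Generator,
                 decoys: dict[str, str] | None = None,
                 strand: str | None = None) -> tuple[str, str, tuple[int, int],
                                                     list[tuple[int, int, str]]]:
    """Build a degraded element copy ready for planting.

    Returns (element sequence in genome orientation, strand, (tir5_len,
    tir3_len) in element-intrinsic orientation, nested insertion spans in
    genome-orientation element coordinates).
    """
    pieces = _build_pieces(template, group, degradation, rng)
    if rng.random() < degradation.tir_tandem_expansion_prob:
        pieces = _expand_tir_tandem(pieces, rng)

    pieces = [(mutate_indels(mutate_substitutions(s, degradation.substitution_rate, rng),
                             degradation.indel_rate, rng), tag)
              for s, tag in pieces]

    host_idx = [i for i, (_, tag) in enumerate(pieces) if tag in ("INT", "TPASE")]
    if decoys and host_idx and rng.random() < degradation.nested_te_prob:
        i = host_idx[rng.integers(len(host_idx))]
        s, tag = pieces[i]
        if len(s) > 80:
            label = sorted(decoys)[rng.integers(len(decoys))]
            cut = int(rng.integers(40, len(s) - 40))
            pieces[i:i + 1] = [(s[:cut], tag), (decoys[label], "NESTED:" + label),
                               (s[cut:], tag)]

    tir5_len = sum(len(s) for s, tag in pieces if tag == "TIR5")
    tir3_len = sum(len(s) for s, tag in pieces if tag == "TIR3")

    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        pieces = [(revcomp(s), tag) for s, tag in reversed(pieces)]

    nested: list[tuple[int, int, str]] = []
    pos = 0
    for s, tag in pieces:
        if tag.startswith("NESTED:"):
            nested.append((pos, pos + len(s), tag.split(":", 1)[1]))
        pos += len(s)
    element = "".join(s for s, _ in pieces)
    return element, strand, (tir5_len, tir3_len), nested


def plant_copy(contig_sequence: str, template: ElementTemplate, group: str,
               degradation: DegradationSpec, tsd: str, position: int,
               rng: np.random.Generator,
               decoys: dict[str, str] | None = None,
               strand: str | None = None,
               copy_id: str = "copy_1",
               contig_name: str = "contig_1") -> tuple[str, GroundTruthRecord]:
    """Insert one degraded copy at a sampled site, flanked by identical TSDs.

    ``position`` is the site start returned by :func:`sample_insertion_site`;
    the element goes in immediately after the TSD written there, and the TSD
    is duplicated on the element's right.  Contig length grows by
    len(element) + len(tsd).
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    ip = position + 4 + len(tsd)
    if not 0 <= ip <= len(contig_sequence):
        raise ValueError("insertion point outside contig")
    element, strand, tir_lengths, nested = build_insert(
        template, group, degradation, rng, decoys=decoys, strand=strand)
    # ensure the left TSD copy is present even on a raw (site-less) contig
    left = contig_sequence[:ip - len(tsd)] + tsd
    new = left + element + tsd + contig_sequence[ip:]
    rec = GroundTruthRecord(
        copy_id=copy_id, contig=contig_name, start=ip, end=ip + len(element),
        strand=strand, tsd_sequence=tsd, group=group, subfamily=template.subfamily,
        tir_lengths=tir_lengths, nested_insertion_spans=nested,
    )
    return new, rec


# ---------------------------------------------------------------------------
# whole-genome simulation
# ---------------------------------------------------------------------------

def default_templates(seed: int = 7, tpase_divergence: float = 0.24,
                      tir_divergence: float = 0.136) -> list[ElementTemplate]:
    base = default_element_template(seed=seed)
    v, w = build_subfamily_templates(base, tpase_divergence, tir_divergence, seed=seed + 1)
    return [v, w]


def _sample_positions(rng: np.random.Generator, length: int, k: int,
                      min_spacing: int, site_len: int) -> list[int]:
    lo, hi = 100, length - 100 - site_len
    if hi <= lo:
        raise ValueError("contig too short for any insertion")
    accepted: list[int] = []
    tries = 0
    while len(accepted) < k:
        tries += 1
        if tries > 500 * max(k, 1):
            raise ValueError("requested copies exceed capacity given spacing constraints")
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) >= min_spacing for q in accepted):
            accepted.append(p)
    return sorted(accepted)


def simulate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate contigs with planted copies; returns (contigs, truth table).

    Deterministic given ``spec.seed``: per-copy randomness comes from
    counter-derived substreams, so the output does not depend on incidental
    iteration details.
    """
    templates = spec.templates if spec.templates is not None else default_templates()
    model = spec.insertion_model if spec.insertion_model is not None else default_insertion_model()
    degr = spec.degradation if spec.degradation is not None else DegradationSpec()
    decoys = spec.decoy_library

    master = np.random.default_rng(spec.seed)
    site_len = len(model.consensus)

    # allocate copies to contigs proportionally to length
    lengths = np.asarray(spec.contig_lengths, float)
    alloc = np.floor(lengths / lengths.sum() * spec.n_copies).astype(int)
    while alloc.sum() < spec.n_copies:
        alloc[int(np.argmax(lengths - alloc))] += 1

    # group labels for every copy
    if spec.group_counts is not None:
        labels = [g for g, n in sorted(spec.group_counts.items()) for _ in range(n)]
        labels = list(np.array(labels)[master.permutation(len(labels))])
    else:
        gs = sorted(degr.group_weights)
        w = np.array([degr.group_weights[g] for g in gs])
        labels = [gs[i] for i in master.choice(len(gs), size=spec.n_copies, p=w / w.sum())]

    contigs: dict[str, str] = {}
    records: list[GroundTruthRecord] = []
    copy_counter = 0
    for ci in range(spec.n_contigs):
        name = f"contig_{ci + 1}"
        bg = random_dna(master, int(spec.contig_lengths[ci]), spec.background_gc)
        positions = _sample_positions(master, len(bg), int(alloc[ci]),
                                      spec.min_spacing, site_len) if alloc[ci] else []

        planted = []
        for p in positions:
            crng = np.random.default_rng([spec.seed % (2**31), 1000 + copy_counter])
            bg, p, tsd = sample_insertion_site(bg, model, crng, position=p)
            group = labels[copy_counter]
            template = templates[int(crng.integers(len(templates)))]
            element, strand, tir_lengths, nested = build_insert(
                template, group, degr, crng, decoys=decoys)
            flank_decoy = None
            if decoys and crng.random() < degr.flanking_te_prob:
                lab = sorted(decoys)[int(crng.integers(len(decoys)))]
                flank_decoy = (lab, "L" if crng.random() < 0.5 else "R")
            planted.append((p, tsd, group, template, element, strand,
                            tir_lengths, nested, flank_decoy))
            copy_counter += 1

        # assemble left-to-right, tracking coordinate shifts
        parts: list[str] = []
        prev = 0
        offset = 0
        for idx, (p, tsd, group, template, element, strand,
                  tir_lengths, nested, flank_decoy) in enumerate(planted):
            ip = p + 4 + len(tsd)  # insertion point on the background
            flanks: list[tuple[int, int, str]] = []
            if flank_decoy and flank_decoy[1] == "L":
                # decoy immediately left of the left TSD copy
                d = decoys[flank_decoy[0]]
                parts.append(bg[prev:ip - len(tsd)])
                parts.append(d)
                parts.append(bg[ip - len(tsd):ip])
                fstart = ip - len(tsd) + offset
                flanks.append((fstart, fstart + len(d), flank_decoy[0]))
                offset += len(d)
            else:
                parts.append(bg[prev:ip])
            start = ip + offset
            parts.append(element)
            parts.append(tsd)
            offset += len(element) + len(tsd)
            if flank_decoy and flank_decoy[1] == "R":
                # decoy immediately right of the right TSD copy
                d = decoys[flank_decoy[0]]
                parts.append(d)
                fstart = ip + offset
                flanks.append((fstart, fstart + len(d), flank_decoy[0]))
                offset += len(d)
            prev = ip
            records.append(GroundTruthRecord(
                copy_id=f"copy_{len(records) + 1}", contig=name,
                start=start, end=start + len(element), strand=strand,
                tsd_sequence=tsd, group=group, subfamily=template.subfamily,
                tir_lengths=tir_lengths,
                nested_insertion_spans=[(start + a, start + b, lab) for a, b, lab in nested],
                flanking_insertion_spans=flanks,
            ))
        parts.append(bg[prev:])
        contigs[name] = "".join(parts)

    truth = truth_table(records)
    return contigs, truth


def truth_table(records: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "copy_id": r.copy_id, "contig": r.contig, "start": r.start, "end": r.end,
            "strand": r.strand, "group": r.group, "subfamily": r.subfamily,
            "tsd": r.tsd_sequence, "tir5_len": r.tir_lengths[0], "tir3_len": r.tir_lengths[1],
            "nested": ";".join(f"{lab}:{a}-{b}" for a, b, lab in r.nested_insertion_spans),
            "flanking": ";".join(f"{lab}:{a}-{b}" for a, b, lab in r.flanking_insertion_spans),
        })
    return pd.DataFrame(rows, columns=["copy_id", "contig", "start", "end", "strand",
                                       "group", "subfamily", "tsd", "tir5_len",
                                       "tir3_len", "nested", "flanking"])
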