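"""Target-site-motif inference: TSM windows, consensus profile, palindrome
detection and stem-loop scoring.

Each copy flanked by an identical 7-bp TSD contributes one 93-bp window: the
50 bp upstream of the element (ending in the TSD) concatenated with the 43 bp
downstream of the element and its TSD copy.  The TSD core therefore sits
centered among 43 + 7 + 43 positions, and a palindromic insertion-site motif
appears as mirrored Watson-Crick complementarity about the core's center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import BASES, IUPAC_COMPLEMENT
from .annotate import ElementCopy

UPSTREAM_FLANK = 50   # contains the TSD
DOWNSTREAM_FLANK = 43
WINDOW_LENGTH = UPSTREAM_FLANK + DOWNSTREAM_FLANK  # 93
TSD_CORE_LENGTH = 7


@dataclass
class TSMWindow:
    copy_id: str
    sequence: str
    tsd_start_within_window: int = UPSTREAM_FLANK - TSD_CORE_LENGTH  # 0-based, 43

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(f"TSM window must be {WINDOW_LENGTH} bp")

    @property
    def tsd_slice(self) -> str:
        a = self.tsd_start_within_window
        return self.sequence[a:a + TSD_CORE_LENGTH]


@dataclass
class MotifProfile:
    counts: np.ndarray                  # (L, 4) integer counts over A,C,G,T
    n_sequences: int
    consensus: str
    information_content: np.ndarray     # bits per column, in [0, 2]
    complementarity: np.ndarray | None = field(default=None, repr=False)
    # complementarity[i, j]: fraction of windows whose base at i is the
    # Watson-Crick complement of the base at j (available when the profile
    # was built from windows; marginal counts alone cannot recover it)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.n_sequences, 1)


@dataclass
class PalindromeReport:
    span: tuple[int, int]               # within the profile, half-open
    length: int
    center: int
    per_position_complementarity: list[float]
    half_site_5p: str
    half_site_3p: str


@dataclass
class HairpinReport:
    paired_bases: int                   # nucleotides engaged in pairs
    stem_length: int                    # number of base pairs in the stem
    loop_length: int
    structure_string: str


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def build_tsm_windows(copies: Sequence[ElementCopy], contigs: Mapping[str, str],
                      ) -> tuple[list[TSMWindow], list[tuple[str, str]]]:
    """One 93-bp window per copy with an identical (mismatch-free) 7-bp TSD.

    Copies with 8-bp or imperfect TSDs, or with insufficient flank, are
    skipped; the reasons are returned alongside.
    """
    windows: list[TSMWindow] = []
    skipped: list[tuple[str, str]] = []
    for c in copies:
        if c.tsd is None:
            skipped.append((c.copy_id, "no TSD call"))
            continue
        if c.tsd.length != TSD_CORE_LENGTH or not c.tsd.identical:
            skipped.append((c.copy_id, f"TSD {c.tsd.length} bp, "
                            f"{c.tsd.mismatches} mismatch(es)"))
            continue
        s, e = c.span
        contig = contigs[c.contig]
        lo = s - UPSTREAM_FLANK
        hi = e + TSD_CORE_LENGTH + DOWNSTREAM_FLANK
        if lo < 0 or hi > len(contig):
            skipped.append((c.copy_id, "insufficient flank"))
            continue
        seq = contig[lo:s] + contig[e + TSD_CORE_LENGTH:hi]
        windows.append(TSMWindow(copy_id=c.copy_id, sequence=seq))
    return windows, skipped


# ---------------------------------------------------------------------------
# consensus profile
# ---------------------------------------------------------------------------

_B2I = {b: i for i, b in enumerate(BASES)}
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in BASES order


def consensus_profile(windows: Sequence[TSMWindow], majority_frac: float = 0.5) -> MotifProfile:
    """Tally per-position base counts over equal-length windows.

    Consensus letter: the most frequent base when unique and at frequency
    >= ``majority_frac``, else N (ties are always N).  Information content is
    2 minus the Shannon entropy of the column (bits), with no small-sample
    correction.  A pairwise complementarity matrix is tallied for palindrome
    detection.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    L = len(windows[0].sequence)
    if any(len(w.sequence) != L for w in windows):
        raise ValueError("windows of unequal length")
    n = len(windows)
    codes = np.full((n, L), -1, dtype=np.int8)
    for r, w in enumerate(windows):
        for c, b in enumerate(w.sequence):
            codes[r, c] = _B2I.get(b, -1)

    counts = np.zeros((L, 4), dtype=int)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)

    cons = []
    for j in range(L):
        col = counts[j]
        top = int(col.max())
        if top == 0 or (col == top).sum() > 1 or top / n < majority_frac:
            cons.append("N")
        else:
            cons.append(BASES[int(col.argmax())])

    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / counts.sum(axis=1, keepdims=True).clip(min=1)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=1)

    comp_codes = np.where(codes >= 0, _COMP_IDX[codes.clip(min=0)], -2)
    C = np.zeros((L, L))
    for j in range(L):
        C[:, j] = (codes == comp_codes[:, j][:, None]).mean(axis=0)

    return MotifProfile(counts=counts, n_sequences=n, consensus="".join(cons),
                        information_content=ic, complementarity=C)


# ---------------------------------------------------------------------------
# palindrome detection
# ---------------------------------------------------------------------------

def detect_palindrome(profile: MotifProfile, center: int,
                      min_complementarity: float = 0.5) -> PalindromeReport:
    """Grow symmetric arms outward from ``center``.

    A position pair (center-k, center+k) is palindromic when the fraction of
    windows carrying Watson-Crick complementary bases at the two positions
    reaches ``min_complementarity``; when the profile carries no pairwise
    tallies, the fallback is IUPAC complementarity of the consensus letters
    (N complements N).  The maximal contiguous palindromic span is returned,
    with the two pentanucleotide half sites anchored at the 7-bp core edges.
    """
    L = profile.length
    if not 0 <= center < L:
        raise ValueError("center outside profile")
    cons = profile.consensus
    comp_fracs: list[float] = []
    k = 0
    while center - (k + 1) >= 0 and center + (k + 1) < L:
        i, j = center - (k + 1), center + (k + 1)
        if profile.complementarity is not None:
            frac = float(profile.complementarity[i, j])
            ok = frac >= min_complementarity
        else:
            ok = IUPAC_COMPLEMENT.get(cons[i], "?") == cons[j]
            frac = 1.0 if ok else 0.0
        if not ok:
            break
        comp_fracs.append(frac)
        k += 1

    span = (center - k, center + k + 1)
    half5 = cons[max(span[0], center - 6):max(span[0], center - 1)]
    half3 = cons[min(span[1], center + 2):min(span[1], center + 7)]
    return PalindromeReport(span=span, length=2 * k + 1, center=center,
                            per_position_complementarity=comp_fracs,
                            half_site_5p=half5, half_site_3p=half3)


# ---------------------------------------------------------------------------
# stem-loop scoring
# ---------------------------------------------------------------------------

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def hairpin_score(consensus: str, min_stem: int = 3, min_loop: int = 3) -> HairpinReport:
    """Best single stem-loop by maximum Watson-Crick pairing.

    Dynamic program over pair/no-pair decisions restricted to chain-nested
    structures (one terminal loop, internal loops and bulges allowed, no
    bifurcation); pairing (i, j) requires j - i - 1 >= ``min_loop``.  N and
    other ambiguity letters never pair.  Structures with fewer than
    ``min_stem`` pairs are reported as unpaired.
    """
    n = len(consensus)
    s = consensus.upper()

    memo: dict[tuple[int, int], int] = {}

    def S(i: int, j: int) -> int:
        if j - i - 1 < min_loop:
            return 0
        key = (i, j)
        if key in memo:
            return memo[key]
        best = max(S(i + 1, j), S(i, j - 1))
        if (s[i], s[j]) in _WC:
            best = max(best, 1 + S(i + 1, j - 1))
        memo[key] = best
        return best

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while j - i - 1 >= min_loop:
            val = S(i, j)
            if val == 0:
                return
            if (s[i], s[j]) in _WC and val == 1 + S(i + 1, j - 1):
                pairs.append((i, j))
                i, j = i + 1, j - 1
            elif val == S(i + 1, j):
                i += 1
            else:
                j -= 1

    if n >= min_loop + 2:
        trace(0, n - 1)

    if len(pairs) < min_stem:
        return HairpinReport(paired_bases=0, stem_length=0, loop_length=n,
                             structure_string="." * n)
    dots = ["."] * n
    for i, j in pairs:
        dots[i], dots[j] = "(", ")"
    inner_i, inner_j = pairs[-1]
    return HairpinReport(paired_bases=2 * len(pairs), stem_length=len(pairs),
                         loop_length=inner_j - inner_i - 1,
                         structure_string="".join(dots))
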