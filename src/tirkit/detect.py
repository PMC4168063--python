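"""Similarity search and hit merging.

A seed-and-extend local search stands in for an external BLAST run: exact
shared words of length >= ``min_word`` between query and genome (either
strand) are chained on near-diagonals, extended, and kept when the local
alignment reaches ``min_identity`` over >= ``min_length`` columns.  Hits are
then merged into candidate element copies with the field rule for fragmented
TE copies: two hits belong to the same copy when they lie on the same contig,
closer than ``max_gap`` (default 5 kb, strict), and in the proper relative
orientation — transposase hits collinear, the two TIR hits of one element in
opposite apparent orientation (TIRs are inverted repeats of each other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib

from ._seq import revcomp

_VALID = set("ACGTN")


@dataclass
class SeedHit:
    contig: str
    start: int
    end: int                      # 0-based half-open genomic interval
    strand: str                   # "+" or "-"
    query_id: str
    query_span: tuple[int, int]   # interval on the original (plus-strand) query
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must be < end")
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateCopy:
    contig: str
    span: tuple[int, int]
    strand: str
    member_hits: list[SeedHit] = field(default_factory=list)


def _check_alphabet(seqs: Mapping[str, str], what: str) -> None:
    if not seqs:
        raise ValueError(f"empty {what} input")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"empty {what} record {name!r}")
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"non-DNA characters {sorted(bad)} in {what} record {name!r}")


def _kmer_index(queries: Mapping[str, str], k: int) -> dict[str, list[tuple[str, str, int]]]:
    """word -> [(query_id, strand, position on the oriented query)]."""
    index: dict[str, list[tuple[str, str, int]]] = {}
    for qid, seq in queries.items():
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(oriented) - k + 1):
                w = oriented[i:i + k]
                if "N" in w:
                    continue
                index.setdefault(w, []).append((qid, strand, i))
    return index


def _chain_seeds(seeds: list[tuple[int, int]], max_seed_gap: int = 150,
                 band: int = 40) -> list[list[tuple[int, int]]]:
    """Greedy chaining of (gpos, qpos) seeds along near-constant diagonals."""
    seeds = sorted(seeds)
    chains: list[list[tuple[int, int]]] = []
    for g, q in seeds:
        placed = False
        for chain in chains:
            lg, lq = chain[-1]
            if 0 <= g - lg <= max_seed_gap and abs((g - q) - (lg - lq)) <= band:
                chain.append((g, q))
                placed = True
                break
        if not placed:
            chains.append([(g, q)])
    return chains


def _extend_ungapped(genome: str, oriented_query: str, gs: int, ge: int,
                     qs: int, qe: int, xdrop: int = 15) -> tuple[int, int, int, int]:
    """X-drop ungapped extension of [gs,ge)/[qs,qe) in both directions."""
    score = best = 0
    bi = 0
    i = 1
    while gs - i >= 0 and qs - i >= 0:
        score += 1 if genome[gs - i] == oriented_query[qs - i] else -2
        if score > best:
            best, bi = score, i
        if best - score > xdrop:
            break
        i += 1
    gs, qs = gs - bi, qs - bi
    score = best = 0
    bj = 0
    j = 0
    while ge + j < len(genome) and qe + j < len(oriented_query):
        score += 1 if genome[ge + j] == oriented_query[qe + j] else -2
        if score > best:
            best, bj = score, j + 1
        if best - score > xdrop:
            break
        j += 1
    return gs, ge + bj, qs, qe + bj


def _trim_to_clean_ends(genome: str, oriented_query: str, gs: int, ge: int,
                        qs: int, qe: int, run: int = 4) -> tuple[int, int, int, int]:
    """Retract hit ends to the outermost position preceded by ``run`` clean
    matches, so chance matches in the flank cannot drag a boundary outward."""
    while ge - gs > run and (genome[ge - run:ge] != oriented_query[qe - run:qe]):
        ge -= 1
        qe -= 1
    while ge - gs > run and (genome[gs:gs + run] != oriented_query[qs:qs + run]):
        gs += 1
        qs += 1
    return gs, ge, qs, qe


def _aligned_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, score) from a global edit-distance alignment of a vs b."""
    if not a or not b:
        return 0.0, 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    n = max(len(a), len(b))
    return 1.0 - d / n, float(n - 2 * d)


def find_seed_hits(genome: Mapping[str, str], queries: Mapping[str, str],
                   min_word: int = 11, min_identity: float = 0.75,
                   min_length: int = 50) -> list[SeedHit]:
    """Seed-and-extend search of every query against every contig, both strands.

    Overlapping hits to the same query are collapsed to the best-scoring one.
    """
    if min_word < 8:
        raise ValueError("min_word must be >= 8")
    _check_alphabet(genome, "genome")
    _check_alphabet(queries, "query")

    index = _kmer_index(queries, min_word)
    raw: list[SeedHit] = []
    for contig, gseq in genome.items():
        per_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for i in range(len(gseq) - min_word + 1):
            entries = index.get(gseq[i:i + min_word])
            if not entries:
                continue
            for qid, strand, qpos in entries:
                per_key.setdefault((qid, strand), []).append((i, qpos))

        for (qid, strand), seeds in per_key.items():
            oriented = queries[qid] if strand == "+" else revcomp(queries[qid])
            qlen = len(oriented)
            for chain in _chain_seeds(seeds):
                gs = min(g for g, _ in chain)
                ge = max(g for g, _ in chain) + min_word
                qs = min(q for _, q in chain)
                qe = max(q for _, q in chain) + min_word
                gs, ge, qs, qe = _extend_ungapped(gseq, oriented, gs, ge, qs, qe)
                gs, ge, qs, qe = _trim_to_clean_ends(gseq, oriented, gs, ge, qs, qe)
                if ge - gs < min_length:
                    continue
                identity, score = _aligned_identity(gseq[gs:ge], oriented[qs:qe])
                if identity < min_identity:
                    continue
                if strand == "+":
                    qspan = (qs, qe)
                else:
                    qspan = (qlen - qe, qlen - qs)
                raw.append(SeedHit(contig, gs, ge, strand, qid, qspan,
                                   score=score, identity=identity))

    return _collapse_overlaps(raw)


def _collapse_overlaps(hits: list[SeedHit], max_overlap_frac: float = 0.5) -> list[SeedHit]:
    """Keep the best-scoring hit among overlapping hits to the same query."""
    kept: list[SeedHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.contig, x.start)):
        clash = False
        for k in kept:
            if k.query_id != h.query_id or k.contig != h.contig:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov > max_overlap_frac * min(k.length, h.length):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda x: (x.contig, x.start, x.end))
    return kept


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def query_kind(query_id: str, query_kinds: Mapping[str, str] | None = None) -> str:
    """'tir' or 'tpase'; inferred from the query name unless given explicitly."""
    if query_kinds and query_id in query_kinds:
        return query_kinds[query_id]
    return "tir" if "tir" in query_id.lower() else "tpase"


def hits_compatible(a: SeedHit, b: SeedHit, max_gap: int = 5000,
                    query_kinds: Mapping[str, str] | None = None,
                    tir_rule: str = "opposite") -> bool:
    """The pairwise chaining rule: distance (end-to-start gap) < max_gap,
    same contig, proper orientation.

    ``tir_rule`` governs TIR-TIR pairs: "opposite" demands the two arms of
    one element show opposite apparent orientation; "any" drops the strand
    requirement — when the query arms are themselves near-reverse-complements
    of each other (as here), each arm matches both strands at nearly equal
    identity and apparent orientation carries no signal.
    """
    if a.contig != b.contig:
        return False
    gap = max(0, max(a.start, b.start) - min(a.end, b.end))
    if gap >= max_gap:
        return False
    ka, kb = query_kind(a.query_id, query_kinds), query_kind(b.query_id, query_kinds)
    if ka == "tpase" and kb == "tpase":
        return a.strand == b.strand
    if ka == "tir" and kb == "tir" and tir_rule == "opposite":
        return a.strand != b.strand
    return True  # mixed TIR/TPase pairs constrain distance only


def _tir_loci(group: list[SeedHit], query_kinds: Mapping[str, str] | None,
              slop: int = 50) -> list[tuple[int, int]]:
    spans = sorted((h.start, h.end) for h in group
                   if query_kind(h.query_id, query_kinds) == "tir")
    loci: list[tuple[int, int]] = []
    for s, e in spans:
        if loci and s <= loci[-1][1] + slop:
            loci[-1] = (loci[-1][0], max(loci[-1][1], e))
        else:
            loci.append((s, e))
    return loci


def _split_tandems(group: list[SeedHit], query_kinds: Mapping[str, str] | None
                   ) -> list[list[SeedHit]]:
    """Chains holding >=4 distinct TIR loci look like tandem elements; split
    at the largest internal gap, recursively."""
    if len(_tir_loci(group, query_kinds)) < 4 or len(group) < 2:
        return [group]
    ordered = sorted(group, key=lambda h: (h.start, h.end))
    gaps = [ordered[i + 1].start - ordered[i].end for i in range(len(ordered) - 1)]
    cut = max(range(len(gaps)), key=lambda i: gaps[i])
    left, right = ordered[:cut + 1], ordered[cut + 1:]
    if not left or not right or max(gaps) <= 0:
        return [group]
    return _split_tandems(left, query_kinds) + _split_tandems(right, query_kinds)


def merge_hits(hits: Iterable[SeedHit], max_gap: int = 5000,
               query_kinds: Mapping[str, str] | None = None,
               tir_rule: str = "opposite") -> list[CandidateCopy]:
    """Partition hits into candidate copies: connected components of the
    pairwise compatibility rule, then tandem-chain splitting.

    Order-independent: the result depends only on the hit set.
    """
    hits = sorted(hits, key=lambda h: (h.contig, h.start, h.end, h.query_id, h.strand))
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hits[j].contig != hits[i].contig:
                break  # sorted by contig: no later j shares this contig
            if hits[j].start - hits[i].end >= max_gap:
                break  # sorted by start: no later j can be closer
            if hits_compatible(hits[i], hits[j], max_gap, query_kinds, tir_rule):
                parent[find(i)] = find(j)

    groups: dict[int, list[SeedHit]] = {}
    for i, h in enumerate(hits):
        groups.setdefault(find(i), []).append(h)

    candidates: list[CandidateCopy] = []
    for group in groups.values():
        for part in _split_tandems(group, query_kinds):
            if not part:
                continue
            members = sorted(part, key=lambda h: (h.start, h.end))
            tpase_strands = [h.strand for h in members
                             if query_kind(h.query_id, query_kinds) == "tpase"]
            if tpase_strands:
                strand = max(set(tpase_strands), key=tpase_strands.count)
            else:
                strand = members[0].strand
            candidates.append(CandidateCopy(
                contig=members[0].contig,
                span=(min(h.start for h in members), max(h.end for h in members)),
                strand=strand, member_hits=members))
    candidates.sort(key=lambda c: (c.contig, c.span))
    return candidates
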