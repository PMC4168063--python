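# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `tirkit`. Coordinates are 0-based half-open internally;
GFF3 and reports print 1-based inclusive.

## The element model

The reference element emulated by the simulator is a 4386-bp Galileo-like
cut-and-paste transposon: a 765-bp 5' TIR at positions [0, 765), a spacer,
a TPase ORF at [983, 3698) encoding a 905-residue protein, and a 757-bp 3'
TIR at [3629, 4386). Three structural quirks of the real element are
reproduced because the annotation logic must cope with them:

- the ORF's final 69 bp lie **inside** the 3' TIR, so the tail of the
  coding segment reappears, reverse-complemented, in the 5' TIR;
- the two arms differ in length (765 vs 757) and align at ~99% identity
  omitting indels (7 substitutions and 8 single-base insertions are placed
  in the 5' arm);
- each arm carries a ~137-bp AT-rich (~92% A+T) segment.

The ORF starts with the non-canonical `ACG` codon and carries the THAP
DNA-binding signature (C16, C21, P40, W49, C67, H70, F71, P87) and the
DDE / D(2)H catalytic residues (D327, D415, E642, D449, H452) at their
1-based protein positions. The codon pool used to realise the protein
includes codons whose reverse complements are stop codons, so the minus
strand of the ORF accumulates stops and the forward ORF is unambiguously
the longest one — a property the ORF-finder tests rely on.

### Subfamilies

`build_subfamily_templates` derives a V template from the base (W)
template by substituting exactly `round(d·L)` positions over the TPase span
(d = 0.24 by default) and topping the 3' TIR up to `round(0.136·757)`
substituted positions. Every 3'-TIR substitution is mirrored as its
complement into the aligned 5'-TIR position (via the arm alignment map), so
each subfamily keeps its internal inverted-repeat identity near 99% while
the two subfamilies diverge by the target fractions. Exact substitution
counts make the realized p-distance land on target instead of fluctuating
binomially. Divergence ≥ 0.75 is rejected (p-distance saturates).

## The insertion-site model

The 15-bp target site is `N AAN GTATTAC NTT N` — a 7-bp TSD core flanked by
4-bp shoulders, palindromic about the core's central base. Consensus
positions carry weight 0.85; degenerate (N) positions are AT-rich
(A/T 0.40 each) and **sampled with mirrored complements** at probability
0.9: a target-binding protein sees both strands, so real sites are
palindromic jointly, not just marginally. The mirrored draw preserves the
per-position marginals because the N-position distribution is
AT-symmetric. An AT-rich halo (14 bp each side, P(A/T) = 0.6) surrounds
the site, reflecting the AT-rich neighbourhoods of real insertions,
without changing the global background (i.i.d., GC 0.40 by default).

TSDs are the core 7-mer; with probability 0.025 the TSD is 8 bp (the core
plus one base to its right), the rare variant seen in real copies. On
planting, the element goes in immediately after the TSD and the TSD is
duplicated on its right, so the two flanking copies are identical at
planting time; degradation never touches the flanks.

## Degradation and the six structural groups

Planted copies decay by per-site substitutions (default 0.03) and indels
(default 5×10⁻⁴ per site, lengths 1–10, geometric) applied uniformly — no
within-copy rate heterogeneity is modelled. Group truncations:

| group | content | breakpoints |
|---|---|---|
| A | both TIRs + full internal region | — |
| B | both TIRs + partial TPase | retained fraction U(0.20, 0.85), deletion position uniform |
| C | one TIR (5' or 3', coin flip) + partial TPase | retained fraction U(0.20, 0.80) |
| D | both TIRs + non-coding spacer | — |
| E | a single TIR | — |
| F | a TPase fragment | length U(500, 2000), position uniform |

B and C retain strictly less than 95% of the coding segment so the
nearly-complete threshold separates them from A by construction — the
generator states what the groups *mean*, it does not tune toward the
classifier. With probability 0.15 a decoy TE (from a small synthetic decoy
library) is nested inside a non-TIR piece of the copy; with probability
0.05 a decoy lands immediately outside a TSD ("flanking"); with
probability 0.05 one TIR is expanded by a tandem array of an internal
~140-bp unit (2–8 extra copies), emulating observed TIR extension by
internal tandem repeats. Copies are planted on either strand with min
spacing 6 kb between insertion sites (configurable), which keeps candidate
merging of neighbours out of scope of the 5-kb rule.

Determinism: one master generator (seeded) lays out background, sites and
group labels; each copy is built from a counter-derived substream, so
per-copy randomness does not depend on incidental iteration order.

## Detection

The search is seed-and-extend: exact shared words of ≥ 11 bp between query
and genome (both strands), greedy chaining along near-constant diagonals
(gap ≤ 150, band ± 40), ungapped X-drop extension (+1/−2, drop 15), then
identity from a global edit-distance alignment of the matched substrings
(edlib); hits need identity ≥ 0.75 over ≥ 50 bp. The thresholds stand in
for an e-value cutoff and were chosen so that copies ~25% diverged from a
query remain findable; the pipeline additionally queries with both
subfamily templates so every copy has a near query. Hit ends are retracted
to the outermost position preceded by four clean matches, so chance
matches in the flank cannot drag an alignment endpoint outward — endpoint
accuracy matters downstream for TSD calling.

Merging follows the fragmented-copy rule: same contig, end-to-start gap
< 5 kb (strict), proper orientation — TPase hits collinear, mixed pairs
unconstrained. For TIR–TIR pairs the strict rule expects opposite apparent
orientation (the arms are inverted repeats of each other); because the
query arms are themselves near-reverse-complements, each arm matches both
strands at almost equal identity and the apparent strand carries no
signal, so the pipeline runs the merge with the TIR strand requirement
relaxed (`tir_rule="any"`); the strict rule remains available and tested.
Chains containing ≥ 4 distinct TIR loci are split at the largest internal
gap (possible element tandems). Merging is a union-find over the pairwise
rule and is order-independent.

## Boundary resolution and TSD calling

Three sources of evidence fix element boundaries, in order:

1. **Hit extents.** Query arms end exactly at the element termini, so hit
   ends cannot overrun the element; they anchor the span.
2. **TIR terminal pinning.** The conserved terminal 20-mer of the
   best-matching TIR query is slid ± 25 bp around each TIR-adjacent
   terminus; the best Hamming placement (≥ 70% matches) pins the boundary.
   Element ends are the best-conserved part of the element, which makes
   this the sharpest single anchor.
3. **TSD refinement.** Around the anchored boundaries, exact terminal
   duplications of k = 8…5 bp are enumerated over small boundary shifts
   (± 8 both sides; pinned sides only ± 2; one side at a time out to ± 25
   for duplications ≥ 7 bp, rescuing badly truncated TPase ends).
   Candidates are scored by k − shift; within the top score class the
   selection prefers the candidate whose duplication most resembles the
   genome-wide TSD consensus (see below), then discards candidates
   Pareto-dominated in (length, shift), then prefers the family-typical
   length (7).

The tie structure motivating step 3: a boundary off by one base always
presents the nested (k−1)-mer at zero shift, and a chance agreement
between the element's terminal base and the opposite shoulder presents a
spurious (k+1)-mer at one shift. Both ties resolve correctly by expecting
the typical length, while a genuine 8-bp TSD at the anchored boundary
dominates its nested 7-mer on both axes and survives the dominance filter.

The genome-wide consensus comes from a **two-pass** design:
`annotate_genome` first calls every copy from per-copy evidence alone,
takes the majority-rule consensus of the identical 7-bp calls (≥ 5
required), and re-runs boundary refinement with that consensus as the
tie-breaker — the family-level evidence a human annotator would use. The
consensus influences only the choice among near-tied boundary candidates;
it does not enter the TSM shoulder statistics, which are measured outside
the TSD.

`call_tsd` itself is a pure per-copy operation: compare the k terminal
bases on each side, k from 8 down to 5, all exact lengths before any
inexact one (≤ 1 mismatch by default); elements closer than 8 bp to a
contig end return an "edge" status.

Residual TSD-calling error (~2–3% of copies at 3% degradation) is
dominated by two irreducible cases: a pinning error of one base caused by
an indel in the outermost TIR bases combined with a shoulder coincidence,
and copies whose terminal fragment is shorter than the 50-bp minimum hit
length (e.g. a nested TE within 50 bp of the element edge).

## Classification

A copy's group follows from its TIR count and TPase coverage — the covered
fraction of the reference TPase query (union of hit query intervals; the
best single query when several are provided). Coverage ≥ 0.95 with two
TIRs is "nearly complete" (A); coverage below 0.05 counts as absent,
because the reference ORF overlaps the 3' TIR by 69 bp and a strictly
positive rule would call every two-TIR-only copy (D) a B from that overlap
fragment alone. The pipeline's TPase query is likewise trimmed to the
non-TIR part of the ORF.

## Insertion-site motif

Windows are 93 bp: the 50 bp upstream of the element (ending in the TSD)
plus the 43 bp downstream of the element and its TSD copy, so the 7-bp
core sits centered among 43+7+43 and the motif center coincides with the
TSD center (window index 46). Only copies with identical, mismatch-free
7-bp TSDs contribute; 8-bp and imperfect cases are excluded with logged
reasons.

The profile stores per-position counts, a majority-rule consensus (most
frequent base if unique and at frequency ≥ 0.5, else N), per-column
information content 2 − H bits without small-sample correction, and an
empirical pairwise complementarity matrix C[i, j] — the fraction of
windows whose base at i is the Watson–Crick complement of the base at j.

`detect_palindrome` grows symmetric arms outward from the center,
accepting pair (c−k, c+k) while C ≥ 0.5. Complementarity is judged
empirically rather than from consensus letters because a letter-based rule
cannot separate a degenerate-but-palindromic motif position (N paired with
N inside the motif) from plain uninformative background (N outside it):
the former shows high joint complementarity across windows, the latter
~0.25–0.34. When a profile carries no pairwise tallies (e.g. built from
counts alone), the consensus-letter IUPAC rule (N complements N) is the
fallback. Half sites are reported as the pentanucleotides anchored at the
core edges (3 shoulder + 2 core bases each), matching the field's
convention for P-superfamily target motifs.

`hairpin_score` replaces thermodynamic folding with the maximum
Watson–Crick pairing single-stem structure: a pair/no-pair dynamic program
over chain-nested pairings with terminal loop ≥ 3 and no bifurcation; N
never pairs. The claim it supports is qualitative — the motif can adopt a
stem-loop — so free-energy tables would add parameters without changing
the conclusion. Internal N·N positions interrupt the helix but not the
chain, which is why the 15-bp consensus scores a stem of 4 pairs.

## Divergence and subfamilies

p-distances use pairwise deletion by default (complete deletion
available): mismatches over sites where neither sequence has a gap or N; a
pair with no comparable sites is a flagged missing value. Subfamily
structure is recovered by average-linkage hierarchical clustering on the
distance matrix, cut into two groups at the root, with lexicographic label
ordering for determinism and mean silhouette width as support
(≤ 0.25 flags low confidence). This deliberately replaces likelihood and
Bayesian tree inference: the quantity of interest is the two-subfamily
partition and its within/between divergence, not tree topology.

Within/between summaries average the relevant unordered pairs; standard
errors come from resampling alignment columns with replacement (default
1000 replicates, seeded) and recomputing the three means. Split dating is
t = d / (2r) with r = 0.016 substitutions/site/Myr — two lineages
accumulate divergence independently after the split; the divergence to
date from is an explicit input. TIR-based analyses take the first 100 bp
of each arm, with both arms of a copy entering independently; terminal
conservation counts columns whose majority-base frequency reaches 100%,
80% and 60% over a 40-column terminal alignment, gaps counting as
mismatches.

`simulate_subfamily_alignment` generates calibrated test sets: star
phylogenies per subfamily with per-copy branch length t = within/2 (exact
substitution counts) and consensus separation between − t_V − t_W, so
expected within/between means land on the targets up to second-order
coincidence terms.

## Problem sizes and verification scope

The test suite exercises the full pipeline on 600-kb genomes with 18
planted copies and, in the end-to-end recovery test, a 2-Mb genome with 60
copies (10 per group) at 3% substitution — sizes chosen so the entire
suite runs in well under a minute of simulation plus ~15 s of annotation
while every stage still sees dozens of copies per condition. At those
conditions the pipeline recovers all planted copies, classifies groups
with ≥ 90% per-group recall, recovers planted TSDs exactly in ≥ 95% of
copies, and rediscovers the GTATTAC core and the 15-bp palindrome.

What passing these tests does and does not show: the simulator's
background is i.i.d. and its degradation uniform, so the tests demonstrate
correctness of the algorithms under the stated element model — they do not
certify performance on real assemblies with segmental duplications,
satellite arrays, N-runs, or TE families the query library does not
represent. The simulator also does not model transposition dynamics,
ectopic recombination, or within-copy rate variation.

## Numerical and edge-case choices

- Alignment scoring for flank/TIR comparisons: match +1, mismatch −1, gap
  open −4, gap extend −1 (configurable); TIR percent identity omits indel
  columns.
- `detect_tir_pair` switches from full local DP to word-seeded window
  cropping above 4×10⁶ matrix cells; the cropped alignment is exact.
- Local alignment may append a couple of chance matches beyond a planted
  arm; TIR lengths are therefore accurate to ±3 bp, and element
  *boundaries* come from hit/pin/TSD evidence rather than arm alignment
  endpoints (the palindromic target site would otherwise pull arm ends
  ~8 bp into the flanks).
- Tandem repeat detection scans lags 20–250 with one-period windowed
  identity ≥ 0.8; smaller periods claim regions first, suppressing
  harmonics; copy number is span/period to one decimal.
- AT-rich segments: sliding 100-bp windows at ≥ 0.8 A+T, merged, trimmed
  to A/T terminal bases. In AT-leaning (rather than GC-rich) context the
  merged span can exceed the underlying segment by up to ~30 bp per side —
  inherent to a windowed definition.
- Degenerate clustering input (all distances equal) still returns a valid
  two-group partition, support ≈ 0, flagged low-confidence.
- ORFs are stop-to-stop frame segments ≥ 50 codons over six frames; with
  non-canonical starts allowed the segment's first codon is the start,
  else the first ATG; codons containing N translate to X.

## Known limitations

- TSD calls on TPase-fragment copies (group F) are intrinsically ±1-bp
  ambiguous when the element's terminal base coincides with a shoulder
  base; the family-consensus tie-break resolves most but not all cases.
- Genuine 8-bp TSDs whose first 7 bp equal the family consensus are
  occasionally demoted to 7-bp calls (and vice versa under pinning
  errors); at the default 8-bp rate (2.5%) this affects well under 1% of
  copies.
- The merge rule's orientation constraint is uninformative for
  near-palindromic TIR queries; distance does the work, which assumes
  distinct elements are separated by more than the 5-kb merge gap.
- `cut_tree` at k=2 always yields two groups; with more than two real
  subfamilies the partition is a coarsening.
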