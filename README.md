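# tirkit

Annotation toolkit for **Galileo-like TIR transposons** — DNA transposons of
the *P* superfamily whose defining features are long terminal inverted
repeats (TIRs), a THAP/DDE-motif transposase (TPase), and short target site
duplications (TSDs) created on insertion. Genomes such as *Drosophila
willistoni*'s carry large families of decayed copies of such elements:
nearly complete elements, copies with two TIRs and a partial TPase segment,
solo TIRs, and bare TPase fragments. `tirkit` turns a genome FASTA plus a
small query library (a reference TIR and TPase segment) into a structured
annotation of every copy, and summarizes the family's insertion preferences
and subfamily structure.

The pipeline:

1. **Detection** — an internal seed-and-extend similarity search (exact
   shared words, diagonal chaining, X-drop extension, edit-distance
   identity) finds hits of the query segments on both strands; hits on the
   same contig closer than 5 kb and in compatible orientation are merged
   into candidate copies.
2. **TIR/TSD resolution** — the upstream flank of each candidate (up to
   5 kb) is locally aligned against the reverse complement of its
   downstream flank to resolve the TIR pair; element boundaries are pinned
   on the conserved TIR termini and on the flanking duplication (the TSD,
   called by comparing the k terminal bases on each side, k = 8…5,
   exact before inexact).
3. **Structural classification** into six groups:
   A nearly complete · B two TIRs + partial TPase · C one TIR + partial
   TPase · D two TIRs only · E one TIR only · F TPase fragment — from the
   TIR count and the covered fraction of the reference TPase segment.
   Per-copy annotation adds nested/flanking TEs, AT-rich segments,
   TIR-internal tandem repeats, the longest ORF and its THAP
   (C16, C21, P40, W49, C67, H70, F71, P87) and catalytic
   (D327, D415, E642, D449(2)H452) residues.
4. **Insertion-site motif (TSM)** — each copy flanked by an identical 7-bp
   TSD contributes a 93-bp window (50 bp upstream including the TSD + 43 bp
   downstream without element or TSD); the per-position profile yields a
   majority-rule consensus, per-column information content
   (2 − Shannon entropy, bits), a maximal palindrome grown outward from the
   TSD center by empirical Watson–Crick complementarity, and a stem-loop
   score (maximum single-stem base pairing with loop ≥ 3).
5. **Divergence** — pairwise p-distances (mismatches over comparable,
   non-gap sites) on aligned TPase or TIR segment sets; average-linkage
   clustering cut at the root into two subfamilies (V/W); within/between
   means with site-bootstrap standard errors; split dating as
   *t* = *d* / (2 × 0.016) Myr using a *Drosophila* synonymous rate.

A first-class synthetic-genome module plants ground-truthed copies —
degraded by substitutions and indels, truncated into the six groups,
inserted at sites drawn from a palindromic AT-rich 15-bp motif with core
consensus `GTATTAC`, in two subfamilies diverged ~24% (TPase) / ~13.6%
(TIRs) — so every stage can be scored against what was actually planted.

## Worked example

```bash
tirkit simulate --seed 3 --out-dir sim --n-copies 15 --genome-length 500000
tirkit classify --genome sim/genome.fasta --te-library sim/decoys.fasta --out-dir cls
tirkit tsm --genome sim/genome.fasta --copies cls/copies.tsv --out-dir tsm
tirkit report --copies cls/copies.tsv --out report.json
```

prints (stderr log plus report):

```
INFO tirkit: classify: 15 copies; group counts {'A': 4, 'B': 1, 'C': 4, 'D': 3, 'E': 3, 'F': 0}
INFO tirkit: tsm: 15 windows, consensus TSD GTATTAC, palindrome 15 bp
total copies: 15
  group A: 4
  group B: 1
  group C: 4
  group D: 3
  group E: 3
  group F: 0
with nested TE: 2 (13.3%)
with flanking TE: 1 (6.7%)
```

All 15 planted copies were recovered and placed into their structural
groups; the insertion-site stage rediscovered the generating TSD consensus
`GTATTAC` and the full 15-bp palindromic target site motif (7-bp duplicated
core plus 4 complementary bp on either side). `cls/annotation.gff3` holds
the per-copy features (element, TIR, TPase_segment, TSD, nested_TE,
AT_rich, tandem_repeat; 1-based inclusive coordinates), `cls/copies.tsv`
the per-copy table, `tsm/profile.tsv` the position–count matrix.

The same objects are available as a library:

```python
import tirkit

contigs, truth = tirkit.simulate_genome(
    tirkit.SyntheticGenomeSpec(n_copies=60, seed=1, contig_lengths=(2_000_000,)))
result = tirkit.annotate_genome(contigs)
tsm = tirkit.tsm_stage(result.copies, contigs)
print(tsm.consensus_tsd, tsm.palindrome.length)   # GTATTAC 15
```

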