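# Methods

This note documents the models, parameters and design choices behind
`duobar`, in the order data flows through the pipeline, followed by the
simulator that defines the package's test conditions.

## Amplicon design and geometry

A specimen's barcode is the 658-nt 5′ *COI* region, amplified as two
overlapping fragments: FC spans barcode positions [0, 307) and BR spans
[225, 658), so the fragments share 82 nt and tile the full barcode
(307 + 433 − 82 = 658). These spans are the package's derived defaults:
they are the geometry that simultaneously satisfies the designed 658-nt
total, the 82-nt fragment overlap, and the fragment length windows
(300–400 nt for FC, 400–500 nt for BR) once each amplicon gains two 5-mer
MIDs and its two primers (FC: 25 + 20 nt of primer; BR: 20 + 26 nt). Each
amplicon has the layout

```
[forward MID][forward primer][fragment][revcomp(reverse primer)][revcomp(reverse MID)]
```

MIDs come from two fixed 20-entry lists (FC list and BR list, 40 distinct
5-mers total); both ends of an amplicon use its own fragment's list. The
combinatorial well layout is not standardized, so it always travels in an
explicit tag-mapping TSV; the simulator's default layout indexes columns
1–12 with list entries 1–12 (forward) and rows A–H with entries 13–20
(reverse).

## Merging (SeqPrep-style)

All ungapped overlaps between the forward read and the reverse-complemented
reverse read are scanned longest-first; the first overlap ≥ 25 nt with a
mismatch fraction ≤ 0.02 is accepted (longest-first/first-accept is the
deterministic tie-break). Consensus keeps the base with the higher Phred
score (forward read on ties), with quality `max(q₁,q₂)` at agreements and
`|q₁−q₂|` at disagreements — the usual convention for conflicting evidence.
The minimum-quality requirement is applied as a *mean*-quality ≥ 20 filter
on the merged read, the least destructive reading of a minimum-Phred
filter; optional per-base trimming was considered and rejected because the
merger's quality arithmetic already down-weights unreliable disagreements.
Length gates default to the raw merged read (trimming order: length gate
before demultiplexing); gating the primer/MID-trimmed insert instead is a
configuration switch.

## Demultiplexing

MIDs are matched exactly by default: a 5-mer has no safe error-correction
margin against a 20-entry list (a `mid_mismatch` flag exists for
experiments). Both read orientations are tried; if both resolve to tag
combinations the read is ambiguous and is left unassigned (unassigned is a
counted outcome, never an error). Primers may contain IUPAC degeneracies
and inosine (`I`), which matches any base; each primer is located within a
30-nt window inward of its MID with ≤ 2 mismatches — a bounded window
prevents internal false hits while tolerating primer-region sequencing
error. Reads whose MIDs resolve but whose primers cannot be located keep
MID-only trimming and are counted (`primer_not_found`); the downstream
length gates police them.

## Dereplication, chimera removal, clustering

Dereplication is exact string identity with counts retained and singletons
kept; the canonical order everywhere is (count descending, sequence
lexicographic), which makes the whole pipeline deterministic without any
seed.

Chimera detection is a de novo two-parent crossover test in the UCHIME
family, applied per specimen × fragment. Candidate parents for a query are
unflagged sequences with count ≥ 2× the query's (PCR arithmetic: a chimera
arises later than its templates, so genuine parents are more abundant).
Over all parent pairs and crossover points, the best two-segment model is
computed from per-position match profiles (columns, for the equal-length
amplicons the assay produces; gapped queries are projected through a global
alignment). A query is flagged when

* the two-segment model matches strictly more positions than the best
  single parent,
* the query diverges ≥ 0.008 from its closest candidate parent (protecting
  sequencing-error copies of an abundant template), and
* the vote score `h = Y/(Y + 8·N + 0.5·A) ≥ 0.28`, where over columns at
  which exactly one parent matches the query, `Y` supports the model's
  local parent and `N` the other parent, and `A` counts columns matching
  neither. Contradicting votes are weighted heavily (β = 8) so genuine
  biological variants straddling two references are not flagged.

The free parameters (fold 2, min divergence 0.008, score 0.28) follow the
published de novo defaults of the algorithm family; β and the abstain
weight are this package's own calibration of the vote formula, documented
here because the original score has several published variants.

Clustering is greedy centroid assignment at 99% identity: scanning in
canonical order, a sequence joins the *first* centroid within threshold,
else founds a cluster. Identity is the fraction of identical columns of
the optimal global alignment under match +1 / mismatch −1 / gap open −2 /
gap extend −1 (identity denominators differ between tools; this one is
fixed and tested). Equal-length pairs with ≤ 5% Hamming mismatches skip
the dynamic programming, where the ungapped alignment is optimal.

## Fragment pairing and assembly

Compatibility screen: the highest-scoring ungapped local segment pair
(HSP) between the FC and BR centroids, found by an exhaustive diagonal
scan (match +1, mismatch −2, vectorised Kadane per diagonal; ties resolve
to higher score, then longer segment, then lower offsets). Both BR
orientations are tried. Acceptance is conjunctive: identity ≥ 98%, length
≥ 25 nt, mismatches ≤ 2 — note that at the designed 82-nt overlap the
identity criterion already rejects 2 mismatches (80/82 = 97.6%).

Assembly joins suffix(FC)/prefix(BR) through the best ungapped overlap
≥ 80 nt with ≤ 2% mismatches (longest-first/first-accept); at overlap
disagreements the larger cluster's base wins (FC on ties). Assembly is
deliberately ungapped: indel-bearing amplicons fail it and are visible in
the logs rather than silently shifted. When several clusters exist on each
side, candidates are matched one-to-one greedily by descending support
(min of the two cluster sizes, then FC size, then centroid order), so each
cluster contributes to at most one barcode.

## Barcode calling and identification

Per specimen, support of an assembled barcode is min(FC cluster size, BR
cluster size) — the paired evidence cannot exceed its weaker side — and a
sequence is reported iff support / Σ support is **strictly** greater than
0.10 (so at most 9 sequences are ever reportable). Specimens are classed
none / single / multiple. Identification is a local best-hit search over a
labelled reference FASTA using the same alignment identity as clustering,
ties to the earlier record. The basis of the abundance fraction (cluster
support, not raw read counts) is an explicit choice: totals after
assembly are otherwise undefined.

## Distances and trees

K2P uses pairwise deletion (sites with gaps, `N` or other ambiguity are
excluded per pair), and raises a saturation error when `1−2P−Q ≤ 0` or
`1−2Q ≤ 0` rather than returning infinities. Neighbor joining is the
standard Saitou–Nei algorithm; ties in the Q-criterion join the
lowest-index pair, and branch lengths are reported as computed (negative
lengths are legitimate NJ output and are not clamped). Heterogeneous
sequence sets must be aligned by the caller (or per-pair alignment is
applied when lengths differ); the package does not build multiple
alignments. Distance matrices serialize to a PHYLIP-style square format
that round-trips exactly at 10 decimal places.

## The simulator

`duobar.simulate` emulates the full study design: plates of specimens each
with one true barcode drawn from a reference pool, two tagged fragments
per specimen, 300 × 2 paired-end reads. Its defaults are the package's
standard test conditions: 2 plates × 96 wells, coverage 50 read pairs per
fragment per specimen, per-base substitution rate 0.001, 5% contaminated
wells, 2% chimeric amplicons, 5% endosymbiont-positive wells.

Choices where the design was open, fixed once and documented:

* **References**: 32 random sequences with pairwise divergence ≥ 0.05
  (random 658-mers are ~75% divergent in practice; the floor only guards
  degenerate draws). Specimens draw their taxon from this pool, so shared
  taxa across wells occur, as in a real bulk sample.
* **Contamination**: a contaminated well carries a second specimen's
  barcode at a 30% read share, tagged with the well's own MIDs —
  modelling intra-sample contamination picked up before tagging, the
  dominant real-world mode.
* **Endosymbiont**: a synthetic "Wolbachia-like" template ≥ 15% divergent
  from every reference, co-amplified at a 20% read share in positive
  wells, and included (labelled) in the simulator's reference FASTA. Under
  the strict >10% rule a positive well whose binomially sampled share
  lands at or below 10% is correctly *not* reported — tests assert the
  rule, not universal reporting.
* **Chimeras**: formed only in wells holding ≥ 2 templates, with a
  breakpoint uniform over the middle half of the fragment (terminal
  breakpoints are indistinguishable from their parents and would be
  untestable as chimeras).
* **Errors and qualities**: substitutions uniform over the three
  alternative bases; qualities ~ N(35, 3) clipped to [2, 41], drawn
  independently of the error process. This exercises every threshold
  without modelling cycle-dependent MiSeq error profiles; indels are not
  simulated, matching the pipeline's ungapped merge/assembly design.

All randomness flows from a single integer seed; identical configurations
are byte-identical. What passing tests on this simulator do **not** show:
robustness to indels, primer-slippage, quality-correlated errors, index
hopping between plates, or reference databases with missing taxa — real
data can fail in those ways while every test here stays green.

## Problem sizes used in the test suite

Unit and property tests run on plates of 4–24 wells at coverage 5–50; the
study-scale acceptance check uses the simulator's full defaults (2 × 96
specimens, 19 200 read pairs) and asserts ≥ 99% exact barcode recovery,
complete flagging of chimeras whose parents are ≥ 10× as abundant, zero
false flags of true fragments, and correct endosymbiont labelling.
`scripts/acceptance.py` reports the assembled length (658) and detected
overlap (82) recomputed from a single error-free specimen at the packaged
defaults.

## Known limitations

* Ungapped merging/assembly: amplicons with real indels are dropped (and
  counted), not rescued.
* The HSP screen returns only the single best segment pair; multi-HSP
  compatibility (e.g. rearranged amplicons) is out of scope.
* The chimera vote formula is one member of a family; sensitivity beyond
  the tested regime (two parents ≥ 3% divergent, ≥ 10× abundance) is not
  characterised.
* `best_hit` is exhaustive over the reference set — appropriate for the
  local, user-supplied databases it targets, not for GenBank-scale search.
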