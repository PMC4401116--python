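# duobar

Full-length DNA barcodes from dual-indexed, two-fragment amplicon
sequencing.

Specimen identification by DNA barcoding conventionally relies on Sanger
sequencing of the ~658-bp 5′ region of mitochondrial *COI*. `duobar`
implements the alternative: thousands of individually tagged specimens are
PCR-amplified as **two overlapping sub-fragments** (FC, the 5′ half; BR, the
3′ half) that fit short paired-end reads, pooled on a single sequencer run,
and reconstructed bioinformatically into full-length barcodes — with enough
per-specimen depth to separate the true barcode from intra-sample
contamination, PCR chimeras and co-amplified endosymbionts (*Wolbachia*).

The package is aimed at people building or evaluating multiplexed barcoding
workflows: it is both a runnable pipeline and a test bed, shipping a
ground-truthed read simulator of the whole study design so every stage can
be validated at desk scale.

## The method

Each amplicon carries a well-identifying 5-mer index (MID) on **both** ends,
drawn from two published 20-entry lists (one per fragment), plus the
amplification primers; plates are kept apart as separate read pools. The
pipeline stages, with their standard thresholds:

1. **Merge** paired-end reads over their ungapped overlap (min 25 nt,
   ≤ 2% overlap mismatches; consensus takes the higher-quality base).
2. **Filter**: mean Phred ≥ 20; merged length 300–400 nt (FC) or
   400–500 nt (BR).
3. **Demultiplex** by the terminal MID pair (exact match, both
   orientations tried) and trim MIDs + degenerate primers (IUPAC and
   inosine aware).
4. **Dereplicate** (counts retained, singletons kept), remove **de novo
   chimeras** with a UCHIME-style two-parent crossover test, and cluster at
   **99% identity** with greedy centroid assignment (UCLUST-style).
5. **Pair fragments**: FC×BR cluster pairs are screened by their best
   ungapped HSP (≥ 98% identity, ≥ 25 nt, ≤ 2 mismatches) and assembled
   through the designed 82-nt overlap (min 80 nt, ≤ 2% mismatches),
   yielding 658-nt barcodes.
6. **Call barcodes**: per specimen, sequences with **> 10%** of total
   support are reported (none / single / multiple) and identified by best
   global-alignment hit against a labelled reference FASTA.
7. **Distances**: Kimura 2-parameter distances
   (`d = −½·ln((1−2P−Q)√(1−2Q))`), Saitou–Nei neighbor-joining trees
   (Newick), and per-specimen concordance against Sanger sequences at the
   2% threshold.

## Worked example

Simulate a messy 4-well plate (50% contaminated wells at a 30% read share,
50% *Wolbachia*-positive wells, 0.1%/base error) and run the pipeline:

```python
from duobar import SimConfig, simulate, run_all, PipelineConfig, ReferenceDb

cfg = SimConfig(n_plates=1, wells_per_plate=4, coverage=20, seed=5,
                contaminant_frac=0.5, contaminant_share=0.3,
                endosymbiont_rate=0.5)
sim = simulate(cfg)
res = run_all(sim.reads, sim.mapping, sim.primers, PipelineConfig(),
              reference_db=ReferenceDb(sim.references))
print(res.calls_table().drop(columns="sequence").to_string(index=False))
```

```
specimen   status  rank  abundance_fraction          label  identity
   P1_A1 multiple     1              0.4444       taxon013       1.0
   P1_A1 multiple     2              0.3889       taxon005       1.0
   P1_A1 multiple     3              0.1667 Wolbachia-like       1.0
   P1_A2   single     1              1.0000       taxon005       1.0
   P1_A3   single     1              1.0000       taxon010       1.0
   P1_A4 multiple     1              0.7333       taxon015       1.0
   P1_A4 multiple     2              0.2667       taxon031       1.0
```

Well A1 carried its own barcode (taxon013), a contaminant (taxon005,
which is A2's true barcode) and a *Wolbachia*-like co-amplicon — all three
pass the >10% rule, are assembled to full length and labelled; the top-ranked
sequence is the specimen's true barcode. Wells A2/A3 are clean
single-barcode specimens. `res.report.to_dataframe()` gives the per-stage
in/out/dropped counts (e.g. `demux[P1:BR] 80 → 79, no_tag=1`: one read hit
the one well whose tags were corrupted by sequencing error).

The same flow is available from a shell:

```bash
duobar simulate --out sim/ --plates 1 --wells 4 --coverage 20 --seed 5
duobar run --in sim/ --out calls/ --refs sim/references.fasta
```

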