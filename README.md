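# otseq

Design and analysis of **barcoded surrogate reporter libraries** for
evaluating CRISPR-Cas9 off-target editing in cells.

Genome-wide screens (GUIDE-seq, CIRCLE-seq and relatives) nominate candidate
off-target (OT) sites for a guide RNA, but validating hundreds or thousands
of them in cells is the bottleneck. A pooled surrogate library solves this:
each candidate site is synthesised as a short surrogate copy on a lentiviral
construct that also carries the guide cassette, the pool is delivered to
Cas9-expressing and unedited (MOCK) cells, and editing at every site is read
out simultaneously by deep amplicon sequencing. Because nuclease-induced
deletions can erase the very bases that distinguish similar OT sites, every
construct carries a 10-nt barcode ("AC" + 8 random bases) immediately
upstream of the surrogate site, so reads remain uniquely assignable even
when the site itself is mutated.

`otseq` implements the complete computational side of this assay for people
running or simulating such screens:

- **Library design** — enumerate, for each 20-nt spacer, every genomic
  window with an NGG PAM within a chosen Hamming distance (default ≤ 4
  mismatches); assign collision-free barcodes; assemble the exact 170-nt
  synthesis oligo (Golden Gate flanks + BsmBI site + `aCACC` linker + `g` +
  spacer + 82-nt scaffold + 10-nt barcode + 27-nt surrogate site + `GTTTg` +
  BsmBI site); discard constructs with internal BsmBI sites.
- **Read processing** — merge mate pairs by overlap, demultiplex on the
  barcode behind a constant scaffold anchor, apply the three background
  filters (exact structural prefix/suffix; subtraction of synthesis-artifact
  alleles shared with MOCK; reclassification of 1-bp indels outside the
  cut-proximal window N15–N21), and call indels by global alignment
  (Needleman–Wunsch, affine gaps, leftmost tie-breaking).
- **Site calling** — per site, the 2×2 table of indel/non-indel clean reads
  in SpCas9 vs MOCK is tested with a two-sided Fisher's exact test and
  Benjamini–Hochberg adjusted across the run. A site is significant when
  adj. *p* < 0.05 **and** the indel-frequency fold change
  FC = IF(SpCas9)/IF(MOCK) ≥ 2, with ≥ 5 supporting indel reads; significant
  sites split at IF = 3% into LIOT (low) and HIOT (high indel) classes.
  Depth (≥ 32 clean reads per sample), synthesis-quality (MOCK IF ≤ 4%) and
  WT-background (MOCK IF ≤ 25%) gates, plus read-share enrichment/depletion
  flags (growth effects), are applied first.
- **Context analysis** — mismatch position (N1 PAM-distal … N20
  PAM-proximal) and type (12 ordered spacer→protospacer substitutions, e.g.
  the wobble-forming GA type) profiles per call group, with two-tailed
  hypergeometric enrichment tests and a guide GC-content comparison.
- **Annotation** — gene-feature categories (5'UTR/3'UTR/exon/intron/±2 kb
  flank/intergenic) from a GFF3, plus user gene-list intersection.
- **Simulation** — a fully ground-truthed generator (genome with planted
  sites, library, paired FASTQ for both samples, truth tables) so every
  stage is testable without external data.

## Worked example

Simulate a two-guide screen (14 constructs, depth 2000 read pairs per
construct per sample, 1% background indel rate) and run the pipeline:

```bash
otseq simulate --seed 42 --out sim
otseq count --manifest sim/manifest.tsv \
    --mock sim/mock_R1.fastq.gz sim/mock_R2.fastq.gz \
    --cas9 sim/cas9_R1.fastq.gz sim/cas9_R2.fastq.gz --out counts
otseq call --counts counts/counts.tsv --out calls
```

The `call` step prints the class tally

```
NSOT    8
HIOT    4
LIOT    2
```

and `calls/calls.tsv` starts with the thresholds in effect followed by one
row per construct, e.g.

```
construct_id    total_mock  indel_mock  total_cas9  indel_cas9  if_mock  if_cas9  ...  fold_change  call
g1|chrS:52:+    1765        4           1739        1561        0.227    89.76    ...  396.1        HIOT
g1|chrS:1583:+  1758        3           1772        4           0.171    0.226    ...  1.32         NSOT
```

The first row is the guide's perfect (on-target) site: ~90% of clean SpCas9
reads carry an indel versus 0.2% background in MOCK, a ~400-fold change —
a high-confidence HIOT. The second site's SpCas9 indel frequency is
indistinguishable from background (Fisher *p* = 1), so it is NSOT.
`otseq context` and `otseq annotate` then profile mismatch determinants and
genomic locations of the significant sites.

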