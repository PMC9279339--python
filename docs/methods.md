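# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `otseq`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The assay being modelled

A pooled surrogate reporter screen measures nuclease-induced indels at many
candidate off-target (OT) sites at once. Each library member is one
synthesis oligo carrying both the guide expression cassette and a surrogate
copy of one candidate site; after lentiviral delivery at low multiplicity,
Cas9 cuts the surrogate site in cis and the resulting indel spectrum is read
by paired-end amplicon sequencing of edited (SpCas9) and unedited (MOCK)
cells. The MOCK sample measures everything that is not editing: oligo
synthesis errors, PCR artifacts and sequencing errors.

### Oligo anatomy

```
ACCA CGTCTC ACACC g [spacer 20] [scaffold 82] [barcode 10][surrogate 27] GTTTG CGTCTC ACGG
 4     6      5   1     20          82              37                     5     6      4   = 170 nt
```

The surrogate region is protospacer (20) + PAM (3) + 4 nt of genomic
downstream context = 27 nt. Spacer/surrogate positions are numbered N1
(PAM-distal) to N20 (PAM-proximal); surrogate coordinates run N1–N27. The
82-nt scaffold constant is the canonical SpCas9 sgRNA scaffold (76 nt)
followed by the TTTTTT pol-III terminator; it is configurable, and every
length check derives from the configured value. The published assay does not
print the scaffold sequence, so this is the package's choice of the standard
constant. The trailing BsmBI site is stored as `CGTCTC` on the given strand,
mirroring the upstream site; both flanking 4-mers are stored uppercase.
Constructs whose variable interior contains `CGTCTC`/`GAGACG` cannot be
Golden Gate cloned and are rejected with reason "BsmBI".

## Off-target enumeration

The scanner tests every 20-nt window on both strands that is followed by an
NGG PAM and 4 nt of downstream sequence, keeping windows within a Hamming
distance `max_mismatches` (default 4, hard cap 6) of the spacer. Only NGG is
enumerated; alternative PAMs are out of scope. Windows whose 27-nt footprint
contains ambiguity codes are skipped and counted. Coordinates are 0-based
half-open; `start` is the leftmost reference coordinate of the protospacer
on either strand, and reported sequences are always on the protospacer
strand. Bulge-containing (gapped) off-targets are not enumerated: the
surrogate design encodes substitution-type mismatches only.

Barcodes are "AC" + 8 bases drawn uniformly with rejection: duplicates (or,
in the optional minimum-Hamming-distance mode, any barcode closer than the
requested distance to an accepted one), barcodes containing a BsmBI site,
and barcodes creating one at the scaffold or protospacer junction are
redrawn. Assignment is deterministic given the seed and the site order.

## Read processing

**Merging.** Mate 2 is reverse-complemented and slid against mate 1; the
overlap with the fewest mismatches wins, ties going to the longest overlap,
and is accepted if its mismatch fraction is ≤ 0.25 with ≥ 10 bases
(defaults). Disagreements resolve to the higher-quality base; at equal
quality mate 1 wins (its cycle is earlier). Pairs with reads fully
containing each other are not specially handled — the amplicon (210 nt with
the simulator's primer flanks) is longer than one 150-nt read.

**Demultiplexing.** The 10-nt barcode is read immediately after the last 12
bases of the scaffold (exact anchor match; reverse complement tried
automatically). Barcode matching is exact: the structural filter requires an
unchanged barcode anyway, so tolerant matching could only admit reads that
would later be discarded.

**Structural filter.** A read passes only if the invariant block
`g + spacer + scaffold + barcode` and the downstream `GTTTG` + BsmBI anchor
both match exactly; the segment between them is the observed surrogate
region. Observed lengths deviating from 27 by more than 24 fail with reason
"length".

**Indel calling.** The observed segment is globally aligned to the 27-nt
reference (Gotoh affine: match +2, mismatch −4, gap open −6, gap extend −1
per base; all configurable). The scores are the package's own defaults —
chosen so one long gap beats scattered gaps — since the assay literature
does not fix them. Only gaps are edits; substitutions never are. Each gap is
reported in reference coordinates (deletions as the deleted interval,
insertions as the reference base they follow, anchor 0 = before N1) and
shifted to its leftmost equivalent placement, so calls are deterministic
within repeat runs. When two structurally different gap layouts tie in
score (possible only with ≥ 2 gaps plus compensating substitutions), the
traceback's diagonal-first preference decides; the test suite verifies the
result is always one of the optimal leftmost-normalised alignments and
exactly the canonical one for single-indel reads.

**Positional filter.** A read whose called events are all 1-bp indels lying
entirely outside N15–N21 is reclassified as non-indel: single-base
PCR/sequencing slippage far from the cut (the blunt cut sits between N17 and
N18, 3 bp upstream of the PAM) is background, while any event of length ≥ 2
or touching the window is kept as an edit. Boundary cases are decided by the
position of the deleted base or insertion anchor in the leftmost-normalised
representation. Reclassified reads stay in the clean-read denominator (the
default; full removal is available), keeping indel frequencies comparable
across sites. The filter is applied identically to MOCK and SpCas9.

**WT pseudo-edit subtraction.** Non-reference alleles present in the MOCK
sample are synthesis/PCR artifacts shared by both samples; their reads are
removed from the SpCas9 tallies (from both indel and total counts, tallied
as `wt_pseudoedit`). An allele must reach 1% of the construct's MOCK clean
reads and ≥ 2 reads (defaults) to trigger subtraction: template-level
artifacts recur at substantial frequency, whereas a single stray MOCK
sequencing error that happens to match a genuine edit allele would otherwise
delete the corresponding SpCas9 evidence wholesale. Setting both thresholds
to 0 restores unconditional subtraction of any shared allele.

## Site calling

Per construct, indel and non-indel clean reads of the two samples form a
2×2 table. The two-sided Fisher p is computed by summing hypergeometric
probabilities over the fixed-margin support for all tables no more likely
than the observed one (relative tolerance 1e-12 on the comparison; the test
suite checks every table with margins ≤ 30 against exact integer
enumeration, and cross-checks scipy). BH adjustment (statsmodels) spans all
constructs of a run that pass the depth and background filters — the widest
defensible family, since the assay tests all sites jointly.

Thresholds (all configurable, echoed into output):

| parameter | default | meaning |
|---|---|---|
| alpha | 0.05 | BH-adjusted significance level |
| min_fold_change | 2 | IF(SpCas9)/IF(MOCK) required for significance |
| hiot_if | 3% | LIOT/HIOT split on SpCas9 IF |
| min_total | 32 | clean reads required in **each** sample |
| min_indel | 5 | SpCas9 indel reads required for significance |
| max_mock_if | 4% | synthesis-quality gate on MOCK IF |
| max_wt_if | 25% | hard background gate on MOCK IF |

Interpretations the assay description leaves open, fixed here: the depth
gate applies per sample (the stricter reading); a site with < 5 SpCas9
indel reads is demoted to NSOT rather than removed (the support rule is a
significance gate, not a quality filter; `min_indel_policy="filter"`
reverses this); when MOCK has zero indel reads the fold change uses a
0.5-read continuity correction on the MOCK numerator only (raw infinite FC
available). The synthesis (4%) and background (25%) gates are independent
switches because different library runs may enable either.

Enrichment/depletion: total clean reads per construct are normalised to
reads-per-million within each sample; a ≥ 2-fold shift in either direction
flags the construct (growth effects from the integrated construct), and
flagged constructs are excluded from context analysis.

## Context analysis

Mismatch types are ordered (spacer base, protospacer base) pairs read on the
non-target strand — "GA" is spacer G opposite protospacer A, the pairing
that forms an rG:dT wobble with the target strand. Profiles count mismatch
positions (N1–N20) and the 12 types over a call group, by default restricted
to sites with 3–4 mismatches where positional effects carry signal.
Enrichment of the significant group against a background (ALL or NSOT, both
supported) is a hypergeometric draw-without-replacement model; upper and
lower tails are both reported. GC content of spacers is compared between
high- and low-efficiency guides (threshold 80% on-target IF) with a
two-sided Mann–Whitney test — a rank test is the package's choice, as the
assay description names none.

## Annotation

Sites are 20-nt protospacer intervals; overlap with any base of a feature
suffices, and the most specific overlapped feature wins:
5'UTR/3'UTR > exon > intron > 2-kb flank > intergenic, with gene-id
alphabetical order breaking ties, so annotation is deterministic. Flank
direction follows the gene's strand. GFF3 input is read through gffutils;
intervals are indexed with intervaltree.

## Simulator

The generator emulates the screen at the read level: a random genome with
planted perfect and mismatched sites (NGG PAMs, non-overlapping slots, +
strand), the designed library, and per-construct paired 150-nt reads over a
210-nt amplicon (the 170-nt oligo plus 20-nt primer flanks, so mates overlap
by ~90 nt).

Defaults and what they emulate:

- depth 2000 read pairs per construct per sample — the per-construct PCR
  coverage of a pooled screen;
- per-read 1% probability of a single 1-bp indel placed uniformly in the
  surrogate region — the 1–2% PCR/sequencing indel background observed in
  unedited cells; an option restricts placement outside N15–N21;
- 0.1% per-base substitution error;
- editing model: on-target sites draw true IF from U(80, 95)%; off-targets
  are inactive with probability 0.85, otherwise log-uniform between 0.5%
  and 50%; edits are indels at the N17/N18 cut (80% deletions, geometric
  length p = 0.5 capped at 6 and kept within N10–N25 so the read structure
  survives; 20% insertions of 1–4 random bases);
- 2% of constructs carry a synthesis-error allele at 3% template fraction in
  both samples — kept below the 4% MOCK-IF synthesis filter, since
  higher-fraction artifacts would remove the construct from analysis
  entirely. The artifact allele (a 1-bp deletion inside N15–N21) is chosen
  to differ from every deletion string the cut model can emit; an identical
  string would be unattributable by construction and the truth table could
  not score the subtraction step;
- 2% of constructs suffer 4-fold read dropout in the SpCas9 sample.

All randomness flows from one seed; identical configurations produce
byte-identical outputs. A counts-level companion
(`simulate_counts`) draws indel/total counts directly from the same
binomial sampling model for calibration studies at large site numbers,
where per-read simulation adds nothing to what is being measured.

What the simulator does **not** model — and hence what passing tests do not
show about real screens: lentiviral integration-position and chromatin
effects on cutting, non-uniform (homopolymer-biased) sequencing error,
microhomology-structured deletion spectra, PCR amplification bias between
alleles, and bulge-type off-target recognition.

## Problem sizes in the standard checks

The shipped verification uses problem sizes chosen to measure each property
cleanly: brute-force scanner comparisons on 50-kb genomes over 10 seeds;
Fisher enumeration over all ~250k tables with margins ≤ 30; null
calibration over 20 replicates of 500 unedited sites at depth 1000 (counts
level); read-level recovery and artifact-subtraction studies at depth 2000
over the spec of true rates 0.5–95%.

## Known limitations

- Enumeration is exact Hamming scanning; for genomes of hundreds of
  megabases a specialised index would be preferable.
- The structural filter is all-or-nothing: a single substitution in the
  113-nt invariant prefix discards the read, so high substitution error
  rates reduce usable depth (unbiasedly).
- When the same allele string can arise from both editing and background,
  subtraction attributes it entirely to background; this caps sensitivity
  at sites whose true edits coincide with recurrent artifacts.
- The Fisher test assumes reads are independent draws; PCR duplicates
  violate this and would make p-values anticonservative at extreme depth.
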