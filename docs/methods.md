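# Methods

This note documents the models, rules and defaults implemented in
`smmipkit`, the reasoning behind choices that were genuinely open, and what
the synthetic data does and does not establish about real specimens.

## Probe model and coordinates

An smMIP is modelled as a 75–80 nt oligo: extension + ligation arms (40–45
nt combined), a 30-nt linker, and a molecular tag (default 5 nt), capturing
a 112-nt target. All coordinates are 0-based half-open internally; VCF
output is 1-based. Arms are stored in read orientation (read 1 begins with
the ligation arm; read 2 begins with tag + extension arm). The sequencing
literature does not fix where the tag sits in the read; placing it at the
start of read 2, adjacent to the extension arm, is this package's
convention and is applied consistently by the simulator and the parser.
Probes designed as SNP-tolerant alternates (arms differing at a common SNP)
share an `allele_group`; assignment tries each alternate's arms exactly.

## Synthetic FFPE reads

The simulator draws, per probe, `templates_per_smmip` template molecules
from a tumor/normal mixture and amplifies each into a geometric number of
read pairs. The pieces, and what they emulate:

* **Tumor purity ρ** (default 0.65, a typical median neoplastic-cell
  fraction for FFPE ovarian carcinoma): templates come from tumor cells
  with probability proportional to allele count — 2ρ normally, ρ at LOH
  loci where tumor cells retain only the variant-bearing haplotype.
  Resulting expectations: heterozygous germline VAF = 0.5, rising to
  1/(2−ρ) under LOH; clonal somatic VAF = ρ/2, or ρ/(2−ρ) under LOH;
  subclonal somatic events scale with their cellular fraction.
* **Deamination** converts C→T on the captured strand of each template
  *before* amplification, so all duplicates of one template share the
  lesion but probes targeting the opposite strand never see it — exactly
  the signature the downstream filter keys on. The per-C per-template rate
  (default 0.01) is an order-of-magnitude choice; no quantitative rate is
  established for the assay, and tests that need callable artifacts raise
  it explicitly (0.05–0.08).
* **Jackpotting**: duplicate counts are geometric with mean
  `amplification_skew` (default 3). The phenomenon is qualitative in the
  assay description; geometric is the simplest heavy-tailed one-parameter
  model and makes raw-read allele fractions visibly biased until
  deduplication.
* **Sequencing error**: flat per-base substitution rate (default 0.001,
  Illumina-like). No indel error model and no base-quality model (all
  bases Q40); injected variants may still be indels.
* The captured insert is exactly the 112-nt target: smMIP inserts are
  arm-defined, so no fragment-length jitter is modelled.

Everything is driven by one seeded `numpy` generator; a run is fully
reproducible from (config, seed), and the truth set (expected VAFs,
deamination positions with strand, per-probe tag statistics) is recorded.

What passing simulated tests does **not** show: robustness to real FFPE
fragmentation (variable insert recovery), arm-hybridisation mismatches,
quality-score-correlated errors, or cross-sample contamination. The
simulator is a correctness harness for the pipeline's logic, not a
generative model of a sequencer.

## Consensus rules

The "30% consensus" discard rule is ambiguous between a per-position and a
per-read reading; both are implemented conservatively: a position keeps its
modal base only with ≥ 30% member support (ties or lower support → unknown),
and a member agreeing with the provisional consensus at < 30% of comparable
positions is discarded and the group re-evaluated. Consensus requires ≥ 2
members and every target position sequenced at least once (a
quality-tie-ambiguous position counts as sequenced). Within one read pair,
mates are merged per reference position toward the higher base quality;
disagreeing ties become unknown.

Fragments are projected onto the target by a Hamming fast path, falling
back to a gapped alignment (edlib, infix mode) capped at 20 edits — a
genuine fragment differs from its target by a few variants plus errors,
while an uncapped aligner would force-fit unrelated sequence with spurious
gaps and defeat the member-agreement rule. Finished consensus reads are
dropped above 15% mismatches (substitutions over known base calls) or
below 50% matching bases of the target span; gaps count as neither.

Indels are reported VCF-style, anchored and left-normalized (trim shared
trailing bases, extending left when an allele empties; then trim shared
leading bases).

## Calling and filters

Candidate variants need VAF ≥ 5% and ≥ 3 unique variant reads. Depth < 20
unique reads adds a `low_depth` filter and the position belongs to the
reported no-call regions; depth in [20, 30) is annotated `below_expected` —
how that band should be reported is not specified anywhere, so annotation
(rather than filtering) is this package's choice. The deamination discard
was a manual review step in practice; automating it needs a floor: with
opposite-strand depth ≥ 10 and zero opposite-strand variant reads a
C:G>T:A call is filtered `deamination`; below the floor it is flagged
`unresolvable_strand` instead of being silently passed or discarded. The
homopolymer rule is generalised from runs of eight adenines to ≥ 8
identical A *or* T bases (the annotation's strand is a reporting
convention); it applies to indel calls. The read-end rule fires when a
variant at the first/last base of its sole supporting probe's target is
absent from an overlapping probe covering the base at depth ≥ 10.

## LOH

Informative sites are known-germline calls with 5% ≤ VAF ≤ 95%; a locus
with mean major VAF > 60% is LOH, no sites is uninformative. The locus
default is the panel's per-gene footprint (configurable flank). Samples
with annotated neoplastic fraction < 32% carry a low-purity caveat:
at ρ < 0.32 the expected LOH major VAF 1/(2−ρ) < 0.60 sits below the
threshold, so a negative call is weak evidence.

## CNV and MLPA

Unique-read counts (samples × probes) are normalized in three steps —
sample total, probe cohort mean (so each probe's cohort average is 1),
per-exon average — making the procedure invariant to per-sample scaling
and sample order. Deletion/duplication thresholds 0.7/1.3 are MLPA-style
conventions (the single-copy expectation is 0.5 germline, 1 − ρ/2
somatic); the coverage data alone fixes no threshold. Samples under a
configurable total-count floor (default 1,000 unique reads) are excluded
from the cohort and reported, since no eligibility floor is established
for the assay. A warning is raised for exons represented by a single
probe. MLPA peak tables use the same population normalization with the
sample *mean* (peaks, not counts). MS-MLPA normalizes each digest within
sample by digestion-resistant reference probes and reports
digested/undigested signal per methylation-sensitive probe; the 0.15
methylated-fraction threshold is a kit convention, configurable, and the
binary calls in the field are reported without a published cut.

## QC

`detection_probability(n, p)` is the exact binomial tail with the
effective threshold k* = max(3, ⌈0.05·n⌉); it assumes unique reads are
independent allele draws and takes no purity correction (purity enters
upstream through the expected VAF). The sensitivity CI is Wald by default
— it reproduces the interval that the confusion counts imply at the
printed rounding — with Clopper–Pearson as an option.

## Problem sizes in the test suite

The end-to-end acceptance property runs 200 seeded replicates of a
20-probe, 5-kb, 200-templates-per-probe sample (≈12,000 read pairs each);
the deduplication oracle covers 50 random small configurations; LOH
recovery uses 300 templates per probe at ρ ∈ {0.5, 0.7, 0.9}; the CNV
cohort is 20 samples × 48 probes (24 exons). These sizes give per-position
unique depths of 200–600, comfortably inside the regime the thresholds
were designed for, while keeping the full suite fast.

## Known limitations

Tumor-only germline/somatic separation relies on the supplied germline
database (no matched-normal subtraction). No structural variants beyond
exon-level ratios; no purity estimation from data; single-contig panels in
the file-based pipeline; arm matching is exact (a documented extension
point — arm-SNP tolerance is handled by alternate probes, not fuzzy
matching).
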