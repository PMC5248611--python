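# smmipkit

Targeted tumor sequencing of *BRCA1*/*BRCA2*-style panels on FFPE-grade DNA
with single-molecule molecular inversion probes (smMIPs): molecular-tag
(UMI) consensus deduplication, strand-aware FFPE artifact filtering,
variant and loss-of-heterozygosity (LOH) calling, coverage-based exon
copy-number detection, MLPA/MS-MLPA normalization and QC — plus a synthetic
FFPE read simulator so the whole stack is testable end to end without any
external data.

## Who this is for

Formalin-fixed, paraffin-embedded (FFPE) tumor DNA is fragmented, carries
cytosine-deamination lesions (C→T on one strand), and often contains few
amplifiable template molecules, so PCR "jackpotting" inflates apparent
allele fractions. smMIP capture addresses all three by design, and this
package implements the corresponding analysis:

* each probe carries a random **molecular tag** (5 nt → 4⁵ = 1,024
  distinguishable templates per probe), so PCR duplicates collapse into
  **unique (consensus) reads** and depth counts template molecules, not
  amplification luck;
* every target region is **double-tiled** — captured by independent probes
  on the plus and the minus strand — so a true variant appears on both
  strands while a deamination artifact, which lives on one strand of the
  template, cannot.

## The model in brief

For a probe with target interval of 112 nt, read pairs are assigned by
exact arm match, grouped by (probe, tag), and collapsed: ≥ 2 tagged read
pairs per consensus, per-position modal base with ≥ 30% support, members
agreeing < 30% discarded, consensus dropped at > 15% mismatches or < 50%
matching bases against the reference.

Variants are called at **VAF ≥ 5% and ≥ 3 unique variant reads**, with 20
unique reads as the minimal and 30 as the expected depth. With unique reads
as independent draws of the allele at fraction *p*, the detection
probability at depth *n* is the exact binomial tail

    P(called) = P(X ≥ k*),  X ~ Binomial(n, p),  k* = max(3, ⌈0.05 n⌉)

which gives ≥ 95% detection at 30×/20% VAF and 20×/30% VAF.

C:G>T:A calls absent from the opposite-strand probes are filtered as
deamination; indels in A₈ homopolymers and single-probe read-end calls are
filtered as context artifacts. LOH is called when the mean **major allele
fraction** of heterozygous germline SNPs (5% ≤ VAF ≤ 95%) exceeds 60%; at
tumor purity ρ, loss of the wild-type allele drives it to 1/(2−ρ). Exon
CNVs come from population-normalized per-probe unique-read counts (sample
total → probe cohort mean → per-exon average), where a heterozygous
deletion reads out near 1 − ρ/2.

## Worked example

```bash
python examples/simulate_and_call.py
```

```
simulated 11999 read pairs from 200 templates/probe (5622 deamination lesions injected)
assigned 11516/11999 pairs -> 3648 tag groups -> 2488 consensus (unique) reads

  pos  ref>alt  depth    VAF  status
   87      C>T    248   5.2%  deamination
  300      A>G    255  49.0%  PASS
  650      C>G    249  26.5%  PASS
  909      C>T    251   5.2%  deamination
```

The two PASS calls are the injected truth: the germline heterozygous SNV
near 50% VAF and the clonal somatic SNV near ρ/2 ≈ 32% at purity 65%. The
C>T candidates sat on one targeted strand only — the opposite-strand probes
covered the same bases ~125× with zero variant reads — and were filtered as
FFPE deamination artifacts. Other narrative examples: `loh_analysis.py`
(major-VAF shift under LOH), `exon_cnv.py` (exon-22 deletion at ratio 0.5),
`mlpa_msmlpa.py`, `detection_power.py`.

A thin CLI wraps the same library functions:

```bash
smmipkit simulate sim.yaml --out-prefix sample1
smmipkit call --reference ref.fasta --panel panel.tsv \
    --r1 sample1.R1.fastq --r2 sample1.R2.fastq --out-prefix sample1
smmipkit cnv --counts cohort_counts.tsv --exon-map exons.tsv --out-prefix cohort
```

## Read layout convention

Probe arms are stored as the sequences expected in the sequenced reads:
read 2 starts with the 5-nt molecular tag, then the extension arm, then the
captured target on the probe's targeted strand; read 1 starts with the
ligation arm followed by the reverse complement of the target. The
simulator writes this layout and the read processor parses it; panel TSV
columns are documented in `smmipkit.panel`.

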