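"""End-to-end orchestration: reads -> consensus -> calls -> reports.

`call_sample` is the in-memory core used by the library API and tests;
`run_pipeline` is the file-based wrapper behind the command line, producing
a VCF, a no-call region TSV, a consensus table and a QC JSON, with
per-stage record counts logged to stderr.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict

import numpy as np

from . import calling, loh, qc, reads as rp
from .calling import GermlineDatabase, Pileup, VariantCall
from .panel import Panel, load_panel, target_regions
from .reads import ConsensusRead, ProcessingStats

logger = logging.getLogger("smmipkit")


@dataclass
class CallingParams:
    """All calling-stage thresholds, defaulting to the validated settings."""

    min_vaf: float = 0.05
    min_var_reads: int = 3
    min_depth: int = 20
    expected_depth: int = 30
    opposite_strand_min_depth: int = 10
    min_overlap_depth: int = 10
    loh_major_vaf: float = 0.60

    def __post_init__(self):
        if not 0 < self.min_vaf <= 1:
            raise ValueError("min_vaf must be in (0, 1]")
        if self.min_var_reads < 1 or self.min_depth < 1:
            raise ValueError("read/depth thresholds must be positive")


@dataclass
class SampleResult:
    consensus: list[ConsensusRead]
    processing: ProcessingStats
    pile: Pileup
    calls: list[VariantCall]
    nocall: list[tuple[int, int]]


def call_sample(
    read_pairs,
    panel: Panel,
    reference: str,
    params: CallingParams | None = None,
    germline_db: GermlineDatabase | None = None,
) -> SampleResult:
    """Run read processing, pileup, calling and artifact filters in memory."""
    params = params or CallingParams()
    consensus, stats = rp.process_read_pairs(read_pairs, panel, reference)
    pile = calling.pileup(consensus, reference)
    calls = calling.call_variants(
        pile,
        min_vaf=params.min_vaf,
        min_var_reads=params.min_var_reads,
        min_depth=params.min_depth,
        expected_depth=params.expected_depth,
    )
    calling.apply_artifact_filters(
        calls,
        reference,
        panel,
        pile.smmip_kept,
        opposite_strand_min_depth=params.opposite_strand_min_depth,
        min_overlap_depth=params.min_overlap_depth,
    )
    if germline_db is not None:
        calling.annotate_known_germline(calls, germline_db)
    nocall = calling.nocall_regions(pile, params.min_depth) if consensus else []
    logger.info(
        "pairs=%d assigned=%d groups=%d consensus_kept=%d calls=%d pass=%d",
        stats.total_pairs, stats.assigned, stats.groups, stats.kept,
        len(calls), sum(c.is_pass for c in calls),
    )
    return SampleResult(consensus, stats, pile, calls, nocall)


@dataclass
class RunConfig:
    reference_fasta: str
    panel_tsv: str
    fastq_r1: str
    fastq_r2: str
    out_prefix: str
    germline_db: str | None = None
    params: CallingParams = field(default_factory=CallingParams)
    loh_flank: int = 0
    tumor_purity: float | None = None
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """File-in, file-out pipeline; returns a dict of written artifact paths."""
    from .simulate import read_fasta, read_fastq_pairs

    ref_by_contig = read_fasta(config.reference_fasta)
    panel = load_panel(config.panel_tsv)
    contigs = {m.contig for m in panel}
    if len(contigs) != 1:
        raise ValueError("the pipeline handles a single-contig panel")
    contig = next(iter(contigs))
    if contig not in ref_by_contig:
        raise ValueError(f"panel contig {contig!r} absent from the reference FASTA")
    reference = ref_by_contig[contig]
    pairs = read_fastq_pairs(config.fastq_r1, config.fastq_r2)
    db = GermlineDatabase.from_tsv(config.germline_db) if config.germline_db else None

    result = call_sample(pairs, panel, reference, config.params, germline_db=db)

    prefix = config.out_prefix
    artifacts = {}
    calling.write_vcf(result.calls, prefix + ".vcf", reference_id=contig)
    artifacts["vcf"] = prefix + ".vcf"
    calling.write_nocall_tsv(result.nocall, prefix + ".nocall.tsv", contig=contig)
    artifacts["nocall"] = prefix + ".nocall.tsv"
    rp.consensus_to_tsv(result.consensus, prefix + ".consensus.tsv")
    artifacts["consensus"] = prefix + ".consensus.tsv"

    # per-locus LOH over the panel's target genes
    loh_calls = []
    genes = sorted({m.target_name for m in panel})
    for gene in genes:
        gene_mips = [m for m in panel if m.target_name == gene]
        lo = min(m.target_start for m in gene_mips) - config.loh_flank
        hi = max(m.target_end for m in gene_mips) + config.loh_flank
        sites = loh.select_informative(result.calls, locus=(lo, hi))
        loh_calls.append(
            loh.call_loh(
                sites, locus=gene,
                threshold=config.params.loh_major_vaf,
                tumor_purity=config.tumor_purity,
            )
        )
    loh.write_loh_tsv(loh_calls, prefix + ".loh.tsv")
    artifacts["loh"] = prefix + ".loh.tsv"

    # QC report over the targeted footprint
    if result.consensus:
        depth = result.pile.depth_plus + result.pile.depth_minus
        mask = np.zeros_like(depth, dtype=bool)
        for _, s, e in target_regions(panel):
            mask[max(0, s - result.pile.start) : max(0, e - result.pile.start)] = True
        cov = qc.coverage_summary(depth[mask]) if mask.any() else None
    else:
        cov = None
    report = {
        "seed": config.seed,
        "processing": asdict(result.processing),
        "n_calls": len(result.calls),
        "n_pass": sum(c.is_pass for c in result.calls),
        "filters": {
            f: sum(f in c.filters for c in result.calls)
            for f in calling.FILTER_VOCAB
        },
        "coverage": None
        if cov is None
        else {
            "n_bases": cov.n_bases,
            "mean_depth": cov.mean_depth,
            "median_depth": cov.median_depth,
            "fraction_at_least": {str(k): v for k, v in cov.fraction_at_least.items()},
        },
        "detection_probability": qc.detection_probability_table(
            [20, 30, 50, 100], [0.05, 0.10, 0.20, 0.30],
            min_var_reads=config.params.min_var_reads,
            min_vaf=config.params.min_vaf,
        ),
    }
    with open(prefix + ".qc.json", "w") as fh:
        json.dump(report, fh, indent=1)
    artifacts["qc"] = prefix + ".qc.json"
    return artifacts


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
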