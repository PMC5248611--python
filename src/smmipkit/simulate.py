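"""Synthetic FFPE-grade smMIP sequencing reads with a known truth set.

The generator emulates what makes formalin-fixed, paraffin-embedded (FFPE)
tumor sequencing hard, so that every downstream stage (tag deduplication,
artifact filtering, variant/LOH/CNV calling) can be tested against ground
truth without external data:

* a toy diploid genome carrying germline variants (het/hom) and somatic
  variants at a given cellular fraction;
* tumor purity: templates are drawn from a mixture of tumor and normal
  cells; at loss-of-heterozygosity (LOH) loci the tumor cells have lost the
  wild-type allele, so a heterozygous variant's expected allele fraction
  rises to 1/(2 - purity);
* cytosine deamination: C -> T flips applied to the captured strand of each
  template *before* amplification, so the artifact is strand-confined (all
  PCR duplicates of one template share it, but probes targeting the opposite
  strand never see it) — exactly the signature the deamination filter keys on;
* PCR jackpotting: each template is amplified into a geometric number of
  read pairs, so raw read counts are a biased estimate of template counts
  until deduplicated via the molecular tag;
* flat per-base substitution sequencing error.

Read layout convention (the probe anatomy fixes the captured insert; the
read layout is this package's documented convention):

    amplicon (read-2 orientation) = tag + extension_arm + S + revcomp(ligation_arm)

where S is the 112-nt captured target on the probe's targeted strand.
Read 2 is the first 151 nt of the amplicon (it therefore starts with the
5-nt molecular tag followed by the extension arm); read 1 is the first
151 nt of its reverse complement (it starts with the ligation arm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dna import BASES, revcomp
from .panel import Panel, SmMIP, LINKER_LENGTH
from .reads import ReadPair


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass(frozen=True)
class GermlineVariant:
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het|hom, got {self.zygosity!r}")


@dataclass(frozen=True)
class SomaticVariant:
    pos: int
    ref: str
    alt: str
    cellular_fraction: float = 1.0  # fraction of tumor cells carrying it

    def __post_init__(self):
        if not 0.0 <= self.cellular_fraction <= 1.0:
            raise ValueError("cellular_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of one simulated capture of one sample."""

    panel: Panel
    seed: int = 0
    reference: str | None = None       # explicit sequence; must match panel arms
    reference_length: int = 5000       # used only when reference is None
    germline_variants: list[GermlineVariant] = field(default_factory=list)
    somatic_variants: list[SomaticVariant] = field(default_factory=list)
    tumor_purity: float = 0.65         # median neoplastic-cell fraction of FFPE OCs
    loh_loci: list[tuple[int, int]] = field(default_factory=list)
    templates_per_smmip: int = 200
    amplification_skew: float = 3.0    # geometric mean duplicates per template
    deamination_rate: float = 0.01     # per C per template, captured strand
    sequencing_error_rate: float = 0.001
    read_length: int = 151

    def __post_init__(self):
        for name in ("tumor_purity", "deamination_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.templates_per_smmip < 0:
            raise ValueError("templates_per_smmip must be >= 0")
        if self.amplification_skew < 1.0:
            raise ValueError("amplification_skew must be >= 1 (mean duplicates)")


@dataclass
class TruthVariant:
    pos: int
    ref: str
    alt: str
    kind: str                      # "germline" | "somatic"
    zygosity: str | None
    cellular_fraction: float | None
    loh: bool
    expected_vaf: float
    capturable: bool


@dataclass
class SmMIPTruth:
    templates: int          # template molecules drawn
    distinct_tags: int      # distinct molecular tags observed
    tags_ge2: int           # distinct tags with >= 2 read pairs (dedup oracle)


@dataclass
class TruthSet:
    """Ground truth of one simulation, for recovery tests and reports."""

    variants: list[TruthVariant]
    deamination_events: list[tuple[int, str]]  # (ref pos, captured strand)
    smmip_stats: dict[str, SmMIPTruth]
    loh_loci: list[tuple[int, int]]
    tumor_purity: float
    seed: int

    def expected_vaf(self, pos: int, alt: str) -> float:
        for v in self.variants:
            if v.pos == pos and v.alt == alt:
                return v.expected_vaf
        raise KeyError((pos, alt))

    def deamination_positions(self) -> set[tuple[int, str]]:
        return set(self.deamination_events)


def expected_vaf(
    kind: str,
    purity: float,
    zygosity: str | None = None,
    cellular_fraction: float | None = None,
    loh: bool = False,
) -> float:
    """Expected variant allele fraction under the tumor/normal mixture.

    Heterozygous germline variant: 1/2 without LOH; with loss of the
    wild-type allele in tumor cells it rises to 1/(2 - purity).  A somatic
    variant at cellular fraction c contributes purity*c alt copies out of
    2 - (purity if LOH else 0) total copies per cell equivalent.
    """
    rho = purity
    if kind == "germline":
        if zygosity == "hom":
            return 1.0
        return 1.0 / (2.0 - rho) if loh else 0.5
    c = 1.0 if cellular_fraction is None else cellular_fraction
    return rho * c / (2.0 - rho) if loh else rho * c / 2.0


# ---------------------------------------------------------------------------
# reference and toy panel construction


def make_reference(length: int, seed: int) -> str:
    """Deterministic uniform-base reference sequence."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def write_fasta(sequence: str, path, name: str = "ref") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


_LINKER = ("CTTCAGCTTCCCGATATCCGACGGTAGTGT")  # constant backbone linker, 30 nt
assert len(_LINKER) == LINKER_LENGTH


def design_tiled_panel(
    reference: str,
    n_smmips: int = 20,
    contig: str = "ref",
    target_name: str = "toy_gene",
    start: int = 60,
    step: int | None = None,
    ext_len: int = 21,
    lig_len: int = 22,
    tag_length: int = 5,
    reference_id: str = "ref",
) -> Panel:
    """Design a toy double-tiled panel whose arms match the given reference.

    Probes alternate strand in pairs: probes 2k and 2k+1 share the same
    112-nt target but capture opposite strands, so every targeted base is
    double-tiled and strand-concordance filters can operate.  ``step`` moves
    each pair along the reference (default: targets abut).
    """
    span = 112
    if step is None:
        step = span
    smmips = []
    pos = start
    for i in range(n_smmips):
        strand = "+" if i % 2 == 0 else "-"
        s, e = pos, pos + span
        if e + lig_len + ext_len > len(reference):
            raise ValueError("reference too short for the requested panel")
        if strand == "+":
            ext = reference[s - ext_len : s]
            lig = revcomp(reference[e : e + lig_len])
        else:
            ext = revcomp(reference[e : e + ext_len])
            lig = reference[s - lig_len : s]
        smmips.append(
            SmMIP(
                id=f"mip{i:03d}{strand}",
                target_name=target_name,
                contig=contig,
                target_start=s,
                target_end=e,
                targeted_strand=strand,
                extension_arm=ext,
                ligation_arm=lig,
                linker=_LINKER,
                tag_length=tag_length,
            )
        )
        if i % 2 == 1:
            pos += step
    return Panel(smmips=smmips, reference_id=reference_id)


# ---------------------------------------------------------------------------
# read simulation


def _apply_variants(
    window: str, start: int, variants: list
) -> tuple[list[str], list[int | None]]:
    """Apply non-overlapping VCF-style variants to reference window.

    Returns parallel per-base lists: the base and the reference position it
    derives from (None for inserted bases).  Variants must lie fully inside
    the window and be sorted by position.
    """
    bases: list[str] = []
    refpos: list[int | None] = []
    cursor = start
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos < cursor:
            raise ValueError(f"overlapping variants at {v.pos}")
        for j in range(cursor, v.pos):
            bases.append(window[j - start])
            refpos.append(j)
        # anchor-preserving substitution/indel
        for k, b in enumerate(v.alt):
            bases.append(b)
            refpos.append(v.pos + k if k < len(v.ref) else None)
        cursor = v.pos + len(v.ref)
    for j in range(cursor, start + len(window)):
        bases.append(window[j - start])
        refpos.append(j)
    return bases, refpos


def simulate_reads(config: SimulationConfig) -> tuple[list[ReadPair], TruthSet]:
    """Draw template molecules per smMIP and amplify them into read pairs.

    Per template: a cell compartment (tumor vs normal, allele-count
    weighted), a haplotype, a molecular tag, strand-confined deamination,
    then a geometric number of duplicate read pairs with flat sequencing
    error.  Returns the reads plus the :class:`TruthSet` recording expected
    VAFs, injected deamination positions and per-smMIP tag statistics.
    """
    rng = np.random.default_rng(config.seed)
    reference = config.reference
    if reference is None:
        reference = make_reference(config.reference_length, config.seed)
    panel = config.panel
    rho = config.tumor_purity
    L = config.read_length

    # capturability bookkeeping
    def capturing_mips(v) -> list[SmMIP]:
        return [
            m
            for m in panel
            if m.target_start <= v.pos and v.pos + len(v.ref) <= m.target_end
        ]

    def in_loh(pos: int) -> bool:
        return any(s <= pos < e for s, e in config.loh_loci)

    truth_variants: list[TruthVariant] = []
    for v in config.germline_variants:
        cap = bool(capturing_mips(v))
        if not cap:
            warnings.warn(f"germline variant at {v.pos} outside every target")
        truth_variants.append(
            TruthVariant(
                v.pos, v.ref, v.alt, "germline", v.zygosity, None,
                in_loh(v.pos),
                expected_vaf("germline", rho, zygosity=v.zygosity, loh=in_loh(v.pos)),
                cap,
            )
        )
    for v in config.somatic_variants:
        cap = bool(capturing_mips(v))
        if not cap:
            warnings.warn(f"somatic variant at {v.pos} outside every target")
        truth_variants.append(
            TruthVariant(
                v.pos, v.ref, v.alt, "somatic", None, v.cellular_fraction,
                in_loh(v.pos),
                expected_vaf("somatic", rho, cellular_fraction=v.cellular_fraction,
                             loh=in_loh(v.pos)),
                cap,
            )
        )

    reads: list[ReadPair] = []
    deam_events: list[tuple[int, str]] = []
    smmip_stats: dict[str, SmMIPTruth] = {}
    base_arr = np.array(list(BASES))
    err = config.sequencing_error_rate

    def sequencing_errors(seq: str, n_err: int) -> str:
        if n_err == 0:
            return seq
        positions = rng.choice(len(seq), size=n_err, replace=False)
        out = list(seq)
        for p in positions:
            choices = [b for b in BASES if b != out[p]]
            out[p] = choices[rng.integers(0, 3)]
        return "".join(out)

    for m in panel:
        s, e = m.target_start, m.target_end
        loh_here = any(not (e <= ls or le <= s) for ls, le in config.loh_loci)
        w_tumor = rho * (1.0 if loh_here else 2.0)
        w_normal = (1.0 - rho) * 2.0
        p_tumor = w_tumor / (w_tumor + w_normal) if (w_tumor + w_normal) > 0 else 0.0
        germ_here = [v for v in config.germline_variants if m in capturing_mips(v)]
        som_here = [v for v in config.somatic_variants if m in capturing_mips(v)]
        window = reference[s:e]
        tag_counts: dict[str, int] = {}

        T = config.templates_per_smmip
        is_tumor = rng.random(T) < p_tumor
        haps = rng.integers(0, 2, size=T)
        if loh_here:
            haps[is_tumor] = 1  # wild-type allele (hap 0) lost in tumor cells
        dup_counts = rng.geometric(1.0 / config.amplification_skew, size=T)
        tag_ints = rng.integers(0, 4, size=(T, m.tag_length))
        n_errs = rng.binomial(L, err, size=(T, int(dup_counts.max()) if T else 0, 2))

        for t in range(T):
            tumor, hap = bool(is_tumor[t]), int(haps[t])
            chosen = [v for v in germ_here if v.zygosity == "hom" or hap == 1]
            if tumor and hap == 1:
                chosen += [
                    v for v in som_here if rng.random() < v.cellular_fraction
                ]
            if chosen:
                bases, refpos = _apply_variants(window, s, chosen)
            else:
                bases, refpos = list(window), list(range(s, e))

            if m.targeted_strand == "-":
                bases = [b.translate(_COMP) for b in reversed(bases)]
                refpos = list(reversed(refpos))

            # strand-confined deamination, pre-amplification
            if config.deamination_rate > 0:
                c_idx = [i for i, b in enumerate(bases) if b == "C"]
                if c_idx:
                    flips = rng.random(len(c_idx)) < config.deamination_rate
                    for i, flip in zip(c_idx, flips):
                        if flip:
                            bases[i] = "T"
                            if refpos[i] is not None:
                                deam_events.append((refpos[i], m.targeted_strand))

            S = "".join(bases)
            tag = "".join(base_arr[tag_ints[t]])
            amplicon = (tag + m.extension_arm + S + revcomp(m.ligation_arm))[:L]
            amplicon_rc = revcomp(tag + m.extension_arm + S + revcomp(m.ligation_arm))[:L]
            k = int(dup_counts[t])
            tag_counts[tag] = tag_counts.get(tag, 0) + k
            q = "I" * L
            for d in range(k):
                r2 = sequencing_errors(amplicon, int(n_errs[t, d, 1]))
                r1 = sequencing_errors(amplicon_rc, int(n_errs[t, d, 0]))
                reads.append(
                    ReadPair(name=f"{m.id}:{tag}:{t}:{d}", r1=r1, q1=q, r2=r2, q2=q)
                )
        smmip_stats[m.id] = SmMIPTruth(
            templates=config.templates_per_smmip,
            distinct_tags=len(tag_counts),
            tags_ge2=sum(1 for n in tag_counts.values() if n >= 2),
        )

    # shuffle so downstream never relies on generation order
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = TruthSet(
        variants=truth_variants,
        deamination_events=deam_events,
        smmip_stats=smmip_stats,
        loh_loci=list(config.loh_loci),
        tumor_purity=rho,
        seed=config.seed,
    )
    return reads, truth


_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_count_matrix(
    n_samples: int,
    smmip_exon: dict[str, str],
    mean_unique_reads: float = 250.0,
    deletions: dict[str, tuple[str, float]] | None = None,
    sample_scale_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
):
    """Cohort-level unique-read counts per smMIP, for the CNV stage.

    Unique-read counts scale with the number of captured template molecules,
    so an exon present at copy ratio r in a sample yields counts scaled by r
    (1 - rho/2 for a heterozygous deletion at tumor purity rho).  Counts are
    Poisson around a per-sample library-size factor times a per-probe
    efficiency; ``deletions`` maps sample -> (exon, copy_ratio).

    Returns a pandas DataFrame (samples x smMIPs).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    smmips = list(smmip_exon)
    deletions = deletions or {}
    efficiency = rng.uniform(0.5, 1.5, size=len(smmips))
    samples = [f"S{i:03d}" for i in range(n_samples)]
    rows = []
    for sample in samples:
        scale = rng.uniform(*sample_scale_range)
        lam = mean_unique_reads * scale * efficiency
        if sample in deletions:
            exon, ratio = deletions[sample]
            mask = np.array([smmip_exon[m] == exon for m in smmips])
            lam = np.where(mask, lam * ratio, lam)
        rows.append(rng.poisson(lam))
    return pd.DataFrame(rows, index=samples, columns=smmips)


# ---------------------------------------------------------------------------
# I/O


def write_fastq(reads: list[ReadPair], path1, path2) -> None:
    """Write paired reads as two plain FASTQ files (R1, R2)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.name}/1\n{r.r1}\n+\n{r.q1}\n")
            f2.write(f"@{r.name}/2\n{r.r2}\n+\n{r.q2}\n")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    from Bio import SeqIO

    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq"), strict=True
    ):
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        name = rec1.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(name=name, r1=str(rec1.seq), q1=q1, r2=str(rec2.seq), q2=q2))
    return pairs


def write_truth(truth: TruthSet, prefix) -> None:
    """Serialise a TruthSet as TSVs + a VCF of the injected variants."""
    prefix = str(prefix)
    with open(prefix + ".variants.tsv", "w") as fh:
        fh.write("pos\tref\talt\tkind\tzygosity\tcellular_fraction\tloh\texpected_vaf\tcapturable\n")
        for v in truth.variants:
            fh.write(
                f"{v.pos}\t{v.ref}\t{v.alt}\t{v.kind}\t{v.zygosity or '.'}\t"
                f"{'.' if v.cellular_fraction is None else repr(v.cellular_fraction)}\t"
                f"{int(v.loh)}\t{v.expected_vaf!r}\t{int(v.capturable)}\n"
            )
    with open(prefix + ".deamination.tsv", "w") as fh:
        fh.write("pos\tstrand\n")
        for pos, strand in truth.deamination_events:
            fh.write(f"{pos}\t{strand}\n")
    with open(prefix + ".smmips.tsv", "w") as fh:
        fh.write("smmip_id\ttemplates\tdistinct_tags\ttags_ge2\n")
        for mid, st in truth.smmip_stats.items():
            fh.write(f"{mid}\t{st.templates}\t{st.distinct_tags}\t{st.tags_ge2}\n")
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(
            {
                "tumor_purity": truth.tumor_purity,
                "seed": truth.seed,
                "loh_loci": [list(x) for x in truth.loh_loci],
            },
            fh,
            indent=1,
        )
    with open(prefix + ".vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=smmipkit-simulator seed={truth.seed}\n")
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="germline or somatic">\n')
        fh.write('##INFO=<ID=EVAF,Number=1,Type=Float,Description="expected VAF">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(truth.variants, key=lambda v: v.pos):
            fh.write(
                f"ref\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"KIND={v.kind};EVAF={v.expected_vaf:.6g}\n"
            )


def load_truth(prefix) -> TruthSet:
    prefix = str(prefix)
    variants = []
    with open(prefix + ".variants.tsv") as fh:
        next(fh)
        for line in fh:
            p, r, a, kind, zyg, cf, loh, ev, cap = line.rstrip("\n").split("\t")
            variants.append(
                TruthVariant(
                    int(p), r, a, kind,
                    None if zyg == "." else zyg,
                    None if cf == "." else float(cf),
                    bool(int(loh)), float(ev), bool(int(cap)),
                )
            )
    deam = []
    with open(prefix + ".deamination.tsv") as fh:
        next(fh)
        for line in fh:
            p, strand = line.rstrip("\n").split("\t")
            deam.append((int(p), strand))
    stats = {}
    with open(prefix + ".smmips.tsv") as fh:
        next(fh)
        for line in fh:
            mid, t, d, g = line.rstrip("\n").split("\t")
            stats[mid] = SmMIPTruth(int(t), int(d), int(g))
    with open(prefix + ".meta.json") as fh:
        meta = json.load(fh)
    return TruthSet(
        variants=variants,
        deamination_events=deam,
        smmip_stats=stats,
        loh_loci=[tuple(x) for x in meta["loh_loci"]],
        tumor_purity=meta["tumor_purity"],
        seed=meta["seed"],
    )
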