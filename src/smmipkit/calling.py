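"""Pileup of consensus reads, variant calling and FFPE artifact filters.

Calling thresholds follow the validated settings for smMIP tumor
sequencing: a variant is called when it is observed in at least 5% of the
unique (consensus) reads and at least 3 unique variant reads support it;
positions with fewer than 20 unique reads are a no-call zone, and depth
between 20 and 30 is annotated as below the expected depth.

Artifact filters:

* deamination — C:G>T:A transitions supported on only one targeted strand
  while the probes covering the opposite strand see none, the signature of
  formalin-induced cytosine deamination (strand-confined by mechanism).  If
  the opposite strand has insufficient depth to judge, the call is flagged
  ``unresolvable_strand`` instead of silently passed or discarded.
* homopolymer_A8 — indel calls inside runs of >= 8 A (or T) residues.
* read_end — calls at the first/last base of a single probe's target that
  are absent from overlapping probes covering the same base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dna import DEL, UNKNOWN, encode
from .panel import Panel
from .reads import ConsensusRead

FILTER_VOCAB = (
    "low_depth",
    "deamination",
    "unresolvable_strand",
    "homopolymer_A8",
    "read_end",
)


@dataclass
class PileupColumn:
    contig: str
    pos: int
    counts_plus: Counter   # base / '-' counts among plus-strand probes' reads
    counts_minus: Counter

    @property
    def unique_depth(self) -> int:
        return sum(self.counts_plus.values()) + sum(self.counts_minus.values())


@dataclass
class _EventCounts:
    plus: int = 0
    minus: int = 0
    smmips: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.plus + self.minus


@dataclass
class Pileup:
    contig: str
    start: int
    end: int
    depth_plus: np.ndarray
    depth_minus: np.ndarray
    events: dict[tuple[int, str, str], _EventCounts]
    smmip_kept: Counter           # kept consensus reads per smMIP
    reads: list[ConsensusRead]

    def depth(self, pos: int) -> int:
        i = pos - self.start
        return int(self.depth_plus[i] + self.depth_minus[i])

    def column(self, pos: int) -> PileupColumn:
        """Per-strand base counts at one position (hand-checkable view)."""
        cp: Counter = Counter()
        cm: Counter = Counter()
        sym = "ACGT-"
        for r in self.reads:
            if not (r.start <= pos < r.end):
                continue
            code = int(r.codes[pos - r.start])
            if code == UNKNOWN:
                continue
            (cp if r.strand == "+" else cm)[sym[code]] += 1
        return PileupColumn(self.contig, pos, cp, cm)


def left_normalize(
    pos: int, ref: str, alt: str, reference: str
) -> tuple[int, str, str]:
    """Left-align an anchored VCF-style indel against the reference.

    Standard normalization: trim shared trailing bases (extending left with
    the previous reference base whenever an allele would empty), then trim
    shared leading bases.
    """
    while ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
        if (not ref or not alt) and pos > 0:
            pos -= 1
            prev = reference[pos]
            ref, alt = prev + ref, prev + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def pileup(
    consensus_reads: list[ConsensusRead],
    reference: str,
    contig: str = "ref",
    regions: list[tuple[int, int]] | None = None,
) -> Pileup:
    """Per-position per-strand unique-read depth plus non-reference events.

    Substitutions are keyed at their position; indels are left-aligned to
    their VCF-style anchor.  Unknown consensus positions do not contribute
    depth.
    """
    if regions:
        start = min(s for s, _ in regions)
        end = max(e for _, e in regions)
    elif consensus_reads:
        start = min(r.start for r in consensus_reads)
        end = max(r.end for r in consensus_reads)
    else:
        start = end = 0
    n = end - start
    depth_plus = np.zeros(n, dtype=np.int32)
    depth_minus = np.zeros(n, dtype=np.int32)
    events: dict[tuple[int, str, str], _EventCounts] = {}
    smmip_kept: Counter = Counter()
    ref_codes = encode(reference[start:end])

    def bump(pos, refa, alta, strand, smmip_id):
        key = (pos, refa, alta)
        ev = events.get(key)
        if ev is None:
            ev = events[key] = _EventCounts()
        if strand == "+":
            ev.plus += 1
        else:
            ev.minus += 1
        ev.smmips[smmip_id] += 1

    for r in consensus_reads:
        smmip_kept[r.smmip_id] += 1
        lo, hi = r.start - start, r.end - start
        darr = depth_plus if r.strand == "+" else depth_minus
        darr_slice = darr[lo:hi]
        darr_slice += 1
        codes = r.codes
        unknown = codes == UNKNOWN
        if unknown.any():
            darr_slice[unknown] -= 1
        rref = ref_codes[lo:hi]
        # substitutions
        subs = (codes < DEL) & (codes != rref)
        if subs.any():
            for i in np.flatnonzero(subs):
                pos = r.start + int(i)
                bump(pos, reference[pos], "ACGT"[codes[i]], r.strand, r.smmip_id)
        # deletion runs, anchored one base left
        dels = codes == DEL
        if dels.any():
            idx = np.flatnonzero(dels)
            run_start = [int(idx[0])]
            run_end = []
            for a, b in zip(idx[:-1], idx[1:]):
                if b != a + 1:
                    run_end.append(int(a) + 1)
                    run_start.append(int(b))
            run_end.append(int(idx[-1]) + 1)
            for rs, re_ in zip(run_start, run_end):
                p0 = r.start + rs
                if p0 == 0:
                    continue  # no left anchor available
                a = p0 - 1
                refa = reference[a : r.start + re_]
                pos, refa, alta = left_normalize(a, refa, reference[a], reference)
                bump(pos, refa, alta, r.strand, r.smmip_id)
        for k, seq in r.insertions.items():
            pos, refa, alta = left_normalize(
                k, reference[k], reference[k] + seq, reference
            )
            bump(pos, refa, alta, r.strand, r.smmip_id)

    return Pileup(
        contig=contig,
        start=start,
        end=end,
        depth_plus=depth_plus,
        depth_minus=depth_minus,
        events=events,
        smmip_kept=smmip_kept,
        reads=consensus_reads,
    )


@dataclass
class VariantCall:
    contig: str
    pos: int            # 0-based; +1 on VCF emission
    ref: str
    alt: str
    depth: int          # unique reads at the call position
    var_reads: int
    vaf: float
    plus_depth: int
    minus_depth: int
    plus_var: int
    minus_var: int
    filters: set[str] = field(default_factory=set)
    origin: str = "novel"       # known_germline | novel
    below_expected: bool = False
    supporting_smmips: frozenset = frozenset()

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


def call_variants(
    pile: Pileup,
    min_vaf: float = 0.05,
    min_var_reads: int = 3,
    min_depth: int = 20,
    expected_depth: int = 30,
) -> list[VariantCall]:
    """Emit candidate calls meeting the VAF and variant-read thresholds.

    Calls at positions below ``min_depth`` unique reads carry the
    ``low_depth`` filter (the position belongs to the reported no-call
    zone); depth in [min_depth, expected_depth) sets ``below_expected``.
    """
    if not 0.0 < min_vaf <= 1.0:
        raise ValueError(f"min_vaf must be in (0, 1], got {min_vaf}")
    calls = []
    for (pos, ref, alt), ev in sorted(pile.events.items()):
        i = pos - pile.start
        if not 0 <= i < pile.end - pile.start:
            continue
        dp = int(pile.depth_plus[i])
        dm = int(pile.depth_minus[i])
        depth = dp + dm
        var = ev.total
        if depth == 0:
            continue
        vaf = var / depth
        if vaf < min_vaf or var < min_var_reads:
            continue
        call = VariantCall(
            contig=pile.contig,
            pos=pos,
            ref=ref,
            alt=alt,
            depth=depth,
            var_reads=var,
            vaf=vaf,
            plus_depth=dp,
            minus_depth=dm,
            plus_var=ev.plus,
            minus_var=ev.minus,
            supporting_smmips=frozenset(ev.smmips),
        )
        if depth < min_depth:
            call.filters.add("low_depth")
        call.below_expected = min_depth <= depth < expected_depth
        calls.append(call)
    return calls


def deamination_filter(call: VariantCall, opposite_strand_min_depth: int = 10) -> None:
    """Strand-concordance gate for C:G>T:A transitions.

    A C>T (or G>A) call present on only one targeted strand, while the
    probes covering the opposite strand have adequate depth and zero variant
    reads, is marked ``deamination``.  Opposite-strand depth below the floor
    flags the call ``unresolvable_strand`` instead.
    """
    if (call.ref, call.alt) not in (("C", "T"), ("G", "A")):
        return
    if call.plus_var > 0 and call.minus_var > 0:
        return
    if call.plus_var > 0:
        opp_depth, opp_var = call.minus_depth, call.minus_var
    else:
        opp_depth, opp_var = call.plus_depth, call.plus_var
    if opp_depth >= opposite_strand_min_depth:
        if opp_var == 0:
            call.filters.add("deamination")
    else:
        call.filters.add("unresolvable_strand")


def _homopolymer_hit(reference: str, lo: int, hi: int, min_run: int = 8) -> bool:
    """Does [lo, hi) overlap a run of >= min_run identical A or T bases?"""
    scan_lo = max(0, lo - min_run)
    scan_hi = min(len(reference), hi + min_run)
    run_base, run_start = None, scan_lo
    for i in range(scan_lo, scan_hi + 1):
        b = reference[i] if i < scan_hi else None
        if b != run_base:
            if run_base in ("A", "T") and i - run_start >= min_run:
                if run_start < hi and lo < i:
                    return True
            run_base, run_start = b, i
    return False


def context_filters(
    call: VariantCall,
    reference: str,
    panel: Panel,
    smmip_kept: Counter,
    min_overlap_depth: int = 10,
) -> None:
    """Homopolymer and read-end false-positive context rules.

    Indels overlapping a stretch of eight or more adenines (or thymines)
    gain ``homopolymer_A8``.  A variant at the first/last base of its sole
    supporting probe's target, while an overlapping probe covers the base at
    adequate depth without seeing the variant, gains ``read_end``.
    """
    if not call.is_snv:
        hi = call.pos + max(len(call.ref), 2)  # anchor + event footprint
        if _homopolymer_hit(reference, call.pos, hi):
            call.filters.add("homopolymer_A8")
    if len(call.supporting_smmips) == 1:
        (mid,) = call.supporting_smmips
        m = panel.by_id(mid)
        last = call.pos + len(call.ref) - 1
        at_edge = call.pos == m.target_start or last == m.target_end - 1
        if at_edge:
            for other in panel.overlapping(m.contig, call.pos):
                if other.id != mid and smmip_kept.get(other.id, 0) >= min_overlap_depth:
                    call.filters.add("read_end")
                    break


class GermlineDatabase:
    """In-house list of known germline variants, keyed (contig, pos, ref, alt)."""

    def __init__(self, records=()):
        self._keys = set(records)

    def __contains__(self, key) -> bool:
        return key in self._keys

    def __len__(self):
        return len(self._keys)

    @classmethod
    def from_tsv(cls, path):
        """TSV columns: contig, pos (0-based), ref, alt."""
        keys = []
        with open(path) as fh:
            header = next(fh)
            for line in fh:
                c, p, r, a = line.rstrip("\n").split("\t")[:4]
                keys.append((c, int(p), r, a))
        return cls(keys)

    @classmethod
    def from_vcf(cls, path):
        keys = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                for alt in f[4].split(","):
                    keys.append((f[0], int(f[1]) - 1, f[3], alt))
        return cls(keys)


def annotate_known_germline(
    calls: list[VariantCall], germline_db: GermlineDatabase
) -> list[VariantCall]:
    """Label calls found in the germline database ``known_germline``."""
    for c in calls:
        key = (c.contig, c.pos, c.ref, c.alt)
        c.origin = "known_germline" if key in germline_db else "novel"
    return calls


def apply_artifact_filters(
    calls: list[VariantCall],
    reference: str,
    panel: Panel,
    smmip_kept: Counter,
    opposite_strand_min_depth: int = 10,
    min_overlap_depth: int = 10,
) -> list[VariantCall]:
    for c in calls:
        deamination_filter(c, opposite_strand_min_depth)
        context_filters(c, reference, panel, smmip_kept, min_overlap_depth)
    return calls


def nocall_regions(pile: Pileup, min_depth: int = 20) -> list[tuple[int, int]]:
    """Intervals of the piled-up span with fewer than min_depth unique reads."""
    total = pile.depth_plus + pile.depth_minus
    low = total < min_depth
    out = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            out.append((pile.start + i, pile.start + j))
            i = j
        else:
            i += 1
    return out


def write_nocall_tsv(regions: list[tuple[int, int]], path, contig: str = "ref") -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\n")
        for s, e in regions:
            fh.write(f"{contig}\t{s}\t{e}\n")


def write_vcf(
    calls: list[VariantCall], path, reference_id: str = "ref", source: str = "smmipkit"
) -> None:
    """Emit calls as VCF v4.2 (1-based positions, filter vocabulary in FILTER)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write(f"##reference={reference_id}\n")
        for f in FILTER_VOCAB:
            fh.write(f'##FILTER=<ID={f},Description="{f} filter">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="unique read depth">\n')
        fh.write('##INFO=<ID=VR,Number=1,Type=Integer,Description="unique variant reads">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="variant allele frequency">\n')
        fh.write('##INFO=<ID=SDP,Number=2,Type=Integer,Description="plus,minus unique depth">\n')
        fh.write('##INFO=<ID=SVR,Number=2,Type=Integer,Description="plus,minus variant reads">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="known_germline or novel">\n')
        fh.write('##INFO=<ID=BELOWEXP,Number=0,Type=Flag,Description="depth below expected">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            filt = "PASS" if c.is_pass else ";".join(sorted(c.filters))
            info = (
                f"DP={c.depth};VR={c.var_reads};VAF={c.vaf:.4f};"
                f"SDP={c.plus_depth},{c.minus_depth};SVR={c.plus_var},{c.minus_var};"
                f"ORIGIN={c.origin}"
            )
            if c.below_expected:
                info += ";BELOWEXP"
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}\n"
            )
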