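"""smMIP panel model: probe anatomy, validation and strand-specific tiling.

A single-molecule molecular inversion probe (smMIP) is a 75-80 nt oligo
consisting of an extension arm and a ligation arm (40-45 nt combined) joined
by a 30-nt linker that carries a stretch of random nucleotides (the molecular
tag, 5 nt by default).  The arms hybridise to the flanks of a 112-nt target
region; gap filling copies the target, so each captured molecule is
identified by its (smMIP, tag) pair.  Independent probes target the plus and
the minus strand of the same region ("double tiling"), which is what later
lets strand-confined deamination artifacts be recognised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

TARGET_SPAN = 112
ARM_TOTAL_RANGE = (40, 45)
LINKER_LENGTH = 30
OLIGO_RANGE = (75, 80)

_DNA = set("ACGT")

PANEL_COLUMNS = [
    "id",
    "target_name",
    "contig",
    "target_start",
    "target_end",
    "strand",
    "extension_arm",
    "ligation_arm",
    "linker",
    "tag_length",
    "allele_group",
]


class PanelValidationError(ValueError):
    """An smMIP or panel violates a structural invariant."""


class PanelParseError(ValueError):
    """A panel file row could not be parsed."""


@dataclass(frozen=True)
class SmMIP:
    """One probe: target interval (0-based half-open), strand and oligo parts."""

    id: str
    target_name: str
    contig: str
    target_start: int
    target_end: int
    targeted_strand: str  # "+" or "-"
    extension_arm: str
    ligation_arm: str
    linker: str
    tag_length: int = 5
    allele_group: str | None = None

    def __post_init__(self) -> None:
        if self.targeted_strand not in ("+", "-"):
            raise PanelValidationError(
                f"smMIP {self.id}: strand must be '+' or '-', got {self.targeted_strand!r}"
            )
        if self.target_end - self.target_start != TARGET_SPAN:
            raise PanelValidationError(
                f"smMIP {self.id}: target span must be {TARGET_SPAN} nt, "
                f"got {self.target_end - self.target_start}"
            )
        arms = len(self.extension_arm) + len(self.ligation_arm)
        if not ARM_TOTAL_RANGE[0] <= arms <= ARM_TOTAL_RANGE[1]:
            raise PanelValidationError(
                f"smMIP {self.id}: combined arm length {arms} outside "
                f"{ARM_TOTAL_RANGE[0]}-{ARM_TOTAL_RANGE[1]} nt"
            )
        if len(self.linker) != LINKER_LENGTH:
            raise PanelValidationError(
                f"smMIP {self.id}: linker must be {LINKER_LENGTH} nt, got {len(self.linker)}"
            )
        oligo = arms + len(self.linker) + self.tag_length
        if not OLIGO_RANGE[0] <= oligo <= OLIGO_RANGE[1]:
            raise PanelValidationError(
                f"smMIP {self.id}: total oligo length {oligo} outside "
                f"{OLIGO_RANGE[0]}-{OLIGO_RANGE[1]} nt"
            )
        for name in ("extension_arm", "ligation_arm"):
            seq = getattr(self, name)
            if not set(seq) <= _DNA:
                raise PanelValidationError(
                    f"smMIP {self.id}: {name} contains non-ACGT characters"
                )
        if self.tag_length < 0:
            raise PanelValidationError(f"smMIP {self.id}: negative tag length")

    @property
    def span(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


@dataclass
class Panel:
    """A validated collection of smMIPs against one reference."""

    smmips: list[SmMIP]
    reference_id: str = "ref"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.smmips]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate smMIP ids: {dup}")
        groups: dict[str, int] = {}
        for m in self.smmips:
            if m.allele_group:
                groups[m.allele_group] = groups.get(m.allele_group, 0) + 1
        for g, n in groups.items():
            if n < 2:
                raise PanelValidationError(
                    f"allele group {g!r} has a single member; SNP-alternate "
                    "groups need at least two probes"
                )

    def __len__(self) -> int:
        return len(self.smmips)

    def __iter__(self):
        return iter(self.smmips)

    def by_id(self, smmip_id: str) -> SmMIP:
        for m in self.smmips:
            if m.id == smmip_id:
                return m
        raise KeyError(smmip_id)

    def overlapping(self, contig: str, pos: int) -> list[SmMIP]:
        """All probes whose target covers reference position ``pos``."""
        return [
            m
            for m in self.smmips
            if m.contig == contig and m.target_start <= pos < m.target_end
        ]


@dataclass
class TilingProfile:
    """Per-base counts of covering probes on each strand over a region set."""

    contig: str
    start: int
    end: int
    plus: np.ndarray  # int counts, length end-start
    minus: np.ndarray
    mask: np.ndarray = field(default=None)  # bool: positions inside the regions

    @property
    def covered_fraction(self) -> float:
        """Fraction of region bases covered by at least one probe on any strand."""
        m = self.mask
        any_cov = (self.plus + self.minus) > 0
        return float(any_cov[m].mean()) if m.any() else 0.0

    @property
    def plus_fraction(self) -> float:
        m = self.mask
        return float((self.plus[m] > 0).mean()) if m.any() else 0.0

    @property
    def minus_fraction(self) -> float:
        m = self.mask
        return float((self.minus[m] > 0).mean()) if m.any() else 0.0

    @property
    def double_tiled_fraction(self) -> float:
        """Fraction of region bases covered on both the plus and minus strand."""
        m = self.mask
        both = (self.plus > 0) & (self.minus > 0)
        return float(both[m].mean()) if m.any() else 0.0


def tag_space_size(tag_length: int) -> int:
    """Number of distinct molecular tags of the given length (4^L).

    A 5-nt tag distinguishes 1,024 template molecules per smMIP; an 8-nt
    tag would distinguish 65,536.
    """
    if tag_length < 0:
        raise ValueError("tag_length must be >= 0")
    return 4**tag_length


def compute_tiling(
    panel: Panel,
    regions: Sequence[tuple[str, int, int]],
    contig_lengths: dict[str, int] | None = None,
) -> TilingProfile:
    """Per-base plus/minus probe coverage over a set of intervals.

    ``regions`` are (contig, start, end) 0-based half-open intervals; all must
    lie on a single contig (the panel's reference sequence).  If
    ``contig_lengths`` is given, regions extending past a contig raise.
    """
    if not regions:
        raise ValueError("no regions given")
    contigs = {r[0] for r in regions}
    if len(contigs) > 1:
        raise ValueError("all regions must be on one contig")
    contig = next(iter(contigs))
    if contig_lengths is not None:
        clen = contig_lengths.get(contig)
        if clen is None:
            raise ValueError(f"region contig {contig!r} not in reference")
        for _, s, e in regions:
            if s < 0 or e > clen:
                raise ValueError(f"region [{s},{e}) off contig {contig!r} (length {clen})")
    start = min(r[1] for r in regions)
    end = max(r[2] for r in regions)
    n = end - start
    plus = np.zeros(n, dtype=np.int32)
    minus = np.zeros(n, dtype=np.int32)
    mask = np.zeros(n, dtype=bool)
    for _, s, e in regions:
        mask[s - start : e - start] = True
    for m in panel:
        if m.contig != contig:
            continue
        s = max(m.target_start, start) - start
        e = min(m.target_end, end) - start
        if s >= e:
            continue
        (plus if m.targeted_strand == "+" else minus)[s:e] += 1
    return TilingProfile(contig=contig, start=start, end=end, plus=plus, minus=minus, mask=mask)


def load_panel(path, reference_id: str = "ref") -> Panel:
    """Read a panel from a tab-separated file with a mandatory header.

    Columns: id, target_name, contig, target_start, target_end, strand,
    extension_arm, ligation_arm, linker, tag_length, allele_group (empty
    allele_group means the probe has no SNP-alternate sibling).
    """
    smmips = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(PANEL_COLUMNS) - set(reader.fieldnames):
            missing = sorted(set(PANEL_COLUMNS) - set(reader.fieldnames or []))
            raise PanelParseError(f"panel file missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                smmips.append(
                    SmMIP(
                        id=row["id"],
                        target_name=row["target_name"],
                        contig=row["contig"],
                        target_start=int(row["target_start"]),
                        target_end=int(row["target_end"]),
                        targeted_strand=row["strand"],
                        extension_arm=row["extension_arm"].upper(),
                        ligation_arm=row["ligation_arm"].upper(),
                        linker=row["linker"].upper(),
                        tag_length=int(row["tag_length"]),
                        allele_group=row["allele_group"] or None,
                    )
                )
            except (KeyError, TypeError) as exc:
                raise PanelParseError(f"line {i}: malformed row ({exc})") from exc
            except ValueError as exc:
                if isinstance(exc, PanelValidationError):
                    raise
                raise PanelParseError(f"line {i}: malformed row ({exc})") from exc
    return Panel(smmips=smmips, reference_id=reference_id)


def write_panel(panel: Panel, path) -> None:
    """Write a panel back to the TSV dialect read by :func:`load_panel`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PANEL_COLUMNS)
        for m in panel:
            w.writerow(
                [
                    m.id,
                    m.target_name,
                    m.contig,
                    m.target_start,
                    m.target_end,
                    m.targeted_strand,
                    m.extension_arm,
                    m.ligation_arm,
                    m.linker,
                    m.tag_length,
                    m.allele_group or "",
                ]
            )


def export_bed(panel: Panel, path) -> None:
    """Write target intervals as 0-based half-open BED with strand."""
    with open(path, "w") as fh:
        for m in panel:
            fh.write(
                f"{m.contig}\t{m.target_start}\t{m.target_end}\t{m.id}\t0\t{m.targeted_strand}\n"
            )


def target_regions(panel: Panel, flank: int = 0) -> list[tuple[str, int, int]]:
    """Merged (contig, start, end) intervals covered by the panel's targets."""
    ivs = sorted((m.contig, m.target_start - flank, m.target_end + flank) for m in panel)
    merged: list[list] = []
    for c, s, e in ivs:
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    return [tuple(x) for x in merged]
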