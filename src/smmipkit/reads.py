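"""Read assignment, molecular-tag grouping and consensus construction.

Raw paired reads are assigned to probes by exact arm match (SNP-tolerant
alternate probes in an allele group are each tried), the 5-nt molecular tag
is excised from its fixed position at the start of read 2, and reads sharing
one (smMIP, tag) pair — i.e. PCR duplicates of one template molecule — are
collapsed into a consensus ("unique") read.  Consensus rules:

* at least two tagged read pairs are required to form a consensus read;
* per position the consensus base is the modal base among members, and it
  must be supported by at least 30% of them (otherwise the position is
  reported unknown);
* a member agreeing with the group consensus at fewer than 30% of positions
  is discarded and the group re-evaluated;
* every target position must be sequenced at least once, else the group is
  rejected as incomplete;
* a finished consensus is dropped if it has more than 15% mismatches against
  the reference target, or if fewer than 50% of its bases match.

Within one read pair, mates covering the same position are merged toward the
higher base quality; quality ties that disagree become unknown.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import dna
from .dna import DEL, UNKNOWN, encode, revcomp
from .panel import Panel, SmMIP

MIN_MEMBERS = 2
MIN_POSITION_SUPPORT = 0.30
MIN_MEMBER_AGREEMENT = 0.30
MAX_MISMATCH_FRACTION = 0.15
MIN_MATCH_FRACTION = 0.50

# Hamming mismatches beyond which the no-indel interpretation of a fragment
# is abandoned in favour of a gapped alignment.
_GAPPED_FALLBACK_MM = 24
# Edit-distance budget for the gapped projection; beyond it a fragment is
# treated as unalignable rather than force-fitted with spurious gaps.
_GAPPED_MAX_EDITS = 20

_COMP_CODE = np.array([3, 2, 1, 0, 4, 5], dtype=np.int8)  # A<->T, C<->G


@dataclass
class ReadPair:
    name: str
    r1: str
    q1: str
    r2: str
    q2: str
    sample: str | None = None


@dataclass
class TagGroup:
    smmip_id: str
    tag: str
    members: list[ReadPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """One deduplicated template molecule, in reference (plus) orientation."""

    smmip_id: str
    tag: str
    member_count: int
    strand: str            # targeted strand of the probe
    contig: str
    start: int             # reference interval [start, end)
    end: int
    codes: np.ndarray      # int8 per reference position: base, DEL or UNKNOWN
    support: np.ndarray    # modal support fraction per position
    insertions: dict[int, str]  # anchor refpos -> inserted sequence (plus strand)

    @property
    def seq(self) -> str:
        return dna.decode(self.codes)

    def known_mask(self) -> np.ndarray:
        return self.codes != UNKNOWN


@dataclass
class Rejected:
    smmip_id: str
    tag: str
    reason: str  # min_members | incomplete | mismatch | low_match


@dataclass
class ProcessingStats:
    """Per-sample accounting mirroring the pipeline's filter cascade."""

    total_pairs: int = 0
    assigned: int = 0
    unassigned_arm: int = 0
    unassigned_tag_n: int = 0
    groups: int = 0
    rejected_min_members: int = 0
    rejected_incomplete: int = 0
    members_dropped: int = 0
    dropped_mismatch: int = 0
    dropped_low_match: int = 0
    kept: int = 0


# ---------------------------------------------------------------------------
# assignment


class ArmIndex:
    """Exact-match lookup of (ligation arm on read 1, extension arm on read 2)."""

    def __init__(self, panel: Panel):
        self._by_lig: dict[tuple[int, str], list[SmMIP]] = defaultdict(list)
        self._lig_lengths: set[int] = set()
        for m in panel:
            self._by_lig[(len(m.ligation_arm), m.ligation_arm)].append(m)
            self._lig_lengths.add(len(m.ligation_arm))

    def assign(self, pair: ReadPair) -> tuple[str, str] | None:
        for L in self._lig_lengths:
            candidates = self._by_lig.get((L, pair.r1[:L]))
            if not candidates:
                continue
            for m in candidates:
                tl = m.tag_length
                if pair.r2[tl : tl + len(m.extension_arm)] == m.extension_arm:
                    tag = pair.r2[:tl]
                    if "N" in tag:
                        return None  # undefined nucleotide in the molecular tag
                    return (m.id, tag)
        return None


def assign_and_tag(pair: ReadPair, panel: Panel) -> tuple[str, str] | None:
    """Assign one read pair to a probe and excise its molecular tag.

    Returns None for unassignable pairs (no exact arm match, or an N in the
    tag) — a counted, normal outcome.
    """
    return ArmIndex(panel).assign(pair)


def group_by_tag(
    assignments: list[tuple[ReadPair, tuple[str, str]]]
) -> list[TagGroup]:
    """Partition assigned pairs by (smMIP, tag)."""
    groups: dict[tuple[str, str], TagGroup] = {}
    for pair, (smmip_id, tag) in assignments:
        key = (smmip_id, tag)
        if key not in groups:
            groups[key] = TagGroup(smmip_id=smmip_id, tag=tag)
        groups[key].members.append(pair)
    return list(groups.values())


# ---------------------------------------------------------------------------
# per-pair fragment extraction (captured-strand space)


def _gapped_call(cref: str, fragment: str, quals: str):
    """Project a fragment onto the captured reference by gapped alignment.

    Returns (codes, qarr, insertions) in captured space; insertions are keyed
    by the captured index they follow.
    """
    n = len(cref)
    codes = np.full(n, UNKNOWN, dtype=np.int8)
    qarr = np.zeros(n, dtype=np.int16)
    insertions: dict[int, str] = {}
    # cap the edit distance: a genuine fragment differs from its target by a
    # few variants plus errors; unalignable fragments stay unknown (and are
    # then discarded by the member-agreement rule)
    res = edlib.align(cref, fragment, mode="HW", task="path", k=_GAPPED_MAX_EDITS)
    if res["editDistance"] < 0 or not res["locations"]:
        return codes, qarr, insertions
    tpos = res["locations"][0][0]
    qpos = 0  # position in cref
    frag_codes = encode(fragment)
    fq = np.frombuffer(quals.encode("ascii"), dtype=np.uint8)
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            codes[qpos : qpos + ln] = frag_codes[tpos : tpos + ln]
            qarr[qpos : qpos + ln] = fq[tpos : tpos + ln]
            qpos += ln
            tpos += ln
        elif ch == "I":  # missing from the fragment: deletion in the read
            codes[qpos : qpos + ln] = DEL
            qarr[qpos : qpos + ln] = 0
            qpos += ln
        elif ch == "D":  # extra fragment bases: insertion in the read
            if qpos > 0:
                insertions[qpos - 1] = fragment[tpos : tpos + ln]
            tpos += ln
    return codes, qarr, insertions


def _pair_call(pair: ReadPair, m: SmMIP, cref: str):
    """Per-position base call for one read pair, in captured-strand space.

    Both mates are projected onto the 112-nt captured reference; positions
    covered by both are merged toward the higher base quality (ties that
    disagree -> unknown).  Returns (codes, insertions).
    """
    n = len(cref)
    tl, ext, lig = m.tag_length, len(m.extension_arm), len(m.ligation_arm)

    # mate 2: tag + extension arm + S ...
    f2 = pair.r2[tl + ext :]
    f2q = pair.q2[tl + ext :]
    # mate 1 reverse-complemented: ...junk + S + revcomp(ligation arm)
    rc1 = revcomp(pair.r1)
    rc1q = pair.q1[::-1]

    def fast(fragment, quals, offset):
        """No-indel interpretation: fragment[offset:offset+n] is S."""
        s = fragment[max(0, offset) : offset + n]
        covered0 = max(0, -offset)  # first captured index covered
        if not s:
            return None
        mm = dna.hamming(s, cref[covered0 : covered0 + len(s)])
        if mm > _GAPPED_FALLBACK_MM:
            return None
        codes = np.full(n, UNKNOWN, dtype=np.int8)
        qarr = np.zeros(n, dtype=np.int16)
        codes[covered0 : covered0 + len(s)] = encode(s)
        q = quals[max(0, offset) : offset + n]
        qarr[covered0 : covered0 + len(s)] = np.frombuffer(
            q.encode("ascii"), dtype=np.uint8
        )
        return codes, qarr, {}

    c2 = fast(f2, f2q, 0)
    if c2 is None:
        c2 = _gapped_call(cref, f2, f2q)
    off1 = len(rc1) - lig - n
    c1 = fast(rc1, rc1q, off1)
    if c1 is None:
        c1 = _gapped_call(cref, rc1, rc1q)

    codes1, q1, ins1 = c1
    codes2, q2, ins2 = c2
    merged = codes2.copy()
    q = q2.copy()
    only1 = (merged == UNKNOWN) & (codes1 != UNKNOWN)
    merged[only1] = codes1[only1]
    q[only1] = q1[only1]
    both = (codes1 != UNKNOWN) & (codes2 != UNKNOWN)
    disagree = both & (codes1 != codes2)
    take1 = disagree & (q1 > q2)
    merged[take1] = codes1[take1]
    tie = disagree & (q1 == q2)
    merged[tie] = UNKNOWN

    covered = (codes1 != UNKNOWN) | (codes2 != UNKNOWN)
    insertions = dict(ins2)
    insertions.update(ins1)  # mates rarely disagree here; mate 1 wins ties
    return merged, covered, insertions


# ---------------------------------------------------------------------------
# consensus


def build_consensus(
    group: TagGroup, smmip: SmMIP, reference: str
) -> ConsensusRead | Rejected:
    """Collapse one (smMIP, tag) group into a consensus read.

    Implements the minimum-two-members rule, the 30% positional-support rule,
    the 30% member-agreement rule (discard and re-evaluate) and the
    every-position-sequenced-once requirement.
    """
    if len(group.members) < MIN_MEMBERS:
        return Rejected(group.smmip_id, group.tag, "min_members")
    s, e = smmip.target_start, smmip.target_end
    window = reference[s:e]
    cref = window if smmip.targeted_strand == "+" else revcomp(window)
    n = len(cref)

    # identical PCR duplicates give identical projections: compute once, weight
    uniq: dict[tuple[str, str], int] = Counter(
        (p.r1, p.r2) for p in group.members
    )
    pair_by_key = {(p.r1, p.r2): p for p in group.members}
    member_codes = []
    member_covered = []
    member_ins = []
    weights = []
    for key, w in uniq.items():
        codes, covered, ins = _pair_call(pair_by_key[key], smmip, cref)
        member_codes.append(codes)
        member_covered.append(covered)
        member_ins.append(ins)
        weights.append(w)

    # common case: every duplicate projected identically -> trivial consensus
    if len(member_codes) == 1 and sum(weights) >= MIN_MEMBERS:
        if not member_covered[0].all():
            return Rejected(group.smmip_id, group.tag, "incomplete")
        consensus = member_codes[0].copy()
        support = np.ones(n, dtype=np.float32)
        support[consensus == UNKNOWN] = 0.0
        return _finalize(
            group, smmip, consensus, support, dict(member_ins[0]),
            int(sum(weights)), 0, s, e,
        )

    active = list(range(len(member_codes)))
    dropped_members = 0
    while True:
        if sum(weights[i] for i in active) < MIN_MEMBERS:
            return Rejected(group.smmip_id, group.tag, "min_members")
        arr = np.stack([member_codes[i] for i in active])
        w_arr = np.array([weights[i] for i in active])[:, None]
        known = arr != UNKNOWN
        covering = (known * w_arr).sum(axis=0)
        counts = np.stack([((arr == c) * w_arr).sum(axis=0) for c in range(5)])
        modal_count = counts.max(axis=0)
        modal = counts.argmax(axis=0).astype(np.int8)
        ties = (counts == modal_count).sum(axis=0) > 1
        with np.errstate(invalid="ignore", divide="ignore"):
            support = np.where(covering > 0, modal_count / np.maximum(covering, 1), 0.0)
        consensus = modal.copy()
        unknown = (covering == 0) | ties | (support < MIN_POSITION_SUPPORT)
        consensus[unknown] = UNKNOWN

        # member agreement against this provisional consensus
        cons_known = consensus != UNKNOWN
        worst, worst_frac = None, 1.0
        for idx_pos, i in enumerate(active):
            overlap = cons_known & known[idx_pos]
            if not overlap.any():
                frac = 0.0
            else:
                frac = float((arr[idx_pos][overlap] == consensus[overlap]).mean())
            if frac < MIN_MEMBER_AGREEMENT and frac < worst_frac:
                worst, worst_frac = i, frac
        if worst is None:
            break
        active.remove(worst)
        dropped_members += weights[worst]

    n_members = int(sum(weights[i] for i in active))
    sequenced = np.zeros(n, dtype=bool)
    for i in active:
        sequenced |= member_covered[i]
    if not sequenced.all():
        return Rejected(group.smmip_id, group.tag, "incomplete")

    # insertion consensus under the same modal >= 30% rule
    insertions: dict[int, str] = {}
    keys = set()
    for i in active:
        keys.update(member_ins[i])
    for k in sorted(keys):
        votes: Counter = Counter()
        for i in active:
            votes[member_ins[i].get(k)] += weights[i]
        seq, cnt = votes.most_common(1)[0]
        if seq is not None and cnt / n_members >= MIN_POSITION_SUPPORT:
            # a tie between an insertion and no-insertion favours no insertion
            if votes[None] < cnt:
                insertions[k] = seq

    return _finalize(
        group, smmip, consensus, support, insertions, n_members, dropped_members, s, e
    )


def _finalize(
    group: TagGroup,
    smmip: SmMIP,
    consensus: np.ndarray,
    support: np.ndarray,
    insertions: dict[int, str],
    n_members: int,
    dropped_members: int,
    s: int,
    e: int,
) -> ConsensusRead:
    """Convert captured-strand space to reference (plus) orientation."""
    if smmip.targeted_strand == "-":
        consensus = _COMP_CODE[consensus][::-1].copy()
        support = np.asarray(support)[::-1].copy()
        insertions = {e - k - 2: revcomp(seq) for k, seq in insertions.items()}
    else:
        insertions = {s + k: seq for k, seq in insertions.items()}

    cr = ConsensusRead(
        smmip_id=group.smmip_id,
        tag=group.tag,
        member_count=n_members,
        strand=smmip.targeted_strand,
        contig=smmip.contig,
        start=s,
        end=e,
        codes=consensus,
        support=np.asarray(support, dtype=np.float32),
        insertions=insertions,
    )
    cr._dropped_members = dropped_members  # accounting only
    return cr


def alignment_filter(
    consensus: ConsensusRead,
    reference: str,
    max_mismatch_fraction: float = MAX_MISMATCH_FRACTION,
    min_match_fraction: float = MIN_MATCH_FRACTION,
) -> tuple[str, str | None]:
    """Reference concordance gate on a finished consensus read.

    Mismatch fraction (substitutions over known base calls) above 15%, or
    matching bases below 50% of the target span, drop the read.  Gaps
    (deletions) are neither matches nor mismatches.
    Returns ("keep", None) or ("drop", reason).
    """
    ref_codes = encode(reference[consensus.start : consensus.end])
    codes = consensus.codes
    base = codes < DEL
    mismatches = int((base & (codes != ref_codes)).sum())
    matches = int((base & (codes == ref_codes)).sum())
    known_bases = int(base.sum())
    span = consensus.end - consensus.start
    mismatch_fraction = mismatches / known_bases if known_bases else 0.0
    match_fraction = matches / span
    if mismatch_fraction > max_mismatch_fraction:
        return "drop", "mismatch"
    if match_fraction < min_match_fraction:
        return "drop", "low_match"
    return "keep", None


# ---------------------------------------------------------------------------
# stage driver


def process_read_pairs(
    reads: list[ReadPair], panel: Panel, reference: str
) -> tuple[list[ConsensusRead], ProcessingStats]:
    """Full read-processing stage: assign, group, consensus, alignment filter."""
    stats = ProcessingStats(total_pairs=len(reads))
    index = ArmIndex(panel)
    assignments = []
    for pair in reads:
        hit = index.assign(pair)
        if hit is None:
            # distinguish N-tag rejections for the log
            tagged = any(
                pair.r1[: len(m.ligation_arm)] == m.ligation_arm
                and pair.r2[m.tag_length : m.tag_length + len(m.extension_arm)]
                == m.extension_arm
                for m in panel
            )
            if tagged:
                stats.unassigned_tag_n += 1
            else:
                stats.unassigned_arm += 1
            continue
        stats.assigned += 1
        assignments.append((pair, hit))

    groups = group_by_tag(assignments)
    stats.groups = len(groups)
    kept: list[ConsensusRead] = []
    for g in groups:
        smmip = panel.by_id(g.smmip_id)
        result = build_consensus(g, smmip, reference)
        if isinstance(result, Rejected):
            if result.reason == "min_members":
                stats.rejected_min_members += 1
            else:
                stats.rejected_incomplete += 1
            continue
        stats.members_dropped += getattr(result, "_dropped_members", 0)
        verdict, reason = alignment_filter(result, reference)
        if verdict == "drop":
            if reason == "mismatch":
                stats.dropped_mismatch += 1
            else:
                stats.dropped_low_match += 1
            continue
        kept.append(result)
    stats.kept = len(kept)
    return kept, stats


def consensus_to_tsv(reads: list[ConsensusRead], path) -> None:
    """Export consensus reads as a SAM-like TSV table."""
    with open(path, "w") as fh:
        fh.write("smmip_id\ttag\tmembers\tstrand\tcontig\tstart\tend\tsequence\tinsertions\n")
        for r in sorted(reads, key=lambda r: (r.start, r.smmip_id, r.tag)):
            ins = ";".join(f"{k}:{v}" for k, v in sorted(r.insertions.items())) or "."
            fh.write(
                f"{r.smmip_id}\t{r.tag}\t{r.member_count}\t{r.strand}\t{r.contig}\t"
                f"{r.start}\t{r.end}\t{r.seq}\t{ins}\n"
            )
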