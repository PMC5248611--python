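"""Read assignment, tag grouping and consensus rules."""

import numpy as np
import pytest

from smmipkit import SimulationConfig, call_sample, simulate_reads
from smmipkit.dna import revcomp
from smmipkit.reads import (
    ArmIndex,
    ConsensusRead,
    ReadPair,
    Rejected,
    TagGroup,
    alignment_filter,
    assign_and_tag,
    build_consensus,
    group_by_tag,
    process_read_pairs,
)

from conftest import captured, make_pair


class TestAssignment:
    def test_simulated_read_maps_back_to_its_probe(self, reference, panel):
        m = panel.smmips[0]
        pair = make_pair(m, captured(reference, m), tag="ACGTA")
        assert assign_and_tag(pair, panel) == (m.id, "ACGTA")

    def test_minus_strand_probe_assignment(self, reference, panel):
        m = panel.smmips[1]
        assert m.targeted_strand == "-"
        pair = make_pair(m, captured(reference, m), tag="GGGCC")
        assert assign_and_tag(pair, panel) == (m.id, "GGGCC")

    def test_n_in_tag_unassigned(self, reference, panel):
        m = panel.smmips[0]
        pair = make_pair(m, captured(reference, m), tag="ACNTA")
        assert assign_and_tag(pair, panel) is None

    def test_no_arm_match_unassigned(self, panel):
        pair = ReadPair("x", "T" * 151, "I" * 151, "A" * 151, "I" * 151)
        assert assign_and_tag(pair, panel) is None

    def test_allele_group_alternates_each_tried(self, reference, panel):
        # an alternate probe whose extension arm carries a SNP allele
        from smmipkit.panel import Panel, SmMIP

        m = panel.smmips[0]
        alt_arm = ("T" if m.extension_arm[10] != "T" else "G").join(
            [m.extension_arm[:10], m.extension_arm[11:]]
        )
        alt = SmMIP(
            id=m.id + "_alt", target_name=m.target_name, contig=m.contig,
            target_start=m.target_start, target_end=m.target_end,
            targeted_strand=m.targeted_strand, extension_arm=alt_arm,
            ligation_arm=m.ligation_arm, linker=m.linker,
            allele_group="g1",
        )
        ref_copy = SmMIP(
            id=m.id + "_ref", target_name=m.target_name, contig=m.contig,
            target_start=m.target_start, target_end=m.target_end,
            targeted_strand=m.targeted_strand, extension_arm=m.extension_arm,
            ligation_arm=m.ligation_arm, linker=m.linker,
            allele_group="g1",
        )
        duo = Panel(smmips=[ref_copy, alt])
        pair_ref = make_pair(ref_copy, captured(reference, m))
        pair_alt = make_pair(alt, captured(reference, m))
        assert assign_and_tag(pair_ref, duo) == (ref_copy.id, "ACGTA")
        assert assign_and_tag(pair_alt, duo) == (alt.id, "ACGTA")


class TestGrouping:
    def test_partition_conserves_counts(self, reference, panel):
        m = panel.smmips[0]
        ins = captured(reference, m)
        tags = [a + b + "CGT" for a, b in zip("AAAACCCCGG", "ACGTACGTAC")]  # 10 distinct
        pairs = [
            (make_pair(m, ins, tag=tags[i % 10], name=f"r{i}"), (m.id, tags[i % 10]))
            for i in range(100)
        ]
        groups = group_by_tag(pairs)
        assert len(groups) == 10
        assert sum(len(g) for g in groups) == 100

    def test_same_tag_different_probes_stay_separate(self, reference, panel):
        m1, m2 = panel.smmips[0], panel.smmips[2]
        pairs = [
            (make_pair(m1, captured(reference, m1)), (m1.id, "ACGTA")),
            (make_pair(m2, captured(reference, m2)), (m2.id, "ACGTA")),
        ]
        assert len(group_by_tag(pairs)) == 2

    def test_empty_input(self):
        assert group_by_tag([]) == []


class TestConsensus:
    def test_two_identical_members_full_support(self, reference, panel):
        m = panel.smmips[0]
        ins = captured(reference, m)
        g = TagGroup(m.id, "ACGTA", [make_pair(m, ins), make_pair(m, ins)])
        cr = build_consensus(g, m, reference)
        assert isinstance(cr, ConsensusRead)
        assert cr.member_count == 2
        assert cr.seq == reference[m.target_start : m.target_end]
        assert (cr.support == 1.0).all()

    def test_singleton_rejected(self, reference, panel):
        m = panel.smmips[0]
        g = TagGroup(m.id, "ACGTA", [make_pair(m, captured(reference, m))])
        out = build_consensus(g, m, reference)
        assert isinstance(out, Rejected) and out.reason == "min_members"

    def test_two_one_split_gives_modal_base_with_two_thirds_support(
        self, reference, panel
    ):
        m = panel.smmips[0]
        ins = captured(reference, m)
        variant = ("G" if ins[50] != "G" else "A") .join([ins[:50], ins[51:]])
        g = TagGroup(
            m.id, "ACGTA",
            [make_pair(m, ins, name="a"), make_pair(m, ins, name="b"),
             make_pair(m, variant, name="c")],
        )
        cr = build_consensus(g, m, reference)
        assert cr.seq == reference[m.target_start : m.target_end]
        assert cr.support[50] == pytest.approx(2 / 3)

    def test_low_agreement_member_dropped_and_group_reevaluated(
        self, reference, panel, rng
    ):
        m = panel.smmips[0]
        ins = captured(reference, m)
        garbage = "".join(rng.choice(list("ACGT"), size=len(ins)))
        g = TagGroup(
            m.id, "ACGTA",
            [make_pair(m, ins, name="a"), make_pair(m, ins, name="b"),
             make_pair(m, garbage, name="z")],
        )
        cr = build_consensus(g, m, reference)
        assert isinstance(cr, ConsensusRead)
        assert cr.member_count == 2  # garbage member discarded
        assert cr.seq == reference[m.target_start : m.target_end]

    def test_deletion_recovered_in_consensus(self, reference, panel):
        m = panel.smmips[0]
        ins = captured(reference, m)
        deleted = ins[:40] + ins[45:]  # 5-nt deletion
        g = TagGroup(m.id, "ACGTA", [make_pair(m, deleted)] * 3)
        cr = build_consensus(g, m, reference)
        assert isinstance(cr, ConsensusRead)
        assert (cr.codes == 4).sum() == 5  # five deleted positions


class TestAlignmentFilter:
    def _consensus_from_codes(self, m, codes):
        return ConsensusRead(
            smmip_id=m.id, tag="ACGTA", member_count=2, strand=m.targeted_strand,
            contig=m.contig, start=m.target_start, end=m.target_end,
            codes=codes, support=np.ones(112, dtype=np.float32), insertions={},
        )

    def test_reference_identical_kept(self, reference, panel):
        from smmipkit.dna import encode

        m = panel.smmips[0]
        codes = encode(reference[m.target_start : m.target_end])
        assert alignment_filter(self._consensus_from_codes(m, codes), reference) == (
            "keep", None,
        )

    def test_twenty_mismatches_dropped(self, reference, panel):
        from smmipkit.dna import encode

        m = panel.smmips[0]
        codes = encode(reference[m.target_start : m.target_end])
        for i in range(20):  # 20/112 = 17.9% > 15%
            codes[i] = (codes[i] + 1) % 4
        verdict, reason = alignment_filter(self._consensus_from_codes(m, codes), reference)
        assert (verdict, reason) == ("drop", "mismatch")

    def test_five_nt_deletion_without_substitutions_kept(self, reference, panel):
        from smmipkit.dna import DEL, encode

        m = panel.smmips[0]
        codes = encode(reference[m.target_start : m.target_end])
        codes[40:45] = DEL
        assert alignment_filter(self._consensus_from_codes(m, codes), reference)[0] == "keep"


class TestStageInvariants:
    def test_dedup_matches_simulator_tags_exactly_without_error(
        self, reference, panel
    ):
        cfg = SimulationConfig(
            panel=panel, reference=reference, seed=13, templates_per_smmip=60,
            sequencing_error_rate=0.0, deamination_rate=0.0,
        )
        reads, truth = simulate_reads(cfg)
        kept, stats = process_read_pairs(reads, panel, reference)
        per_mip = {}
        for r in kept:
            per_mip[r.smmip_id] = per_mip.get(r.smmip_id, 0) + 1
        for mid, st in truth.smmip_stats.items():
            assert per_mip.get(mid, 0) == st.tags_ge2

    def test_jackpotting_immunity(self, reference, panel):
        m = panel.smmips[0]
        ins = captured(reference, m)
        pairs = [make_pair(m, ins, name=f"r{i}") for i in range(3)]
        g1 = TagGroup(m.id, "ACGTA", pairs)
        g10 = TagGroup(m.id, "ACGTA", pairs * 10)
        c1 = build_consensus(g1, m, reference)
        c10 = build_consensus(g10, m, reference)
        assert c1.seq == c10.seq
        assert (c1.support == c10.support).all()

    def test_conservation_of_pairs_and_groups(self, reference, panel):
        cfg = SimulationConfig(
            panel=panel, reference=reference, seed=21, templates_per_smmip=40,
        )
        reads, _ = simulate_reads(cfg)
        kept, s = process_read_pairs(reads, panel, reference)
        assert s.total_pairs == s.assigned + s.unassigned_arm + s.unassigned_tag_n
        assert (
            s.kept
            + s.rejected_min_members
            + s.rejected_incomplete
            + s.dropped_mismatch
            + s.dropped_low_match
            == s.groups
        )
        assert s.kept == len(kept)
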