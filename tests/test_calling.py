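"""Pileup arithmetic, calling thresholds and the FFPE artifact filters."""

import numpy as np
import pytest

from smmipkit import (
    GermlineDatabase,
    SimulationConfig,
    annotate_known_germline,
    call_sample,
    call_variants,
    simulate_reads,
)
from smmipkit.calling import (
    VariantCall,
    context_filters,
    deamination_filter,
    left_normalize,
    nocall_regions,
    pileup,
    write_vcf,
)
from smmipkit.dna import DEL, encode
from smmipkit.reads import ConsensusRead


def make_read(m, reference, subs=(), dels=(), strand=None, tag="ACGTA"):
    """ConsensusRead for probe m with substitutions {pos: base} applied."""
    codes = encode(reference[m.target_start : m.target_end])
    for pos, base in dict(subs).items():
        codes[pos - m.target_start] = "ACGT".index(base)
    for pos in dels:
        codes[pos - m.target_start] = DEL
    return ConsensusRead(
        smmip_id=m.id, tag=tag, member_count=2,
        strand=strand or m.targeted_strand, contig=m.contig,
        start=m.target_start, end=m.target_end, codes=codes,
        support=np.ones(len(codes), dtype=np.float32), insertions={},
    )


class TestPileup:
    def test_all_reference_column(self, reference, panel):
        m = panel.smmips[0]
        reads = [make_read(m, reference, tag=f"TAG{i:02d}") for i in range(10)]
        pile = pileup(reads, reference)
        pos = m.target_start + 50
        assert pile.depth(pos) == 10
        assert pile.events == {}
        col = pile.column(pos)
        assert col.unique_depth == 10
        assert col.counts_plus[reference[pos]] == 10

    def test_strand_split(self, reference, panel):
        mp, mm = panel.smmips[0], panel.smmips[1]  # same target, both strands
        reads = [make_read(mp, reference, tag=f"P{i}") for i in range(6)] + [
            make_read(mm, reference, tag=f"M{i}") for i in range(4)
        ]
        pile = pileup(reads, reference)
        pos = mp.target_start + 10
        col = pile.column(pos)
        assert sum(col.counts_plus.values()) == 6
        assert sum(col.counts_minus.values()) == 4

    def test_snv_counts_match_hand_enumeration(self, reference, panel):
        m = panel.smmips[0]
        pos = m.target_start + 30
        alt = "G" if reference[pos] != "G" else "A"
        reads = [make_read(m, reference, tag=f"T{i}") for i in range(3)] + [
            make_read(m, reference, subs={pos: alt}, tag=f"V{i}") for i in range(2)
        ]
        pile = pileup(reads, reference)
        ev = pile.events[(pos, reference[pos], alt)]
        assert ev.total == 2 and ev.plus == 2 and ev.minus == 0
        assert pile.depth(pos) == 5
        # strand counts sum to unique depth at the column
        col = pile.column(pos)
        assert col.unique_depth == 5
        assert col.counts_plus[alt] == 2 and col.counts_plus[reference[pos]] == 3

    def test_unknown_positions_do_not_add_depth(self, reference, panel):
        m = panel.smmips[0]
        r = make_read(m, reference)
        r.codes[7] = 5  # unknown
        pile = pileup([r, make_read(m, reference, tag="X")], reference)
        assert pile.depth(m.target_start + 7) == 1
        assert pile.depth(m.target_start + 8) == 2


class TestCallThresholds:
    def _pile_with(self, reference, panel, n_ref, n_var, pos_offset=30):
        m = panel.smmips[0]
        pos = m.target_start + pos_offset
        alt = "G" if reference[pos] != "G" else "A"
        reads = [make_read(m, reference, tag=f"r{i}") for i in range(n_ref)] + [
            make_read(m, reference, subs={pos: alt}, tag=f"v{i}") for i in range(n_var)
        ]
        return pileup(reads, reference), pos, alt

    def test_five_percent_and_three_reads_called(self, reference, panel):
        pile, pos, alt = self._pile_with(reference, panel, 95, 5)
        calls = call_variants(pile)
        (c,) = [c for c in calls if c.pos == pos]
        assert c.vaf == pytest.approx(0.05) and c.var_reads == 5

    def test_two_variant_reads_not_called(self, reference, panel):
        pile, pos, alt = self._pile_with(reference, panel, 98, 2)
        assert [c for c in call_variants(pile) if c.pos == pos] == []

    def test_five_percent_but_two_reads_not_called(self, reference, panel):
        pile, pos, alt = self._pile_with(reference, panel, 38, 2)
        assert [c for c in call_variants(pile) if c.pos == pos] == []

    def test_low_depth_flag_and_below_expected(self, reference, panel):
        pile, pos, alt = self._pile_with(reference, panel, 10, 5)
        (c,) = call_variants(pile)
        assert "low_depth" in c.filters and not c.is_pass
        pile2, pos2, _ = self._pile_with(reference, panel, 20, 5)
        (c2,) = call_variants(pile2)
        assert c2.below_expected and c2.is_pass

    def test_invalid_min_vaf_rejected(self, reference, panel):
        pile, *_ = self._pile_with(reference, panel, 10, 5)
        with pytest.raises(ValueError, match="min_vaf"):
            call_variants(pile, min_vaf=0.0)

    def test_vaf_equals_ratio_exactly_on_simulation(self, reference, panel):
        cfg = SimulationConfig(panel=panel, reference=reference, seed=17,
                               templates_per_smmip=80, deamination_rate=0.03)
        reads, _ = simulate_reads(cfg)
        result = call_sample(reads, panel, reference)
        assert result.calls, "expected candidate calls at this deamination rate"
        for c in result.calls:
            assert c.vaf == c.var_reads / c.depth


def _call(ref, alt, pv, mv, pd=50, md=50, **kw):
    return VariantCall(
        contig="ref", pos=100, ref=ref, alt=alt, depth=pd + md,
        var_reads=pv + mv, vaf=(pv + mv) / (pd + md), plus_depth=pd,
        minus_depth=md, plus_var=pv, minus_var=mv, **kw,
    )


class TestDeaminationFilter:
    def test_plus_only_ct_with_covered_minus_is_artifact(self):
        c = _call("C", "T", pv=10, mv=0)
        deamination_filter(c)
        assert c.filters == {"deamination"}

    def test_both_strand_support_passes(self):
        c = _call("C", "T", pv=8, mv=7)
        deamination_filter(c)
        assert c.filters == set()

    def test_ga_transition_also_checked(self):
        c = _call("G", "A", pv=0, mv=6)
        deamination_filter(c)
        assert c.filters == {"deamination"}

    def test_non_cg_ta_substitution_unaffected(self):
        c = _call("A", "G", pv=9, mv=0)
        deamination_filter(c)
        assert c.filters == set()

    def test_thin_opposite_strand_is_unresolvable(self):
        c = _call("C", "T", pv=10, mv=0, md=5)
        deamination_filter(c)
        assert c.filters == {"unresolvable_strand"}


class TestContextFilters:
    def test_deletion_in_polyA_flagged(self, panel):
        m = panel.smmips[0]
        ref = "G" * 100 + "A" * 8 + "G" * 100
        c = VariantCall(
            contig="ref", pos=102, ref=ref[102:104], alt=ref[102], depth=50,
            var_reads=5, vaf=0.1, plus_depth=25, minus_depth=25, plus_var=3,
            minus_var=2, supporting_smmips=frozenset({m.id}),
        )
        context_filters(c, ref, panel, smmip_kept={})
        assert "homopolymer_A8" in c.filters

    def test_snv_in_polyA_not_homopolymer_flagged(self, panel):
        ref = "G" * 100 + "A" * 8 + "G" * 100
        c = _call("A", "C", pv=3, mv=3)
        c.pos = 104
        context_filters(c, ref, panel, smmip_kept={})
        assert "homopolymer_A8" not in c.filters

    def test_edge_variant_absent_from_overlapping_probe_flagged(
        self, reference, panel
    ):
        m = panel.smmips[2]
        twin = panel.smmips[3]  # same target, opposite strand
        c = _call(reference[m.target_start], "T" if reference[m.target_start] != "T" else "G",
                  pv=4, mv=0)
        c.pos = m.target_start
        c.supporting_smmips = frozenset({m.id})
        context_filters(c, reference, panel, smmip_kept={twin.id: 50})
        assert "read_end" in c.filters

    def test_mid_target_variant_supported_by_two_probes_clean(
        self, reference, panel
    ):
        m = panel.smmips[2]
        c = _call("A", "G", pv=4, mv=4)
        c.pos = m.target_start + 50
        c.supporting_smmips = frozenset({m.id, panel.smmips[3].id})
        context_filters(c, reference, panel, smmip_kept={})
        assert c.filters == set()


class TestGermlineAnnotation:
    def test_matching_position_and_allele(self):
        db = GermlineDatabase([("ref", 100, "C", "T")])
        c = _call("C", "T", pv=5, mv=5)
        annotate_known_germline([c], db)
        assert c.origin == "known_germline"

    def test_same_position_other_allele_is_novel(self):
        db = GermlineDatabase([("ref", 100, "C", "G")])
        c = _call("C", "T", pv=5, mv=5)
        annotate_known_germline([c], db)
        assert c.origin == "novel"

    def test_empty_db_all_novel(self):
        c = _call("C", "T", pv=5, mv=5)
        annotate_known_germline([c], GermlineDatabase())
        assert c.origin == "novel"


class TestIndelNormalization:
    def test_deletion_in_repeat_left_aligned(self):
        #            0123456789
        reference = "GGCACACACT"
        # deleting any CA pair of the repeat is one event; leftmost anchor is G1
        pos, ref, alt = left_normalize(4, "CAC", "C", reference)
        assert (pos, ref, alt) == (1, "GCA", "G")

    def test_non_repeat_deletion_unchanged(self):
        reference = "GGTACGTTAG"
        assert left_normalize(3, "ACG", "A", reference) == (3, "ACG", "A")


class TestReports:
    def test_nocall_regions_found(self, reference, panel):
        m = panel.smmips[4]
        reads = [make_read(m, reference, tag=f"t{i}") for i in range(25)]
        pile = pileup(reads, reference)
        regions = nocall_regions(pile, min_depth=20)
        assert regions == []  # whole piled span at depth 25
        deep = nocall_regions(pile, min_depth=30)
        assert deep == [(m.target_start, m.target_end)]

    def test_vcf_round_trip(self, tmp_path):
        from smmipkit.cli import _read_calls_from_vcf

        c = _call("C", "T", pv=8, mv=7)
        c.origin = "known_germline"
        c2 = _call("G", "A", pv=0, mv=6)
        c2.pos = 200
        c2.filters = {"deamination"}
        path = tmp_path / "out.vcf"
        write_vcf([c, c2], path)
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        back = _read_calls_from_vcf(path)
        assert [(b.pos, b.ref, b.alt) for b in back] == [(100, "C", "T"), (200, "G", "A")]
        assert back[0].is_pass and back[0].origin == "known_germline"
        assert back[1].filters == {"deamination"}
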