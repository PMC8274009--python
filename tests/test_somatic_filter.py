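"""Every somatic filter rule exercised with a positive and a boundary
negative, plus PON, event annotation and quality rescue."""

import pytest

from svkit.model import (
    HEAD,
    TAIL,
    Breakend,
    BreakpointCall,
    LinkKind,
    PhaseLink,
    SingleBreakendCall,
    SupportBreakdown,
    revcomp,
)
from svkit.somatic_filter import (
    FilterResult,
    PanelOfNormals,
    Status,
    annotate_events,
    apply_somatic_filters,
    build_pon,
    classify_confidence,
    emit_call_sets,
    hard_filter,
    pon_filter,
    quality_filter_with_rescue,
)

from conftest import random_seq


def make_bp(
    cid="c1", p1=10_000, p2=20_000, d1=HEAD, d2=TAIL, chrom2="chr1",
    t_vf=30, t_ref=30, t_refpair=20, t_sr=10, t_rp=5, t_assr=10, t_asrp=5,
    n_vf=0, n_ref=20, n_refpair=15, n_sr=0,
    qual=800.0, sb=0.5, precise=True, homlen=0, ihom=(0, 0), insert="",
):
    call = BreakpointCall(
        id=cid, b1=Breakend("chr1", p1, d1), b2=Breakend(chrom2, p2, d2),
        precise=precise, insert_seq=insert,
    )
    call.qual = qual
    call.sb = sb
    call.homlen = homlen
    call.ihompos = ihom
    call.breakdowns["t"] = SupportBreakdown(
        VF=t_vf, REF=t_ref, REFPAIR=t_refpair, SR=t_sr, RP=t_rp,
        ASSR=t_assr, ASRP=t_asrp,
    )
    call.breakdowns["n"] = SupportBreakdown(
        VF=n_vf, REF=n_ref, REFPAIR=n_refpair, SR=n_sr
    )
    return call


def make_be(
    cid="b1", pos=10_000, d=HEAD, seq=None, t_bvf=30, t_ref=30, t_basrp=3,
    n_bvf=0, n_ref=20, qual=1500.0, precise=True,
):
    call = SingleBreakendCall(
        id=cid, be=Breakend("chr1", pos, d),
        breakend_seq=seq if seq is not None else random_seq(80, 1),
        precise=precise,
    )
    call.qual = qual
    call.breakdowns["t"] = SupportBreakdown(BVF=t_bvf, REF=t_ref, BASRP=t_basrp)
    call.breakdowns["n"] = SupportBreakdown(BVF=n_bvf, REF=n_ref)
    return call


class TestHardFilter:
    def test_3_percent_normal_support(self):
        call = make_bp(t_vf=32, n_vf=1)  # 1/33 = 3.03%
        assert hard_filter(call, "t", "n").reasons == ["normalSupport"]

    def test_below_3_percent_survives(self):
        call = make_bp(t_vf=40, n_vf=1)  # 1/41 = 2.4%
        assert hard_filter(call, "t", "n") is None

    def test_short_event_with_normal_split_read(self):
        call = make_bp(p1=10_000, p2=10_800, n_sr=1)  # 800 bp deletion
        assert hard_filter(call, "t", "n").reasons == ["shortSRNormal"]

    def test_long_event_normal_sr_not_hard(self):
        call = make_bp(p1=10_000, p2=12_000, n_sr=1)
        assert hard_filter(call, "t", "n") is None


class TestLowConfidenceRules:
    def test_normal_coverage_boundary(self):
        low = make_be(n_bvf=0, n_ref=7)
        assert "normalCoverage" in classify_confidence(low, "t", "n")
        ok = make_be(n_bvf=0, n_ref=8)
        assert "normalCoverage" not in classify_confidence(ok, "t", "n")

    def test_tumour_af_boundary(self):
        low = make_bp(t_vf=1, t_ref=200, t_refpair=51)  # 1/252 = 0.397%
        assert "lowAF" in classify_confidence(low, "t", "n")
        ok = make_bp(t_vf=2, t_ref=200, t_refpair=51)  # 0.79%
        assert "lowAF" not in classify_confidence(ok, "t", "n")

    def test_imprecise_flagged(self):
        assert "imprecise" in classify_confidence(make_bp(precise=False), "t", "n")

    def test_breakend_requires_assembled_read_pair(self):
        low = make_be(t_basrp=0)
        assert "noAssemblyRP" in classify_confidence(low, "t", "n")
        ok = make_be(t_basrp=1)
        assert "noAssemblyRP" not in classify_confidence(ok, "t", "n")

    def test_poly_gc_run_boundary(self):
        low = make_be(seq="ACAT" * 5 + "G" * 16)
        assert "polyGC" in classify_confidence(low, "t", "n")
        ok = make_be(seq="ACAT" * 5 + "G" * 15 + "A")
        assert "polyGC" not in classify_confidence(ok, "t", "n")

    def test_short_deldup_strand_bias_boundary(self):
        low = make_bp(p1=10_000, p2=10_500, sb=0.96)
        assert "strandBias" in classify_confidence(low, "t", "n")
        at = make_bp(p1=10_000, p2=10_500, sb=0.95)
        assert "strandBias" in classify_confidence(at, "t", "n")  # "or greater"
        ok = make_bp(p1=10_000, p2=10_500, sb=0.94)
        assert "strandBias" not in classify_confidence(ok, "t", "n")
        long = make_bp(p1=10_000, p2=20_000, sb=0.99)
        assert "strandBias" not in classify_confidence(long, "t", "n")

    def test_homology_over_50(self):
        low = make_bp(homlen=51)
        assert "homology" in classify_confidence(low, "t", "n")
        ok = make_bp(homlen=50)
        assert "homology" not in classify_confidence(ok, "t", "n")

    def test_inexact_homology_over_50_spares_short_deldup(self):
        low = make_bp(p1=10_000, p2=20_000, ihom=(-26, 25))
        assert "inexactHomology" in classify_confidence(low, "t", "n")
        short = make_bp(p1=10_000, p2=10_500, ihom=(-26, 25))
        assert "inexactHomology" not in classify_confidence(short, "t", "n")

    def test_short_deldup_needs_split_reads(self):
        low = make_bp(p1=10_000, p2=10_500, t_sr=0, t_assr=0)
        assert "noSR" in classify_confidence(low, "t", "n")
        via_asm = make_bp(p1=10_000, p2=10_500, t_sr=0, t_assr=2)
        assert "noSR" not in classify_confidence(via_asm, "t", "n")

    def test_long_events_need_read_pairs(self):
        low = make_bp(p1=10_000, p2=20_000, t_rp=0, t_asrp=0)
        assert "noRP" in classify_confidence(low, "t", "n")
        via_asm = make_bp(p1=10_000, p2=20_000, t_rp=0, t_asrp=1)
        assert "noRP" not in classify_confidence(via_asm, "t", "n")
        short = make_bp(p1=10_000, p2=10_500, t_rp=0, t_asrp=0)
        assert "noRP" not in classify_confidence(short, "t", "n")

    def test_short_deldup_normal_sr_low_confidence(self):
        low = make_bp(p1=10_000, p2=10_500, n_sr=1)
        assert "normalSR" in classify_confidence(low, "t", "n")

    def test_mid_size_deletion_inexact_homology_6(self):
        low = make_bp(p1=10_000, p2=10_301, ihom=(-3, 3))  # 300 bp del, ihom 6
        assert "delIhom" in classify_confidence(low, "t", "n")
        ok = make_bp(p1=10_000, p2=10_301, ihom=(-3, 2))  # ihom 5
        assert "delIhom" not in classify_confidence(ok, "t", "n")
        small = make_bp(p1=10_000, p2=10_100, ihom=(-3, 3))  # 99 bp del
        assert "delIhom" not in classify_confidence(small, "t", "n")

    def test_small_inversion_with_homology(self):
        low = make_bp(p1=10_000, p2=10_040, d2=HEAD, homlen=6)
        assert "invHom" in classify_confidence(low, "t", "n")
        bigger = make_bp(p1=10_000, p2=10_041, d2=HEAD, homlen=6)
        assert "invHom" not in classify_confidence(bigger, "t", "n")
        less_hom = make_bp(p1=10_000, p2=10_040, d2=HEAD, homlen=5)
        assert "invHom" not in classify_confidence(less_hom, "t", "n")

    def test_pseudo_deletion_insert_length(self):
        seq = random_seq(20_000, 3)
        # deleted bases 10001..10100: far from their own reverse complement
        seq = seq[:10_000] + "A" * 50 + "C" * 50 + seq[10_100:]
        ref = {"chr1": seq}
        deleted = ref["chr1"][10_000:10_100]
        low = make_bp(p1=10_000, p2=10_101, insert=random_seq(98, 4))
        assert "pseudoDeletion" in classify_confidence(low, "t", "n", ref)
        ok = make_bp(p1=10_000, p2=10_101, insert=random_seq(90, 4))  # diff 10
        assert "pseudoDeletion" not in classify_confidence(ok, "t", "n", ref)
        # exemption: insert far from deleted bases but near their revcomp
        rc_ins = revcomp(deleted)
        exempt = make_bp(p1=10_000, p2=10_101, insert=rc_ins)
        assert "pseudoDeletion" not in classify_confidence(exempt, "t", "n", ref)


class TestPon:
    def test_build_thresholds(self):
        lo_bp = make_bp("a", qual=74.0)
        hi_bp = make_bp("b", qual=75.0)
        lo_be = make_be("c", qual=427.0)
        hi_be = make_be("d", qual=428.0)
        imprecise = make_bp("e", qual=500.0, precise=False)
        pon = build_pon([[lo_bp, hi_bp, lo_be, hi_be, imprecise]])
        assert len(pon.breakpoints) == 1
        assert len(pon.breakends) == 1

    def test_match_within_2bp_orientation_and_both_ends(self):
        pon = PanelOfNormals()
        pon.add_call(make_bp(p1=1_000_003, p2=2_000_000))
        assert pon_filter(make_bp(p1=1_000_001, p2=2_000_001), pon)
        assert not pon_filter(make_bp(p1=1_000_001, p2=2_000_001, d1=TAIL, d2=HEAD), pon)
        assert not pon_filter(make_bp(p1=1_000_006, p2=2_000_000), pon)
        # one matching breakend is not enough
        assert not pon_filter(make_bp(p1=1_000_003, p2=2_000_900), pon)


class TestEvents:
    def test_equivalent_single_breakends(self):
        seq = random_seq(30, 9)
        a = make_be("a", pos=1000, seq=seq)
        b = make_be("b", pos=1003, seq=seq)
        anns = annotate_events([a, b])
        assert ("EQUIVALENT", ("a", "b")) in [(x.kind, x.members) for x in anns]

    def test_divergent_sequences_not_equivalent(self):
        a = make_be("a", pos=1000, seq=random_seq(30, 10))
        b = make_be("b", pos=1003, seq=random_seq(30, 11))
        assert not [x for x in annotate_events([a, b]) if x.kind == "EQUIVALENT"]

    def test_simple_inversion_support_ratio(self):
        a = make_bp("a", p1=10_000, p2=20_000, d1=HEAD, d2=HEAD, t_vf=10)
        b = make_bp("b", p1=10_010, p2=20_010, d1=TAIL, d2=TAIL, t_vf=29)
        anns = annotate_events([a, b])
        assert [x.kind for x in anns] == ["SIMPLE_INVERSION"]
        b29 = make_bp("b", p1=10_010, p2=20_010, d1=TAIL, d2=TAIL, t_vf=31)
        assert annotate_events([a, b29]) == []  # ratio 3.1 > 3

    def test_reciprocal_translocation(self):
        a = make_bp("a", p1=10_000, chrom2="chr2", p2=50_000, d1=HEAD, d2=HEAD, t_vf=10)
        b = make_bp("b", p1=10_020, chrom2="chr2", p2=50_020, d1=TAIL, d2=TAIL, t_vf=12)
        anns = annotate_events([a, b])
        assert [x.kind for x in anns] == ["RECIPROCAL_TRANSLOCATION"]

    def test_templated_insertion_breakend_pair(self):
        a = make_be("a", pos=1000, d=HEAD, seq=random_seq(40, 12))
        b = make_be("b", pos=1020, d=TAIL, seq=random_seq(40, 13))
        anns = annotate_events([a, b])
        assert "TEMPLATED_INSERTION" in [x.kind for x in anns]


class TestQualityRescue:
    def test_thresholds(self):
        low_bp = make_bp("a", qual=349.0)
        ok_bp = make_bp("b", qual=350.0)
        low_be = make_be("c", qual=999.0)
        ok_be = make_be("d", qual=1000.0)
        res = quality_filter_with_rescue([low_bp, ok_bp, low_be, ok_be], [])
        assert res == {"a": False, "b": True, "c": False, "d": True}

    def test_link_rescues(self):
        low = make_bp("a", qual=349.0)
        ok = make_bp("b", qual=400.0)
        link = PhaseLink(LinkKind.ASSEMBLY_CIS, ("a", "b"), "l1")
        res = quality_filter_with_rescue([low, ok], [link])
        assert res["a"] is True

    def test_equivalence_never_rescues(self):
        low = make_be("a", qual=999.0)
        ok = make_be("b", qual=2000.0)
        link = PhaseLink(LinkKind.EQUIVALENT, ("a", "b"), "l1")
        res = quality_filter_with_rescue([low, ok], [link])
        assert res["a"] is False

    def test_rescue_closure_order_independent(self):
        calls = [make_bp(f"c{i}", qual=100.0) for i in range(4)]
        calls.append(make_bp("top", qual=500.0))
        chain = [
            PhaseLink(LinkKind.TRANSITIVE, ("top", "c0"), "l0"),
            PhaseLink(LinkKind.TRANSITIVE, ("c0", "c1"), "l1"),
            PhaseLink(LinkKind.TRANSITIVE, ("c1", "c2"), "l2"),
        ]
        for links in (chain, list(reversed(chain))):
            res = quality_filter_with_rescue(calls, links)
            assert res == {"c0": True, "c1": True, "c2": True, "c3": False, "top": True}


class TestCallSets:
    def test_set_membership(self):
        passing = make_bp("pass")
        low = make_bp("low", t_vf=1, t_ref=300, t_refpair=0)  # lowAF
        hard = make_bp("hard", t_vf=10, n_vf=10)
        calls = [passing, low, hard]
        results = apply_somatic_filters(calls, "t", "n")
        assert results["pass"].status is Status.PASS
        assert results["low"].status is Status.LOW_CONFIDENCE
        assert results["hard"].status is Status.HARD_FILTERED
        high, lowset = emit_call_sets(calls, results)
        assert [c.id for c in high] == ["pass"]
        assert {c.id for c in lowset} == {"pass", "low"}

    def test_rules_are_pure_order_invariant(self):
        calls = [make_bp(f"x{i}", p1=1000 * i + 10_000, p2=1000 * i + 30_000) for i in range(5)]
        calls[2].breakdowns["n"].VF = 5  # one hard-filtered
        a = apply_somatic_filters(list(calls), "t", "n")
        b = apply_somatic_filters(list(reversed(calls)), "t", "n")
        assert {k: (v.status, sorted(v.reasons)) for k, v in a.items()} == {
            k: (v.status, sorted(v.reasons)) for k, v in b.items()
        }
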