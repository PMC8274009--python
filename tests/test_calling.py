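"""Evidence scoring, maximal-clique candidates, unique allocation and call
emission, with a brute-force clique oracle."""

import itertools

import numpy as np
import pytest

from svkit.calling import (
    Candidate,
    allocate_evidence,
    call_variants,
    compute_support_breakdown,
    enumerate_candidates,
    evidence_quality,
    unique_fragments,
)
from svkit.model import (
    HEAD,
    TAIL,
    AssemblyContig,
    Breakend,
    BreakendInterval,
    BreakpointCall,
    EvidenceItem,
    EvidenceKind,
    SingleBreakendCall,
)

from conftest import make_metrics


def dp_item(frag, lo, hi, rlo, rhi, d1=HEAD, d2=TAIL, sample="t", quality=10.0):
    it = EvidenceItem(
        frag, sample, EvidenceKind.DISCORDANT_PAIR,
        BreakendInterval("chr1", lo, hi, d1),
        BreakendInterval("chr1", rlo, rhi, d2),
        local_mapq=60, remote_mapq=60,
    )
    it.quality = quality
    return it


def sc_item(frag, pos, d=HEAD, sample="t", quality=10.0, strand="+"):
    it = EvidenceItem(
        frag, sample, EvidenceKind.SOFT_CLIP,
        BreakendInterval("chr1", pos, pos, d), None,
        seq="ACGTACGTAC", local_mapq=60, read_strand=strand,
    )
    it.quality = quality
    return it


class TestEvidenceQuality:
    def test_rate_to_phred(self):
        m = make_metrics(clip_rates={("S", 10): 1e-3})
        item = sc_item("f", 100)
        item.quality = 0.0
        assert evidence_quality(item, m) == pytest.approx(30.0)

    def test_mapq_cap(self):
        m = make_metrics(clip_rates={("S", 10): 1e-3})
        item = sc_item("f", 100)
        item.local_mapq = 20
        assert evidence_quality(item, m) == pytest.approx(20.0)

    def test_split_read_capped_by_both_sides(self):
        m = make_metrics(clip_rates={("S", 10): 1e-5})
        it = EvidenceItem(
            "f", "t", EvidenceKind.SPLIT_READ,
            BreakendInterval("chr1", 100, 100, HEAD),
            BreakendInterval("chr1", 900, 900, TAIL),
            seq="ACGTACGTAC", local_mapq=60, remote_mapq=25,
        )
        assert evidence_quality(it, m) <= 25.0


def brute_force_cliques(items):
    """Oracle: enumerate all maximal mutually-compatible subsets."""
    from svkit.calling import _compatible

    n = len(items)
    cliques = []
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            if all(
                _compatible(items[i], items[j])
                for i, j in itertools.combinations(combo, 2)
            ):
                if not any(set(combo) < set(c) for c in cliques):
                    cliques.append(set(combo))
    return {frozenset(c) for c in cliques}


def _clique_sets(items):
    cands = enumerate_candidates(items)
    out = set()
    ids = {id(it): i for i, it in enumerate(items)}
    for c in cands:
        out.add(frozenset(ids[id(m)] for m in c.items))
    return out


class TestEnumerate:
    def test_three_overlapping_plus_disjoint(self):
        items = [
            dp_item("a", 100, 400, 900, 1200),
            dp_item("b", 150, 450, 950, 1250),
            dp_item("c", 200, 500, 1000, 1300),
            dp_item("d", 5000, 5300, 9000, 9300),
        ]
        assert _clique_sets(items) == {frozenset({0, 1, 2}), frozenset({3})}

    def test_single_split_read_width_one(self):
        it = dp_item("a", 250, 250, 800, 800)
        (cand,) = enumerate_candidates([it])
        assert cand.local.width == 1

    def test_chain_overlap_two_cliques(self):
        a = dp_item("a", 100, 300, 900, 1100)
        b = dp_item("b", 250, 500, 1050, 1300)
        c = dp_item("c", 450, 700, 1250, 1500)
        assert _clique_sets([a, b, c]) == {frozenset({0, 1}), frozenset({1, 2})}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        items = []
        for i in range(n):
            lo = int(rng.integers(0, 600))
            w = int(rng.integers(1, 300))
            rlo = int(rng.integers(1000, 1600))
            rw = int(rng.integers(1, 300))
            items.append(dp_item(f"f{i}", lo, lo + w, rlo, rlo + rw))
        assert _clique_sets(items) == brute_force_cliques(items)


class TestAllocate:
    def test_highest_score_wins(self):
        shared = dp_item("s", 200, 260, 1000, 1060)
        big = [dp_item(f"b{i}", 150, 300, 950, 1100, quality=40.0) for i in range(3)]
        small = [dp_item("sm", 240, 400, 1040, 1200, quality=10.0)]
        items = big + small + [shared]
        cands = enumerate_candidates(items)
        allocate_evidence(cands, items, make_metrics())
        owner = [c for c in cands if shared in c.items]
        assert len(owner) == 1
        assert all(b in owner[0].items for b in big)

    def test_assembly_preference_overrides_score(self):
        shared = dp_item("s", 200, 260, 1000, 1060)
        big = [dp_item(f"b{i}", 150, 300, 950, 1100, quality=40.0) for i in range(3)]
        small = [dp_item("sm", 240, 400, 1040, 1200, quality=1.0)]
        contig = AssemblyContig(
            "ctg", "chr1", 250, HEAD, anchor_seq="A" * 40, breakend_seq="C" * 40,
            support={"s": (1, 80)},
        )
        items = big + small + [shared]
        cands = enumerate_candidates(items)
        for c in cands:
            if small[0] in c.items or (c.local.contains(250) and big[0] not in c.items):
                c.contigs.append(contig)
        target = [c for c in cands if c.contigs]
        allocate_evidence(cands, items, make_metrics())
        assert any(shared in c.items for c in target)

    def test_allocation_is_partition(self):
        rng = np.random.default_rng(99)
        items = [
            dp_item(f"f{i}", int(rng.integers(0, 500)), int(rng.integers(500, 900)),
                    int(rng.integers(1000, 1400)), int(rng.integers(1400, 1900)))
            for i in range(15)
        ]
        cands = enumerate_candidates(items)
        allocate_evidence(cands, items, make_metrics())
        counts = {}
        for c in cands:
            for it in c.items:
                counts[it.fragment_id] = counts.get(it.fragment_id, 0) + 1
        assert all(v == 1 for v in counts.values())
        assert len(counts) == len(items)

    def test_symmetric_tie_leftmost_deterministic(self):
        it = dp_item("tie", 200, 400, 1000, 1200)
        a = Candidate("L", BreakendInterval("chr1", 150, 450, HEAD),
                      BreakendInterval("chr1", 950, 1250, TAIL))
        b = Candidate("R", BreakendInterval("chr1", 160, 460, HEAD),
                      BreakendInterval("chr1", 960, 1260, TAIL))
        for order in ([a, b], [b, a]):
            for c in order:
                c.items, c.cq = [], 0.0
            allocate_evidence(order, [it], make_metrics())
            assert it in a.items and it not in b.items


def _precise_candidate(pos1, pos2, items=(), cid="pc"):
    c = Candidate(
        cid,
        BreakendInterval("chr1", pos1, pos1, HEAD),
        BreakendInterval("chr1", pos2, pos2, TAIL),
        precise=True,
        b1=Breakend("chr1", pos1, HEAD),
        b2=Breakend("chr1", pos2, TAIL),
    )
    c.items = list(items)
    return c


class TestCallVariants:
    def _emit(self, cand):
        frag_sample = {i.fragment_id: i.sample for i in cand.items}
        return call_variants([cand], ["t", "n"], frag_sample)

    def test_single_fragment_not_called(self):
        cand = _precise_candidate(100, 5000, [sc_item("only", 100)])
        assert self._emit(cand) == []

    def test_min_size_filter_spares_inversions(self):
        small_del = _precise_candidate(
            100, 110, [sc_item("a", 100), sc_item("b", 100)]
        )
        assert self._emit(small_del) == []
        fold = Candidate(
            "inv",
            BreakendInterval("chr1", 100, 100, HEAD),
            BreakendInterval("chr1", 109, 109, HEAD),
            precise=True,
            b1=Breakend("chr1", 100, HEAD),
            b2=Breakend("chr1", 109, HEAD),
        )
        fold.items = [sc_item("a", 100), sc_item("b", 109)]
        (call,) = self._emit(fold)
        assert call.inversion_like

    def test_unalignable_breakend_gives_single_breakend(self):
        cand = Candidate(
            "sb",
            BreakendInterval("chr1", 100, 100, HEAD),
            None,
            precise=True,
            breakend_seq="ACGT" * 20,
            bealn=["chrR:10|+|80M|0"],
        )
        cand.items = [sc_item("a", 100), sc_item("b", 100)]
        frag_sample = {"a": "t", "b": "t"}
        (call,) = call_variants([cand], ["t", "n"], frag_sample)
        assert isinstance(call, SingleBreakendCall)
        assert call.bealn == ["chrR:10|+|80M|0"]
        assert call.breakdowns["t"].BVF == 2


class TestBreakdown:
    def test_strand_bias_extremes(self):
        cand = _precise_candidate(
            100, 5000,
            [sc_item(f"p{i}", 100, strand="+") for i in range(10)],
        )
        call = BreakpointCall(id="x", b1=cand.b1, b2=cand.b2)
        compute_support_breakdown(call, cand, ["t"], {f"p{i}": "t" for i in range(10)})
        assert call.sb == 1.0

    def test_strand_bias_balanced(self):
        items = [sc_item(f"p{i}", 100, strand="+") for i in range(5)]
        items += [sc_item(f"m{i}", 100, strand="-") for i in range(5)]
        cand = _precise_candidate(100, 5000, items)
        call = BreakpointCall(id="x", b1=cand.b1, b2=cand.b2)
        compute_support_breakdown(
            call, cand, ["t"], {i.fragment_id: "t" for i in items}
        )
        assert call.sb == 0.5

    def test_qual_is_sum_of_components(self):
        rng = np.random.default_rng(5)
        items = [
            sc_item(f"s{i}", 100, quality=float(rng.integers(5, 40))) for i in range(4)
        ] + [
            dp_item(f"d{i}", 90, 110, 4990, 5010, quality=float(rng.integers(5, 40)))
            for i in range(3)
        ]
        cand = _precise_candidate(100, 5000, items)
        call = BreakpointCall(id="x", b1=cand.b1, b2=cand.b2)
        compute_support_breakdown(
            call, cand, ["t"], {i.fragment_id: "t" for i in items}
        )
        bd = call.breakdowns["t"]
        assert call.qual == pytest.approx(bd.SRQ + bd.RPQ + bd.ASQ + bd.RASQ + bd.CASQ + bd.IQ)
        assert bd.VF == len(items)

    def test_vf_counts_unique_fragments_once(self):
        """A fragment supporting directly and via assembly is one VF."""
        items = [sc_item("dual", 100), sc_item("other", 100)]
        contig = AssemblyContig(
            "ctg", "chr1", 100, HEAD, anchor_seq="A" * 30, breakend_seq="C" * 30,
            support={"dual": (1, 60)},
        )
        cand = _precise_candidate(100, 5000, items)
        cand.contigs.append(contig)
        cand.contig_homology["ctg"] = (31, 30)
        assert unique_fragments(cand) == {"dual", "other"}
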