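"""Aligner contract, compound realignment, split-bound adjustment and
exact/inexact homology, each checked against an independent oracle."""

import numpy as np
import pytest

from svkit.align_homology import (
    SeedAligner,
    adjust_split_bounds,
    compound_realign,
    exact_homology,
    inexact_homology,
)
from svkit.model import (
    HEAD,
    TAIL,
    AlignmentHit,
    AssemblyContig,
    Breakend,
    SplitAlignmentChain,
    revcomp,
)

from conftest import random_seq


def brute_force_best_score(query: str, ref: dict) -> float:
    """Independent oracle: best ungapped local alignment score over every
    diagonal of every chromosome and strand, +1/-4 scoring."""
    best = 0.0
    for q in (query, revcomp(query)):
        for seq in ref.values():
            for diag in range(-len(q) + 1, len(seq)):
                lo = max(0, -diag)
                hi = min(len(q), len(seq) - diag)
                cur = run_best = 0.0
                for i in range(lo, hi):
                    s = 1.0 if q[i] == seq[diag + i] else -4.0
                    cur = max(s, cur + s)
                    run_best = max(run_best, cur)
                best = max(best, run_best)
    return best


class TestAligner:
    def test_unique_substring_full_length_mapq60(self):
        ref = {"chr1": random_seq(5000, 1)}
        q = ref["chr1"][2000:2060]
        hits = SeedAligner().align(q, ref)
        top = hits[0]
        assert (top.query_lo, top.query_hi) == (1, 60)
        assert (top.ref_lo, top.ref_hi) == (2001, 2060)
        assert top.mapq == 60

    def test_duplicated_query_is_ambiguous(self):
        s = random_seq(300, 2)
        ref = {"chr1": s + random_seq(200, 3) + s}
        hits = SeedAligner().align(s[50:110], ref)
        assert hits[0].mapq < 20

    def test_one_mismatch_score(self):
        ref = {"chr1": random_seq(3000, 4)}
        q = list(ref["chr1"][1000:1060])
        q[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[30]]
        q = "".join(q)
        hits = SeedAligner().align(q, ref)
        # 59 matches - 4*1 mismatch; clipping of the mismatch scores 59-29=30
        # less, so the full-length diagonal run wins
        assert hits[0].score == 59 - 4

    def test_reverse_strand_hit(self):
        ref = {"chr1": random_seq(2000, 5)}
        q = revcomp(ref["chr1"][500:560])
        top = SeedAligner().align(q, ref)[0]
        assert top.strand == "-"
        assert (top.ref_lo, top.ref_hi) == (501, 560)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_top_score_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = {"chrA": random_seq(800, seed), "chrB": random_seq(600, seed + 100)}
        src = ref["chrA"] if rng.random() < 0.5 else ref["chrB"]
        start = int(rng.integers(0, len(src) - 80))
        q = list(src[start : start + 70])
        for _ in range(int(rng.integers(0, 3))):  # up to 2 mutations
            i = int(rng.integers(5, 65))
            q[i] = "ACGT"[int(rng.integers(0, 4))]
        q = "".join(q)
        hits = SeedAligner().align(q, ref)
        assert hits and hits[0].score == brute_force_best_score(q, ref)


def _contig(chrom, pos, direction, anchor, breakend, cid="c0"):
    return AssemblyContig(
        id=cid, chrom=chrom, pos=pos, dir=direction,
        anchor_seq=anchor, breakend_seq=breakend,
    )


class TestCompoundRealign:
    def test_two_segment_contig_gives_one_junction(self):
        ref = {"chr1": random_seq(6000, 21)}
        a = ref["chr1"][1000:1150]  # anchor ends at 1150
        b = ref["chr1"][4000:4100]
        contig = _contig("chr1", 1150, HEAD, a, b)
        chain = compound_realign(contig, SeedAligner(), ref)
        assert len(chain.hits) == 2
        hit_b = chain.hits[1]
        assert (hit_b.ref_lo, hit_b.ref_hi) == (4001, 4100)
        assert chain.gap_seq(0) == ""

    def test_novel_insert_between_segments(self):
        ref = {"chr1": random_seq(6000, 22)}
        a = ref["chr1"][1000:1150]
        ins = list(random_seq(25, 99))
        # boundary bases must not extend the flanking alignments
        ins[0] = next(c for c in "ACGT" if c != ref["chr1"][1150])
        ins[-1] = next(c for c in "ACGT" if c != ref["chr1"][3999])
        ins = "".join(ins)
        b = ref["chr1"][4000:4100]
        contig = _contig("chr1", 1150, HEAD, a, ins + b)
        chain = compound_realign(contig, SeedAligner(), ref)
        assert len(chain.hits) == 2
        assert chain.gap_seq(0) == ins

    def test_short_segments_left_as_insert(self):
        ref = {"chr1": random_seq(6000, 23)}
        a = ref["chr1"][1000:1150]
        b = ref["chr1"][4000:4025]  # 25 bp < 30 bp floor
        contig = _contig("chr1", 1150, HEAD, a, b)
        chain = compound_realign(contig, SeedAligner(), ref)
        assert len(chain.hits) == 1
        assert chain.unaligned == [(151, 175)]

    def test_origin_filter_discards_foreign_contig(self):
        ref = {"chr1": random_seq(6000, 24)}
        seq = ref["chr1"][3000:3200]
        contig = _contig("chr1", 50_000, HEAD, "", seq)  # claims a wrong origin
        assert compound_realign(contig, SeedAligner(), ref) is None


def _total_cost(chain, ref):
    """Edit distance of the chain to the reference: aligned mismatches plus
    unaligned (inserted) bases between hits."""
    cost = 0
    for h in chain.hits:
        for q in range(h.query_lo, h.query_hi + 1):
            if h.strand == "+":
                r = h.ref_lo + (q - h.query_lo)
                qb = chain.query[q - 1]
            else:
                r = h.ref_hi - (q - h.query_lo)
                qb = revcomp(chain.query[q - 1])
            if ref[h.chrom][r - 1] != qb:
                cost += 1
    for i in range(len(chain.hits) - 1):
        cost += len(chain.gap_seq(i))
    return cost


class TestAdjustSplitBounds:
    def _chain(self, ref, a_hit, b_hit, query):
        return SplitAlignmentChain("c", query, [a_hit, b_hit])

    def test_microhomology_split_leftmost(self):
        base = random_seq(3000, 31)
        hom = "GATC"  # shared flank: junction placement ambiguous over 4 bp
        left = base[:1000] + hom
        right = hom + base[2000:2500]
        ref = {"chr1": left + base[1200:1800] + right}
        n1 = len(left)
        r_start = n1 + 600  # where `right` begins (1-based: r_start+1)
        query = ref["chr1"][n1 - 104 : n1] + ref["chr1"][r_start : r_start + 100]
        # over-aligned initial split: give all homology bases to segment A
        a = AlignmentHit(1, 104, "chr1", n1 - 103, n1, "+", 104, 60)
        b = AlignmentHit(105, 204, "chr1", r_start + 1, r_start + 100, "+", 100, 60)
        chain = self._chain(ref, a, b, query)
        before = _total_cost(chain, ref)
        out = adjust_split_bounds(chain, ref)
        after = _total_cost(out, ref)
        assert after <= before
        # leftmost split: segment A retracts through the homology
        assert out.hits[0].query_hi <= 104

    def test_overaligned_terminal_mismatch_becomes_insert(self):
        ref = {"chr1": random_seq(3000, 32)}
        a_seq = ref["chr1"][1000:1100]
        b_seq = ref["chr1"][2000:2100]
        # 1 bp non-template base matching neither flanking reference base
        ins = next(c for c in "ACGT" if c not in (ref["chr1"][1100], ref["chr1"][1999]))
        query = a_seq + ins + b_seq
        # over-aligned: the inserted base was absorbed into segment A with a
        # terminal mismatch
        a = AlignmentHit(1, 101, "chr1", 1001, 1101, "+", 97, 60)
        b = AlignmentHit(102, 201, "chr1", 2001, 2100, "+", 100, 60)
        chain = self._chain(ref, a, b, query)
        out = adjust_split_bounds(chain, ref)
        assert out.hits[0].query_hi == 100
        assert out.gap_seq(0) == ins

    def test_blunt_junction_unchanged(self):
        ref = {"chr1": random_seq(3000, 33)}
        query = ref["chr1"][1000:1100] + ref["chr1"][2000:2100]
        a = AlignmentHit(1, 100, "chr1", 1001, 1100, "+", 100, 60)
        b = AlignmentHit(101, 200, "chr1", 2001, 2100, "+", 100, 60)
        out = adjust_split_bounds(self._chain(ref, a, b, query), ref)
        assert (out.hits[0].query_hi, out.hits[1].query_lo) == (100, 101)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_increases_edit_distance(self, seed):
        rng = np.random.default_rng(seed)
        ref = {"chr1": random_seq(4000, 200 + seed)}
        p1 = int(rng.integers(500, 1200))
        p2 = int(rng.integers(2000, 3000))
        query = ref["chr1"][p1 - 100 : p1] + ref["chr1"][p2 : p2 + 100]
        shift = int(rng.integers(0, 4))
        a = AlignmentHit(1, 100 + shift, "chr1", p1 - 99, p1 + shift, "+", 90, 60)
        b = AlignmentHit(101 + shift, 200, "chr1", p2 + 1 + shift, p2 + 100, "+", 90, 60)
        chain = SplitAlignmentChain("c", query, [a, b])
        before = _total_cost(chain, ref)
        after = _total_cost(adjust_split_bounds(chain, ref), ref)
        assert after <= before


def deletion_homology_oracle(ref_seq: str, del_start: int, del_len: int):
    """Enumerate all equal-length deletions producing the same alternate
    sequence (1-based del_start = first deleted base)."""
    alt = ref_seq[: del_start - 1] + ref_seq[del_start - 1 + del_len :]
    placements = []
    for s in range(1, len(ref_seq) - del_len + 2):
        if ref_seq[: s - 1] + ref_seq[s - 1 + del_len :] == alt:
            placements.append(s)
    return placements


class TestExactHomology:
    def test_deletion_with_3bp_homology_worked_example(self):
        ref = {"chr1": "TTTTGATCCCCGATAAAA"}
        # delete bases 8..14 ("CCCCGAT"); "GAT" homology allows 4 placements
        placements = deletion_homology_oracle(ref["chr1"], 8, 7)
        assert len(placements) == 4
        b1 = Breakend("chr1", 7, HEAD)
        b2 = Breakend("chr1", 15, TAIL)
        n_l, n_r, homseq = exact_homology(b1, b2, "", ref)
        assert n_l + n_r == 3
        assert n_l + n_r == max(placements) - min(placements)
        assert len(homseq) == 3

    def test_blunt_junction_no_homology(self):
        ref = {"chr1": random_seq(2000, 41), "chr2": random_seq(2000, 42)}
        b1 = Breakend("chr1", 800, HEAD)
        b2 = Breakend("chr2", 1200, TAIL)
        n_l, n_r, homseq = exact_homology(b1, b2, "", ref)
        assert (n_l + n_r) <= 1  # random flanks share at most a base by chance

    def test_tandem_duplication_inside_repeat(self):
        unit = random_seq(12, 43)
        ref = {"chr1": random_seq(500, 44) + unit * 4 + random_seq(500, 45)}
        # duplication junction placed at the end of the repeat tract:
        # HEAD at the last base of unit 3, TAIL at the start of unit 2
        start = 500 + 12  # 1-based start of unit 2
        b1 = Breakend("chr1", 500 + 36, HEAD)
        b2 = Breakend("chr1", start + 1, TAIL)
        n_l, n_r, _ = exact_homology(b1, b2, "", ref)
        assert n_l + n_r >= 12  # at least one full unit of homology

    def test_insert_suppresses_homology(self):
        ref = {"chr1": random_seq(2000, 46)}
        n_l, n_r, homseq = exact_homology(
            Breakend("chr1", 700, HEAD), Breakend("chr1", 900, TAIL), "ACGT", ref
        )
        assert (n_l, n_r, homseq) == (0, 0, "")

    def test_symmetry_between_breakends(self):
        ref = {"chr1": "A" * 4 + "GATTACA" + "C" * 6 + "GATTACA" + "T" * 5}
        b1 = Breakend("chr1", 11, HEAD)  # after first GATTACA
        b2 = Breakend("chr1", 25, TAIL)
        f_l, f_r, _ = exact_homology(b1, b2, "", ref)
        r_l, r_r, _ = exact_homology(b2, b1, "", ref)
        assert (f_l, f_r) == (r_r, r_l)


def sw_extension_oracle(query, ref, match=1, mismatch=-4, gap_open=6, gap_extend=1):
    """Plain nested-loop affine-gap DP; furthest query row whose best score
    stays positive."""
    m, n = len(query), len(ref)
    NEG = float("-inf")
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        H[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, m + 1):
        H[i][0] = -(gap_open + gap_extend * i)
    furthest = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            sub = H[i - 1][j - 1] + (match if query[i - 1] == ref[j - 1] else mismatch)
            H[i][j] = max(sub, E[i][j], F[i][j])
        if max(H[i][1:]) > 0:
            furthest = i
    return furthest


class TestInexactHomology:
    def _junction_ref(self, hom_len, seed, mismatch_at=None):
        """Reference with two loci sharing `hom_len` bases after the break."""
        a = random_seq(800, seed)
        b = random_seq(800, seed + 1)
        shared = random_seq(hom_len, seed + 2)
        chr1 = a + shared + random_seq(400, seed + 3)
        b_shared = list(shared)
        if mismatch_at is not None and hom_len:
            b_shared[mismatch_at] = {"A": "G", "C": "T", "G": "A", "T": "C"}[
                b_shared[mismatch_at]
            ]
        chr2 = b + "".join(b_shared) + random_seq(400, seed + 4)
        ref = {"chr1": chr1, "chr2": chr2}
        b1 = Breakend("chr1", 800, HEAD)
        b2 = Breakend("chr2", 801, TAIL)
        return ref, b1, b2

    def test_exact_homology_contained(self):
        ref, b1, b2 = self._junction_ref(5, 50)
        # exact 5 bp shared: junction placed at chr1:800 / chr2:801... the
        # shared bases sit on both sides, giving exact homology 5
        n_l, n_r, _ = exact_homology(b1, b2, "", ref)
        il, ir = inexact_homology(b1, b2, "", ref)
        assert il + ir >= n_l + n_r
        assert ir >= 5

    def test_matches_direct_sw_oracle_through_mismatch(self):
        ref, b1, b2 = self._junction_ref(9, 60, mismatch_at=4)
        il, ir = inexact_homology(b1, b2, "", ref)
        # right side: breakpoint continuation (chr2 side) vs chr1 reference
        bp_seq = ref["chr2"][800:1100]
        ref_seq = ref["chr1"][800:1110]
        assert ir == sw_extension_oracle(bp_seq, ref_seq)

    def test_random_flanks_negligible_homology(self):
        """Unrelated flanks: the extension dies within a few bases (a
        chance-matching leading base can give width 1-2, never more)."""
        widths = []
        for seed in range(100, 200):
            ref, b1, b2 = self._junction_ref(0, seed)
            il, ir = inexact_homology(b1, b2, "", ref)
            widths.append(il + ir)
        assert np.mean(widths) < 1.5
        assert np.mean([w <= 2 for w in widths]) > 0.9
        assert max(widths) < 10

    @pytest.mark.parametrize("seed", [300, 301, 302, 303])
    def test_ihompos_contains_cipos(self, seed):
        rng = np.random.default_rng(seed)
        hom = int(rng.integers(0, 12))
        ref, b1, b2 = self._junction_ref(hom, seed)
        n_l, n_r, _ = exact_homology(b1, b2, "", ref)
        il, ir = inexact_homology(b1, b2, "", ref)
        assert il >= n_l and ir >= n_r
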