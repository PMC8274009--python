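"""Alignment engine and breakpoint homology computation.

The built-in aligner is a seeded exact-match + ungapped-extension engine
adequate for the small synthetic references this toolkit targets; an
external aligner can be plugged in by providing any object with the same
``align(query, reference)`` contract.  Alignments carry no clipping
penalty, and the effective mapping quality encodes placement uniqueness:
60 when the best hit clearly beats the runner-up, 0 when tied.

Homology: ``exact_homology`` finds the maximal interval of junction
placements that produce an identical derivative sequence (CIPOS/HOMLEN);
``inexact_homology`` measures how far a Smith-Waterman alignment (scores
+1 match, -4 mismatch, 6 gap open, 1 gap extend) can be extended from the
common flank into the partner sequence (IHOMPOS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    HEAD,
    TAIL,
    AlignmentHit,
    AssemblyContig,
    Breakend,
    SplitAlignmentChain,
    revcomp,
)

MIN_SEGMENT_BP = 30  # shorter segments are not uniquely alignable
MIN_MAPQ = 20
SW_MATCH, SW_MISMATCH, SW_GAP_OPEN, SW_GAP_EXTEND = 1, -4, 6, 1
HOM_FLANK = 300
HOM_REF_EXTRA = 10
MAX_HOMOLOGY = 2000

Reference = dict  # chrom -> sequence (str), 1-based access via seq[pos-1]


def ref_base(ref: Reference, chrom: str, pos: int) -> Optional[str]:
    seq = ref.get(chrom)
    if seq is None or pos < 1 or pos > len(seq):
        return None
    return seq[pos - 1]


def load_fasta(path: str) -> Reference:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


class SeedAligner:
    """Seeded exact-match aligner with ungapped diagonal extension.

    Finds candidate diagonals from exact seed occurrences (query prefix,
    middle and suffix), scores each diagonal with +1/-4 unit scoring and
    trims to the maximal-scoring run (no clipping penalty).
    """

    def __init__(self, seed_len: int = 16, mapq_margin: float = 1.0):
        self.seed_len = seed_len
        self.mapq_margin = mapq_margin

    def align(self, query: str, reference: Reference) -> list[AlignmentHit]:
        query = query.upper()
        if not query:
            return []
        hits: dict[tuple[str, str, int], AlignmentHit] = {}
        for strand, q in (("+", query), ("-", revcomp(query))):
            for chrom, seq in reference.items():
                for diag in self._candidate_diagonals(q, seq):
                    hit = self._extend(q, seq, chrom, strand, diag)
                    if hit is None:
                        continue
                    key = (chrom, strand, diag)
                    if key not in hits or hit.score > hits[key].score:
                        hits[key] = hit
        out = sorted(
            hits.values(), key=lambda h: (-h.score, h.chrom, h.ref_lo, h.strand)
        )
        self._assign_mapq(out)
        return out

    def _candidate_diagonals(self, q: str, seq: str) -> set[int]:
        s = min(self.seed_len, len(q))
        offsets = {0, max(0, (len(q) - s) // 2), len(q) - s}
        diags: set[int] = set()
        for off in offsets:
            seed = q[off : off + s]
            start = seq.find(seed)
            while start != -1:
                diags.add(start - off)
                start = seq.find(seed, start + 1)
        return diags

    def _extend(
        self, q: str, seq: str, chrom: str, strand: str, diag: int
    ) -> Optional[AlignmentHit]:
        """Best-scoring contiguous run of the query along one diagonal
        (maximal-sum subarray of per-base +1/-4 scores)."""
        lo = max(0, -diag)
        hi = min(len(q), len(seq) - diag)
        if hi - lo < 1:
            return None
        best = cur = 0.0
        best_range = (lo, lo)
        cur_start = lo
        for i in range(lo, hi):
            s = SW_MATCH if q[i] == seq[diag + i] else SW_MISMATCH
            if cur <= 0:
                cur = s
                cur_start = i
            else:
                cur += s
            if cur > best:
                best = cur
                best_range = (cur_start, i + 1)
        if best <= 0:
            return None
        qlo, qhi = best_range  # 0-based half-open on strand-oriented query
        if strand == "+":
            query_lo, query_hi = qlo + 1, qhi
        else:  # map back to original query coordinates
            query_lo, query_hi = len(q) - qhi + 1, len(q) - qlo
        return AlignmentHit(
            query_lo=query_lo,
            query_hi=query_hi,
            chrom=chrom,
            ref_lo=diag + qlo + 1,
            ref_hi=diag + qhi,
            strand=strand,
            score=best,
            mapq=0,
        )

    def _assign_mapq(self, hits: list[AlignmentHit]) -> None:
        """Placement uniqueness of the top hit: 60 * (1 - second/best),
        competing only against hits covering substantially the same query
        interval (hits to other parts of a chimeric query do not count)."""
        if not hits:
            return
        top = hits[0]
        second = 0.0
        for h in hits[1:]:
            ov = min(top.query_hi, h.query_hi) - max(top.query_lo, h.query_lo) + 1
            if ov >= 0.5 * min(top.query_len, h.query_len):
                second = h.score
                break
        mapq = int(round(60.0 * max(0.0, 1.0 - second / top.score))) if top.score > 0 else 0
        top.mapq = min(60, max(0, mapq))
        for h in hits[1:]:
            h.mapq = 0


def compound_realign(
    contig: AssemblyContig,
    aligner,
    reference: Reference,
    min_segment: int = MIN_SEGMENT_BP,
    origin_slack: int = 100,
) -> Optional[SplitAlignmentChain]:
    """Iteratively realign a contig into a split-alignment chain.

    Unaligned bases from each round are fed back until everything is
    aligned or no confident alignment remains.  Segments shorter than
    ``min_segment`` stay unaligned (insert sequence).  Chains with no
    segment partially aligning to the contig's originating locus on the
    forward strand are discarded.
    """
    query = contig.sequence
    hits: list[AlignmentHit] = []
    unaligned: list[tuple[int, int]] = []
    bealn: list[AlignmentHit] = []
    # the anchor placement is known by construction: seed the chain with it
    # and feed only the soft-clipped (breakend) bases to the aligner
    a_len = len(contig.anchor_seq)
    if a_len > 0:
        if contig.dir.value == "+":  # HEAD: anchor first
            anchor_hit = AlignmentHit(
                1, a_len, contig.chrom,
                contig.pos - a_len + 1, contig.pos, "+", float(a_len), 60,
            )
            pending = [(a_len + 1, len(query))] if len(query) > a_len else []
        else:
            b_len = len(query) - a_len
            anchor_hit = AlignmentHit(
                b_len + 1, len(query), contig.chrom,
                contig.pos, contig.pos + a_len - 1, "+", float(a_len), 60,
            )
            pending = [(1, b_len)] if b_len else []
        hits.append(anchor_hit)
    else:
        pending = [(1, len(query))]
    while pending:
        pending.sort(key=lambda seg: seg[0] - seg[1])  # largest first
        lo, hi = pending.pop(0)
        if hi - lo + 1 < min_segment:
            unaligned.append((lo, hi))
            continue
        seg_hits = aligner.align(query[lo - 1 : hi], reference)
        if not seg_hits or seg_hits[0].mapq < MIN_MAPQ:
            unaligned.append((lo, hi))
            bealn.extend(_offset_hit(h, lo - 1) for h in seg_hits[:8])
            continue
        h = _offset_hit(seg_hits[0], lo - 1)
        hits.append(h)
        if h.query_lo - lo >= 1:
            pending.append((lo, h.query_lo - 1))
        if hi - h.query_hi >= 1:
            pending.append((h.query_hi + 1, hi))
    if not hits:
        return None
    hits.sort(key=lambda h: h.query_lo)
    chain = SplitAlignmentChain(
        contig_id=contig.id,
        query=query,
        hits=hits,
        unaligned=sorted(unaligned),
    )
    chain.bealn = bealn  # type: ignore[attr-defined]
    if not _overlaps_origin(chain, contig, origin_slack):
        return None
    return chain


def _offset_hit(h: AlignmentHit, query_offset: int) -> AlignmentHit:
    return AlignmentHit(
        query_lo=h.query_lo + query_offset,
        query_hi=h.query_hi + query_offset,
        chrom=h.chrom,
        ref_lo=h.ref_lo,
        ref_hi=h.ref_hi,
        strand=h.strand,
        score=h.score,
        mapq=h.mapq,
    )


def _overlaps_origin(
    chain: SplitAlignmentChain, contig: AssemblyContig, slack: int
) -> bool:
    anchor_lo = contig.pos - len(contig.anchor_seq) - slack
    anchor_hi = contig.pos + len(contig.anchor_seq) + slack
    for h in chain.hits:
        if (
            h.chrom == contig.chrom
            and h.strand == "+"
            and h.ref_lo <= anchor_hi
            and h.ref_hi >= anchor_lo
        ):
            return True
    return False


def adjust_split_bounds(
    chain: SplitAlignmentChain, reference: Reference, window: int = 20
) -> SplitAlignmentChain:
    """Move each query split point to minimise the edit distance of the
    chain to the reference.

    Candidates slide both segment ends within ``window`` bases.  Cost is
    lexicographic (edit distance, mismatching aligned bases, left query
    end, right query start): ties prefer converting a terminal mismatch
    into inserted sequence and then the leftmost split.
    """
    if len(chain.hits) < 2:
        return chain
    for i in range(len(chain.hits) - 1):
        a, b = chain.hits[i], chain.hits[i + 1]
        best: Optional[tuple] = None
        best_pair = (a.query_hi, b.query_lo)
        for qa in range(a.query_hi - window, a.query_hi + window + 1):
            if qa < a.query_lo or qa > len(chain.query):
                continue
            cost_a, ok_a = _end_cost(chain.query, a, qa, reference, left_end=False)
            if not ok_a:
                continue
            for qb in range(
                max(qa + 1, b.query_lo - window), b.query_lo + window + 1
            ):
                if qb > b.query_hi:
                    continue
                cost_b, ok_b = _end_cost(chain.query, b, qb, reference, left_end=True)
                if not ok_b:
                    continue
                ins = qb - qa - 1
                mism = cost_a + cost_b
                key = (mism + ins, mism, qa, qb)
                if best is None or key < best:
                    best = key
                    best_pair = (qa, qb)
        qa, qb = best_pair
        chain.hits[i] = _retrim(a, new_query_hi=qa)
        chain.hits[i + 1] = _retrim(b, new_query_lo=qb)
    return chain


def _end_cost(
    query: str, hit: AlignmentHit, new_end: int, reference: Reference, left_end: bool
) -> tuple[int, bool]:
    """Cost delta of moving one end of ``hit`` to ``new_end``.

    Retraction removes formerly-aligned mismatches (negative cost);
    extension is only permitted over exactly-matching bases -- a split
    point never migrates into non-matching (inserted) sequence."""
    cost = 0
    if left_end:
        rng = range(new_end, hit.query_lo)  # extension leftwards
    else:
        rng = range(hit.query_hi + 1, new_end + 1)  # extension rightwards
    for q in rng:
        r = _diag_ref_pos(hit, q)
        base = ref_base(reference, hit.chrom, r)
        if base is None:
            return 0, False
        qbase = query[q - 1]
        if hit.strand == "-":
            qbase = revcomp(qbase)
        if qbase != base:
            return 0, False
    # mismatches already inside the alignment that remain: count those in the
    # retained interval next to this end is unnecessary -- they are shared by
    # all candidates; only the delta matters.  But retracting over a
    # mismatching base *removes* its cost:
    if left_end:
        rng2 = range(hit.query_lo, min(new_end, hit.query_hi + 1))
    else:
        rng2 = range(max(new_end + 1, hit.query_lo), hit.query_hi + 1)
    for q in rng2:
        r = _diag_ref_pos(hit, q)
        base = ref_base(reference, hit.chrom, r)
        qbase = query[q - 1]
        if hit.strand == "-":
            qbase = revcomp(qbase)
        if base is not None and qbase != base:
            cost -= 1
    return cost, True


def _diag_ref_pos(hit: AlignmentHit, q: int) -> int:
    if hit.strand == "+":
        return hit.ref_lo + (q - hit.query_lo)
    return hit.ref_hi - (q - hit.query_lo)


def _retrim(
    hit: AlignmentHit,
    new_query_lo: Optional[int] = None,
    new_query_hi: Optional[int] = None,
) -> AlignmentHit:
    qlo = hit.query_lo if new_query_lo is None else new_query_lo
    qhi = hit.query_hi if new_query_hi is None else new_query_hi
    if hit.strand == "+":
        ref_lo = hit.ref_lo + (qlo - hit.query_lo)
        ref_hi = hit.ref_hi + (qhi - hit.query_hi)
    else:
        ref_hi = hit.ref_hi - (qlo - hit.query_lo)
        ref_lo = hit.ref_lo - (qhi - hit.query_hi)
    return AlignmentHit(
        query_lo=qlo, query_hi=qhi, chrom=hit.chrom,
        ref_lo=ref_lo, ref_hi=ref_hi, strand=hit.strand,
        score=hit.score, mapq=hit.mapq,
    )


# --------------------------------------------------------------------------
# homology


def _junction_accessors(b1: Breakend, b2: Breakend, ref: Reference):
    """Base accessors around a junction written as left-side ``b1`` joined
    to right-side ``b2`` in derivative orientation.

    Returns four functions of i >= 1:

    * ``cont1(i)`` -- side-1 reference base i positions past the junction;
    * ``end1(i)``  -- side-1 anchored base i positions before the junction;
    * ``b_side(i)`` -- derivative base i positions after the junction
      (from side 2);
    * ``pre2(i)``  -- side-2 reference base i positions before its breakend.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def g(chrom: str, pos: int) -> Optional[str]:
        return ref_base(ref, chrom, pos)

    if b1.dir is HEAD:
        cont1 = lambda i: g(b1.chrom, b1.pos + i)
        end1 = lambda i: g(b1.chrom, b1.pos - i + 1)
    else:  # derivative traverses side 1 reverse-complemented
        cont1 = lambda i: _c(g(b1.chrom, b1.pos - i), comp)
        end1 = lambda i: _c(g(b1.chrom, b1.pos + i - 1), comp)
    if b2.dir is TAIL:
        b_side = lambda i: g(b2.chrom, b2.pos + i - 1)
        pre2 = lambda i: g(b2.chrom, b2.pos - i)
    else:  # side 2 entered reverse-complemented
        b_side = lambda i: _c(g(b2.chrom, b2.pos - i + 1), comp)
        pre2 = lambda i: _c(g(b2.chrom, b2.pos + i), comp)
    return cont1, end1, b_side, pre2


def _c(base: Optional[str], comp: dict) -> Optional[str]:
    return None if base is None else comp.get(base, "N")


def exact_homology(
    b1: Breakend,
    b2: Breakend,
    insert_seq: str,
    ref: Reference,
    max_hom: int = MAX_HOMOLOGY,
) -> tuple[int, int, str]:
    """Maximal junction-placement interval producing an identical alternate
    sequence.

    Returns ``(n_left, n_right, homseq)``: the junction may slide n_left
    bases left and n_right right (in derivative orientation) of its given
    placement.  Junctions with inserted sequence have no exact homology.
    """
    if insert_seq:
        return 0, 0, ""
    cont1, end1, b_side, pre2 = _junction_accessors(b1, b2, ref)
    n_r = 0
    while n_r < max_hom:
        x, y = cont1(n_r + 1), b_side(n_r + 1)
        if x is None or y is None or x != y:
            break
        n_r += 1
    n_l = 0
    while n_l < max_hom:
        x, y = end1(n_l + 1), pre2(n_l + 1)
        if x is None or y is None or x != y:
            break
        n_l += 1
    # derivative bases spanning the slide window; reconstruct from side 2
    homseq = "".join(
        b_side(i) or "N" for i in range(-(n_l - 1), n_r + 1)
    ) if (n_l + n_r) else ""
    return n_l, n_r, homseq


def _extension_length(query: Sequence[str], ref: Sequence[str]) -> int:
    """How far an affine-gap alignment anchored at the common flank can be
    extended into ``query``: the furthest query index whose best running
    score stays positive (scores +1/-4/6/1)."""
    m, n = len(query), len(ref)
    if m == 0 or n == 0:
        return 0
    neg = -1e9
    H = np.full(n + 1, neg)
    E = np.full(n + 1, neg)  # gap in query (ref consumed)
    H[0] = 0.0
    for j in range(1, n + 1):
        H[j] = -(SW_GAP_OPEN + SW_GAP_EXTEND * j)
    furthest = 0
    F_col = np.full(n + 1, neg)
    for i in range(1, m + 1):
        prev = H.copy()
        H[0] = -(SW_GAP_OPEN + SW_GAP_EXTEND * i)
        F_col[0] = neg
        qc = query[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (SW_MATCH if qc == ref[j - 1] else SW_MISMATCH)
            E[j] = max(E[j] - SW_GAP_EXTEND, prev[j] - SW_GAP_OPEN - SW_GAP_EXTEND)
            F_col[j] = max(
                F_col[j - 1] - SW_GAP_EXTEND, H[j - 1] - SW_GAP_OPEN - SW_GAP_EXTEND
            )
            H[j] = max(sub, E[j], F_col[j])
        if H[1:].max() > 0:
            furthest = i
    return furthest


def inexact_homology(
    b1: Breakend,
    b2: Breakend,
    insert_seq: str,
    ref: Reference,
    flank: int = HOM_FLANK,
) -> tuple[int, int]:
    """Inexact homology interval (IHOMPOS) around the junction at ``b1``.

    The breakpoint sequence on the far side of the junction is aligned
    against this breakend's reference continuation (and mirrored for the
    left side); the reference is extended ``HOM_REF_EXTRA`` bp beyond the
    breakpoint-sequence window to absorb indels.
    """
    cont1, end1, b_side, pre2 = _junction_accessors(b1, b2, ref)
    ins = list(insert_seq.upper())

    def take(fn, n: int) -> list[str]:
        out = []
        for i in range(1, n + 1):
            x = fn(i)
            if x is None:
                break
            out.append(x)
        return out

    # right: breakpoint sequence past the junction (insert then side-2)
    # vs side-1 reference continuation
    bp_right = (ins + take(b_side, flank))[:flank]
    ref_right = take(cont1, flank + HOM_REF_EXTRA)
    n_r = _extension_length(bp_right, ref_right)
    # left: breakpoint sequence before the junction (side-1 anchor, read
    # outward) vs side-2 reference before its breakend
    bp_left = take(end1, flank)
    ref_left = take(pre2, flank + HOM_REF_EXTRA)
    n_l = _extension_length(bp_left, ref_left)
    return n_l, n_r
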