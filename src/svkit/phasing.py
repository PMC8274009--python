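"""SV phasing: assembly cis/trans links, transitive call collapsing, and
phasability statistics.

Two junctions are phased *cis* when one assembly contig spans both, and
*trans* when a contig supports one junction while aligning to the
reference across the other's locus.  Imprecise spanning calls whose
breakends match the termini of a short chain of precise breakpoints are
*transitive* calls: artefacts of fragments jumping the intervening DNA
segments, collapsed onto the underlying chain.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    HEAD,
    TAIL,
    Breakend,
    BreakpointCall,
    CallBase,
    Direction,
    LinkKind,
    PhaseLink,
    SingleBreakendCall,
    SplitAlignmentChain,
)

log = logging.getLogger(__name__)

SC_TRANS_MARGIN = 10  # bp of anchoring support beyond a neighbour's junction
TRANSITIVE_MAX_TOTAL = 1000
TRANSITIVE_MAX_SEGMENTS = 4
TRANSITIVE_MIN_SEGMENT = 20
TRANSITIVE_MAX_PATHS = 100_000
TRANSITIVE_MAX_PATHS_PER_START = 1000


def assembly_links(
    chains_with_calls: Sequence[tuple[SplitAlignmentChain, list[Optional[str]]]],
    calls: Sequence[CallBase],
) -> list[PhaseLink]:
    """Phase links implied by compound-realigned assembly contigs.

    A chain with >= 3 non-overlapping alignments phases its adjacent
    breakpoints cis (n-2 links sharing the contig id).  A chain supporting
    junction X whose alignments span reference across another call Y's
    locus (>= 10 bp each side) phases X and Y trans.
    """
    links: list[PhaseLink] = []
    by_id = {c.id: c for c in calls}
    for chain, junction_calls in chains_with_calls:
        called = [cid for cid in junction_calls if cid is not None]
        if len(chain.hits) >= 3:
            for i in range(len(junction_calls) - 1):
                a, b = junction_calls[i], junction_calls[i + 1]
                if a is None or b is None or a == b:
                    continue
                links.append(
                    PhaseLink(
                        LinkKind.ASSEMBLY_CIS,
                        (a, b),
                        link_id=f"{chain.contig_id}.cis{i}",
                        provenance=chain.contig_id,
                    )
                )
        # trans: reference-supporting span across another call's breakend
        chain_set = set(called)
        for other in calls:
            if other.id in chain_set or not isinstance(other, BreakpointCall):
                continue
            for be in (other.b1, other.b2):
                if _chain_spans(chain, be):
                    for cid in called:
                        links.append(
                            PhaseLink(
                                LinkKind.ASSEMBLY_TRANS,
                                (cid, other.id),
                                link_id=f"{chain.contig_id}.trans.{other.id}",
                                provenance=chain.contig_id,
                            )
                        )
                    break
    return _dedupe(links)


def _chain_spans(chain: SplitAlignmentChain, be: Breakend, margin: int = SC_TRANS_MARGIN) -> bool:
    for h in chain.hits:
        if h.chrom == be.chrom and h.ref_lo <= be.pos - margin and h.ref_hi >= be.pos + margin:
            return True
    return False


def sc_trans_links(
    calls: Sequence[CallBase],
    anchor_extent: dict[str, tuple[str, int, int]],
    neighbourhood: int,
) -> list[PhaseLink]:
    """Trans links from anchoring support: a call whose anchoring reads
    extend >= 10 bp past a nearby call's junction cannot share a derivative
    molecule with it at that junction."""
    links: list[PhaseLink] = []
    ids = [c.id for c in calls if c.id in anchor_extent]
    for i, a in enumerate(ids):
        chrom_a, lo_a, hi_a = anchor_extent[a]
        for b in ids[i + 1 :]:
            chrom_b, lo_b, hi_b = anchor_extent[b]
            if chrom_a != chrom_b:
                continue
            pos_a = _junction_pos(next(c for c in calls if c.id == a), chrom_a)
            pos_b = _junction_pos(next(c for c in calls if c.id == b), chrom_b)
            if pos_a is None or pos_b is None or abs(pos_a - pos_b) > neighbourhood:
                continue
            a_past_b = lo_a <= pos_b - SC_TRANS_MARGIN and hi_a >= pos_b + SC_TRANS_MARGIN
            b_past_a = lo_b <= pos_a - SC_TRANS_MARGIN and hi_b >= pos_a + SC_TRANS_MARGIN
            if a_past_b or b_past_a:
                links.append(
                    PhaseLink(LinkKind.SC_TRANS, (a, b), link_id=f"sc.{a}.{b}")
                )
    return _dedupe(links)


def _junction_pos(call: CallBase, chrom: str) -> Optional[int]:
    if isinstance(call, BreakpointCall):
        if call.b1.chrom == chrom:
            return call.b1.pos
        if call.b2.chrom == chrom:
            return call.b2.pos
    elif isinstance(call, SingleBreakendCall) and call.be.chrom == chrom:
        return call.be.pos
    return None


# --------------------------------------------------------------------------
# transitive collapsing


@dataclass
class TransitivePath:
    breakpoints: list[str]  # ordered precise call ids
    segment_lengths: list[int]

    @property
    def total(self) -> int:
        return sum(self.segment_lengths)

    def validate(self) -> None:
        assert self.total <= TRANSITIVE_MAX_TOTAL
        assert 1 <= len(self.segment_lengths) <= TRANSITIVE_MAX_SEGMENTS
        assert all(s >= TRANSITIVE_MIN_SEGMENT for s in self.segment_lengths)
        assert len(set(self.breakpoints)) == len(self.breakpoints)


def _be_interval(call: BreakpointCall, which: int) -> tuple[str, int, int, Direction]:
    if which == 0:
        b, ci = call.b1, call.cipos
    else:
        b, ci = call.b2, call.cirpos
    return (b.chrom, b.pos + ci[0], b.pos + ci[1], b.dir)


def _overlap(iv: tuple[str, int, int, Direction], b: Breakend) -> bool:
    chrom, lo, hi, d = iv
    return b.chrom == chrom and d is b.dir and lo <= b.pos <= hi


def transitive_collapse(
    calls: Sequence[BreakpointCall],
    max_total: int = TRANSITIVE_MAX_TOTAL,
    max_segments: int = TRANSITIVE_MAX_SEGMENTS,
    min_segment: int = TRANSITIVE_MIN_SEGMENT,
    max_paths: int = TRANSITIVE_MAX_PATHS,
    max_paths_per_start: int = TRANSITIVE_MAX_PATHS_PER_START,
) -> tuple[list[PhaseLink], list[str]]:
    """Collapse imprecise transitive calls onto chains of precise
    breakpoints.

    Breadth-first search over the breakpoint graph from each imprecise
    call's first breakend, traversing precise junctions and walking the
    anchored DNA between them; a path terminates when the partner breakend
    of the last junction lands inside the imprecise call's other breakend
    interval.  Paths are limited to ``max_total`` bp and ``max_segments``
    segments of at least ``min_segment`` bp, may not self-intersect, and
    search is budgeted globally and per start.  Expansion order is by
    leftmost coordinate, so results are deterministic.
    """
    precise = [c for c in calls if c.precise]
    imprecise = [c for c in calls if not c.precise]
    links: list[PhaseLink] = []
    collapsed: list[str] = []
    total_paths = 0
    for imp in imprecise:
        start_iv = _be_interval(imp, 0)
        end_iv = _be_interval(imp, 1)
        found: Optional[TransitivePath] = None
        paths_here = 0
        # frontier entries: (current partner breakend, path, segment lengths)
        frontier: list[tuple[Breakend, list[str], list[int]]] = []
        for pc in precise:
            for which in (0, 1):
                b_near = pc.b1 if which == 0 else pc.b2
                b_far = pc.b2 if which == 0 else pc.b1
                if _overlap(start_iv, b_near):
                    frontier.append((b_far, [pc.id], []))
        frontier.sort(key=lambda t: (t[0].chrom, t[0].pos))
        while frontier and found is None:
            if total_paths >= max_paths or paths_here >= max_paths_per_start:
                log.warning("transitive path budget exhausted; partial result")
                break
            v, path, segs = frontier.pop(0)
            total_paths += 1
            paths_here += 1
            if _overlap(end_iv, v) and segs:
                cand = TransitivePath(path, segs)
                if cand.total <= max_total:
                    found = cand
                    break
            if len(segs) >= max_segments:
                continue
            nxt = []
            for pc in precise:
                if pc.id in path:
                    continue
                for which in (0, 1):
                    w = pc.b1 if which == 0 else pc.b2
                    far = pc.b2 if which == 0 else pc.b1
                    seg = _segment_len(v, w)
                    if seg is None or seg < min_segment:
                        continue
                    if sum(segs) + seg > max_total:
                        continue
                    nxt.append((far, path + [pc.id], segs + [seg]))
            nxt.sort(key=lambda t: (t[0].chrom, t[0].pos))
            frontier.extend(nxt)
        if found is not None:
            found.validate()
            collapsed.append(imp.id)
            for i in range(len(found.breakpoints) - 1):
                links.append(
                    PhaseLink(
                        LinkKind.TRANSITIVE,
                        (found.breakpoints[i], found.breakpoints[i + 1]),
                        link_id=f"trs.{imp.id}.{i}",
                        provenance=imp.id,
                    )
                )
    return _dedupe(links), collapsed


def _segment_len(v: Breakend, w: Breakend) -> Optional[int]:
    """Length of anchored DNA between partner breakend ``v`` and the next
    junction breakend ``w`` (facing orientations), or None."""
    if v.chrom != w.chrom:
        return None
    if v.dir is HEAD and w.dir is TAIL and w.pos <= v.pos:
        return v.pos - w.pos
    if v.dir is TAIL and w.dir is HEAD and w.pos >= v.pos:
        return w.pos - v.pos
    return None


def _dedupe(links: list[PhaseLink]) -> list[PhaseLink]:
    seen = set()
    out = []
    for l in links:
        key = (l.kind, tuple(sorted(l.members)))
        if key in seen:
            continue
        seen.add(key)
        out.append(l)
    return out


# --------------------------------------------------------------------------
# phasability


def phasability(
    breakends: Sequence[Breakend], max_phase_distance: int
) -> tuple[list[float], float]:
    """Per-breakend length of the DNA segment to the first facing junction,
    and the fraction of breakends phaseable within ``max_phase_distance``.

    A HEAD breakend at p pairs with the nearest TAIL breakend at q <= p
    (shared anchored segment [q, p]); mirrored for TAIL.
    """
    by_chrom: dict[str, list[Breakend]] = defaultdict(list)
    for b in breakends:
        by_chrom[b.chrom].append(b)
    dists: list[float] = []
    for chrom, bes in by_chrom.items():
        heads = sorted(b.pos for b in bes if b.dir is HEAD)
        tails = sorted(b.pos for b in bes if b.dir is TAIL)
        import bisect

        for b in bes:
            if b.dir is HEAD:
                i = bisect.bisect_right(tails, b.pos)
                d = b.pos - tails[i - 1] if i > 0 else float("inf")
            else:
                i = bisect.bisect_left(heads, b.pos)
                d = heads[i] - b.pos if i < len(heads) else float("inf")
            dists.append(d)
    frac = (
        sum(1 for d in dists if d <= max_phase_distance) / len(dists)
        if dists
        else float("nan")
    )
    return dists, frac


def expected_phasability(
    n_junctions: int,
    genome_length: int,
    max_phase_distance: int,
    n_sims: int = 20,
    seed: int = 0,
) -> float:
    """Baseline phasability under uniformly random junction placement
    (each junction contributes one HEAD and one TAIL breakend), estimated
    by simulation; the closed form is 1 - exp(-n*d/L)."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_sims):
        bes = [
            Breakend("sim", int(p), HEAD)
            for p in rng.integers(1, genome_length + 1, size=n_junctions)
        ] + [
            Breakend("sim", int(p), TAIL)
            for p in rng.integers(1, genome_length + 1, size=n_junctions)
        ]
        fracs.append(phasability(bes, max_phase_distance)[1])
    return float(np.mean(fracs))
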