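"""Probabilistic evidence scoring, maximal-clique candidate enumeration,
unique evidence allocation and call emission.

Each read or read pair receives a phred-scaled quality score::

    score = min(mapq cap, -10 * log10(empirical rate of that signature))

where the empirical rate comes from the library profile: the CIGAR-operator
distribution for clips, split reads and indels, the fragment-size tail for
within-range discordant pairs, the discordant mapping rate for distal
pairs, and the unmapped-mate rate for one-ended fragments.  Two-sided
evidence is capped by the mapping quality on *both* sides.

Candidates are maximal cliques of the evidence compatibility graph (local
interval x direction overlap, and remote overlap for breakpoints); evidence
is then uniquely assigned, preferring candidates backed by an assembly that
contains the read, then the highest-scoring clique, then the leftmost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .assembly import fragment_supports_breakpoint
from .evidence import LibraryMetrics
from .model import (
    HEAD,
    TAIL,
    AssemblyContig,
    Breakend,
    BreakendInterval,
    BreakpointCall,
    CallBase,
    EvidenceItem,
    EvidenceKind,
    SingleBreakendCall,
    SupportBreakdown,
)

DEFAULT_MIN_FRAGMENTS = 2
DEFAULT_MIN_EVENT_SIZE = 10


def evidence_quality(item: EvidenceItem, metrics: LibraryMetrics) -> float:
    """Phred-scaled support quality of one evidence item."""
    floor = metrics.rate_floor
    kind = item.kind
    if kind in (EvidenceKind.SOFT_CLIP, EvidenceKind.SPLIT_READ):
        rate = metrics.cigar_rates.get(("S", len(item.seq)), floor)
    elif kind is EvidenceKind.INDEL:
        if item.seq:
            rate = metrics.cigar_rates.get(("I", len(item.seq)), floor)
        else:
            ln = item.remote.lo - item.local.lo - 1
            rate = metrics.cigar_rates.get(("D", ln), floor)
    elif kind is EvidenceKind.UNMAPPED_MATE:
        rate = metrics.unmapped_mate_rate
    elif kind is EvidenceKind.DISCORDANT_PAIR:
        if item.remote is not None and item.remote.chrom == item.local.chrom:
            # within-range orientation: score by fragment-size tail
            sep = abs(item.remote.lo - item.local.lo)
            if sep <= metrics.max_fragment * 2:
                rate = metrics.fragment_tail_prob(sep)
            else:
                rate = metrics.discordant_rate
        else:
            rate = metrics.discordant_rate
    else:  # pragma: no cover - exhaustive
        rate = floor
    rate = max(rate, floor)
    score = -10.0 * math.log10(rate) if rate < 1.0 else 0.0
    cap = float(item.local_mapq)
    if item.remote_mapq is not None:
        cap = min(cap, float(item.remote_mapq))
    return max(0.0, min(cap, score))


@dataclass
class Candidate:
    """A putative variant: either a precise assembly-derived junction or a
    maximal clique of direct evidence."""

    id: str
    local: BreakendInterval
    remote: Optional[BreakendInterval] = None
    precise: bool = False
    b1: Optional[Breakend] = None
    b2: Optional[Breakend] = None
    insert_seq: str = ""
    items: list[EvidenceItem] = field(default_factory=list)
    contigs: list[AssemblyContig] = field(default_factory=list)
    remote_contigs: list[AssemblyContig] = field(default_factory=list)
    breakend_seq: str = ""
    bealn: list[str] = field(default_factory=list)
    score: float = 0.0
    cq: float = 0.0
    # contig-coordinate homology interval per backing contig id
    contig_homology: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def is_breakpoint(self) -> bool:
        return self.remote is not None

    def assembly_fragments(self) -> set[str]:
        frags: set[str] = set()
        for c in self.contigs + self.remote_contigs:
            hom = self.contig_homology.get(c.id, (c.junction_base + 1, c.junction_base))
            for f in c.support:
                if fragment_supports_breakpoint(c, f, hom):
                    frags.add(f)
        return frags


def _compatible(a: EvidenceItem, b: EvidenceItem) -> bool:
    if not a.local.overlaps(b.local):
        return False
    if (a.remote is None) != (b.remote is None):
        return False
    if a.remote is not None and not a.remote.overlaps(b.remote):
        return False
    return True


def enumerate_candidates(evidence: list[EvidenceItem]) -> list[Candidate]:
    """Maximal cliques of the evidence compatibility graph.

    Two-sided evidence (split reads, indels, discordant pairs) forms
    breakpoint candidates; one-sided evidence forms breakend candidates.
    Each clique's interval is the intersection of its members' intervals.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(evidence)))
    for i in range(len(evidence)):
        for j in range(i + 1, len(evidence)):
            if _compatible(evidence[i], evidence[j]):
                graph.add_edge(i, j)
    out: list[Candidate] = []
    seen: set[tuple[int, ...]] = set()
    for clique in nx.find_cliques(graph):
        key = tuple(sorted(clique))
        if key in seen:
            continue
        seen.add(key)
        members = [evidence[i] for i in key]
        local = members[0].local
        remote = members[0].remote
        for m in members[1:]:
            local = local.intersect(m.local)
            if remote is not None:
                remote = remote.intersect(m.remote)
        out.append(
            Candidate(
                id=f"clique_{local.chrom}_{local.lo}_{local.dir.value}_{len(out)}",
                local=local,
                remote=remote,
                items=members,
            )
        )
    out.sort(key=lambda c: (c.local.chrom, c.local.lo, c.local.dir.value, c.id))
    return out


def _item_matches(item: EvidenceItem, cand: Candidate) -> bool:
    if cand.is_breakpoint:
        if item.remote is None:
            # one-sided evidence can still support a breakpoint locally
            # (a clip at the junction); require positional precision
            return item.local.width <= 2 and (
                item.local.overlaps(cand.local) or item.local.overlaps(cand.remote)
            )
        return (
            item.local.overlaps(cand.local) and item.remote.overlaps(cand.remote)
        ) or (
            item.local.overlaps(cand.remote) and item.remote.overlaps(cand.local)
        )
    return item.remote is None and item.local.overlaps(cand.local)


def allocate_evidence(
    candidates: list[Candidate],
    evidence: list[EvidenceItem],
    metrics: LibraryMetrics,
) -> None:
    """Uniquely assign every evidence item to one candidate (in place).

    Preference: (1) a candidate backed by an assembly containing the
    fragment, (2) highest clique score, (3) leftmost candidate.  Candidate
    scores are recomputed afterwards; ``cq`` keeps the pre-reallocation
    quality.
    """
    for item in evidence:
        if item.quality == 0.0:
            item.quality = evidence_quality(item, metrics)
    for cand in candidates:
        cand.items = []
        cand.cq = 0.0
    # pre-allocation scores (every compatible item counts)
    compat: dict[int, list[int]] = {}
    for idx, item in enumerate(evidence):
        compat[idx] = [i for i, c in enumerate(candidates) if _item_matches(item, c)]
        for ci in compat[idx]:
            candidates[ci].cq += item.quality
    asm_frags = [c.assembly_fragments() for c in candidates]
    for idx, item in enumerate(evidence):
        choices = compat[idx]
        if not choices:
            continue

        def rank(ci: int):
            c = candidates[ci]
            in_asm = item.fragment_id in asm_frags[ci]
            return (
                0 if in_asm else 1,
                -c.cq,
                c.local.chrom,
                c.local.lo,
                c.id,
            )

        best = min(choices, key=rank)
        candidates[best].items.append(item)
    for cand in candidates:
        cand.score = sum(i.quality for i in cand.items)


def unique_fragments(cand: Candidate) -> set[str]:
    """Fragments supporting directly or through assembly, counted once."""
    frags = {i.fragment_id for i in cand.items}
    frags |= cand.assembly_fragments()
    return frags


def compute_support_breakdown(
    call: CallBase,
    cand: Candidate,
    samples: list[str],
    fragment_sample: dict[str, str],
    discordant_frags: Optional[set[str]] = None,
) -> None:
    """Populate the per-sample evidence ledger of ``call`` from its
    allocated evidence and backing assemblies."""
    for s in samples:
        call.breakdowns[s] = SupportBreakdown()
    is_bp = cand.is_breakpoint
    disc = discordant_frags or set()
    mapqs: list[int] = []
    n_plus = n_minus = 0
    asm_frags = cand.assembly_fragments()
    for item in cand.items:
        bd = call.breakdown(item.sample)
        q = item.quality
        mapqs.append(item.local_mapq)
        if item.kind in (EvidenceKind.SPLIT_READ, EvidenceKind.SOFT_CLIP):
            if item.read_strand == "+":
                n_plus += 1
            else:
                n_minus += 1
        if is_bp:
            if item.kind is EvidenceKind.SPLIT_READ:
                bd.SR += 1
                bd.SRQ += q
            elif item.kind is EvidenceKind.SOFT_CLIP:
                bd.SR += 1  # clip at a called junction counts as split support
                bd.SRQ += q
            elif item.kind is EvidenceKind.INDEL:
                bd.IC += 1
                bd.IQ += q
            elif item.kind is EvidenceKind.DISCORDANT_PAIR:
                bd.RP += 1
                bd.RPQ += q
            elif item.kind is EvidenceKind.UNMAPPED_MATE:
                bd.BUM += 1
                bd.BUMQ += q
        else:
            if item.kind in (EvidenceKind.SOFT_CLIP, EvidenceKind.SPLIT_READ):
                bd.BSC += 1
                bd.BSCQ += q
            elif item.kind is EvidenceKind.UNMAPPED_MATE:
                bd.BUM += 1
                bd.BUMQ += q
    # assembly contributions
    for c, remote in [(c, False) for c in cand.contigs] + [
        (c, True) for c in cand.remote_contigs
    ]:
        contrib: dict[str, float] = {}
        for frag, kind in c.fragment_kinds.items():
            sample = c.fragment_samples.get(frag, samples[0])
            hom = cand.contig_homology.get(c.id, (c.junction_base + 1, c.junction_base))
            spans = fragment_supports_breakpoint(c, frag, hom)
            bd = call.breakdown(sample)
            q = _assembled_read_quality(cand, frag)
            # a clipped read whose fragment is also a discordant pair counts
            # as read-pair support contributed through the assembly
            as_pair = kind is EvidenceKind.UNMAPPED_MATE or frag in disc
            if is_bp:
                if spans:
                    if as_pair:
                        bd.ASRP += 1
                    else:
                        bd.ASSR += 1
                    contrib[sample] = contrib.get(sample, 0.0) + q
                else:
                    if as_pair:
                        bd.BANRP += 1
                        bd.BANRPQ += q
                    else:
                        bd.BANSR += 1
                        bd.BANSRQ += q
            else:
                if as_pair:
                    bd.BASRP += 1
                else:
                    bd.BASSR += 1
                contrib[sample] = contrib.get(sample, 0.0) + q
        for sample, q in contrib.items():
            bd = call.breakdown(sample)
            if is_bp:
                if remote:
                    bd.RAS += 1
                    bd.RASQ += q
                else:
                    bd.AS_ += 1
                    bd.ASQ += q
            else:
                bd.BA += 1
                bd.BAQ += q
    # unique fragment counts per sample
    for frag in unique_fragments(cand):
        sample = fragment_sample.get(frag)
        if sample is None:
            continue
        bd = call.breakdown(sample)
        if is_bp:
            bd.VF += 1
        else:
            bd.BVF += 1
    call.qual = sum(bd.qual if is_bp else bd.bqual for bd in call.breakdowns.values())
    call.cq = cand.cq
    if n_plus + n_minus:
        call.sb = round(n_plus / (n_plus + n_minus), 4)
    if mapqs:
        call.mq = round(sum(mapqs) / len(mapqs), 2)
        call.mqn = min(mapqs)
        call.mqx = max(mapqs)


def _assembled_read_quality(cand: Candidate, frag: str) -> float:
    for item in cand.items:
        if item.fragment_id == frag:
            return item.quality
    return 10.0  # assembled read not independently scored: nominal phred


def call_variants(
    candidates: list[Candidate],
    samples: list[str],
    fragment_sample: dict[str, str],
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
    min_event_size: int = DEFAULT_MIN_EVENT_SIZE,
    discordant_frags: Optional[set[str]] = None,
) -> list[CallBase]:
    """Emit breakpoint / single-breakend calls from allocated candidates.

    Requires ``min_fragments`` unique supporting fragments; intrachromosomal
    breakpoints smaller than ``min_event_size`` are suppressed unless
    inversion-like (foldback inversions are exempt from the size filter).
    """
    calls: list[CallBase] = []
    n = 0
    for cand in candidates:
        frags = unique_fragments(cand)
        if len(frags) < min_fragments:
            continue
        if cand.is_breakpoint:
            if cand.precise:
                b1, b2 = cand.b1, cand.b2
            else:
                b1 = Breakend(cand.local.chrom, cand.local.lo, cand.local.dir)
                b2 = Breakend(cand.remote.chrom, cand.remote.lo, cand.remote.dir)
            call = BreakpointCall(
                id=f"bp{n}",
                b1=b1,
                b2=b2,
                insert_seq=cand.insert_seq,
                precise=cand.precise,
            )
            if not cand.precise:
                call.cipos = (0, cand.local.width - 1)
                call.cirpos = (0, cand.remote.width - 1)
            if (
                call.is_intrachromosomal
                and not call.inversion_like
                and call.event_size is not None
                and call.event_size < min_event_size
            ):
                continue
        else:
            be = Breakend(cand.local.chrom, cand.local.lo, cand.local.dir)
            call = SingleBreakendCall(
                id=f"be{n}",
                be=be,
                breakend_seq=cand.breakend_seq,
                precise=cand.precise,
                bealn=list(cand.bealn),
            )
            if not cand.precise:
                call.cipos = (0, cand.local.width - 1)
        call.beids = [c.id for c in cand.contigs + cand.remote_contigs]
        if cand.precise and cand.is_breakpoint:
            call.homlen = getattr(cand, "homlen", 0)
            call.homseq = getattr(cand, "homseq", "")
        compute_support_breakdown(
            call, cand, samples, fragment_sample, discordant_frags=discordant_frags
        )
        call.candidate = cand  # provenance for downstream annotation
        calls.append(call)
        n += 1
    return calls
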