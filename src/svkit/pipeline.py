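"""End-to-end somatic SV calling: SAM ingest, evidence extraction, joint
breakend assembly, compound realignment, candidate construction, unique
evidence allocation, annotation, phasing and somatic filtering.

The tumour and normal are assembled jointly (so germline support is visible
on somatic candidates) with per-sample evidence ledgers kept throughout.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pysam

from . import phasing as phasing_mod
from . import somatic_filter as sf
from .align_homology import (
    MIN_MAPQ,
    Reference,
    SeedAligner,
    adjust_split_bounds,
    compound_realign,
    exact_homology,
    inexact_homology,
    load_fasta,
)
from .assembly import assemble, extend_contigs, DEFAULT_K
from .calling import (
    Candidate,
    allocate_evidence,
    call_variants,
    enumerate_candidates,
    evidence_quality,
)
from .evidence import (
    LibraryMetrics,
    ReadRecord,
    SAEntry,
    classify_read,
    estimate_library_metrics,
    realign_soft_clips,
)
from .model import (
    HEAD,
    TAIL,
    AssemblyContig,
    Breakend,
    BreakendInterval,
    BreakpointCall,
    CallBase,
    Direction,
    EvidenceItem,
    EvidenceKind,
    PhaseLink,
    SingleBreakendCall,
    SplitAlignmentChain,
    revcomp,
)

log = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(s: str) -> tuple[tuple[str, int], ...]:
    return tuple((op, int(n)) for n, op in _CIG_RE.findall(s))


def _sa_to_internal(tag: str, primary_reverse: bool) -> tuple[SAEntry, ...]:
    """Standard SA tag -> stored-orientation SAEntry tuple."""
    out = []
    for part in tag.strip(";").split(";"):
        if not part:
            continue
        rname, pos, strand, cigar, mapq, _nm = part.split(",")
        seq_strand = strand
        internal = seq_strand if not primary_reverse else ("-" if seq_strand == "+" else "+")
        cig = _parse_cigar(cigar)
        if internal == "-":
            cig = tuple(reversed(cig))
        out.append(SAEntry(rname, int(pos), internal, cig, int(mapq)))
    return tuple(out)


def read_record_from_pysam(rec: pysam.AlignedSegment, refnames: Sequence[str]) -> ReadRecord:
    sa = ()
    if rec.has_tag("SA"):
        sa = _sa_to_internal(rec.get_tag("SA"), rec.is_reverse)
    mate_mapq = rec.get_tag("MQ") if rec.has_tag("MQ") else None
    return ReadRecord(
        name=rec.query_name,
        chrom=refnames[rec.reference_id],
        pos=rec.reference_start + 1,
        strand="-" if rec.is_reverse else "+",
        cigar=_parse_cigar(rec.cigarstring or ""),
        mapq=rec.mapping_quality,
        seq=rec.query_sequence or "",
        is_read1=rec.is_read1,
        mate_chrom=refnames[rec.next_reference_id] if rec.next_reference_id >= 0 else None,
        mate_pos=rec.next_reference_start + 1,
        mate_strand="-" if rec.mate_is_reverse else "+",
        mate_mapped=not rec.mate_is_unmapped,
        mate_mapq=mate_mapq,
        tlen=rec.template_length,
        is_duplicate=rec.is_duplicate,
        is_secondary=rec.is_secondary or rec.is_supplementary,
        sa=sa,
    )


def iter_read_records(sam_path: Union[str, Path]) -> Iterator[ReadRecord]:
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        refnames = list(fh.references)
        for rec in fh:
            if rec.is_unmapped or rec.reference_id < 0:
                continue
            yield read_record_from_pysam(rec, refnames)


def estimate_metrics_from_sam(
    sam_path: Union[str, Path], max_reads: int = 10_000_000
) -> LibraryMetrics:
    return estimate_library_metrics(iter_read_records(sam_path), max_reads=max_reads)


def extract_evidence(
    sam_path: Union[str, Path],
    metrics: LibraryMetrics,
    sample: str,
    reference: Optional[Reference] = None,
    aligner: Optional[SeedAligner] = None,
) -> list[EvidenceItem]:
    """Two-pass extraction: the first pass records low-mapq / unmapped reads
    (potential unmapped mates), the second classifies each primary read.
    Plain soft clips are realigned into split reads when an aligner and
    reference are supplied."""
    low: dict[tuple[str, bool], tuple[str, bool]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.is_unmapped or rec.mapping_quality < MIN_MAPQ:
                low[(rec.query_name, rec.is_read1)] = (
                    rec.query_sequence or "",
                    rec.is_reverse,
                )
    items: list[EvidenceItem] = []
    for read in iter_read_records(sam_path):
        if read.is_duplicate or read.is_secondary or read.mapq < MIN_MAPQ:
            continue
        mate_key = (read.name, not read.is_read1)
        mate_low = (
            not read.mate_mapped
            or (read.mate_mapq is not None and read.mate_mapq < MIN_MAPQ)
            or mate_key in low
        )
        mate_seq = None
        if mate_low and mate_key in low:
            stored, rev = low[mate_key]
            mate_seq = stored
        if aligner is not None and reference is not None and not read.sa:
            if read.clip_left >= 5 or read.clip_right >= 5:
                read = realign_soft_clips(read, aligner, reference)
        items.extend(
            classify_read(
                read,
                metrics,
                mate_seq=mate_seq,
                sample=sample,
                mate_is_low_mapq=mate_low,
            )
        )
    return items


def canonical_two_sided(items: list[EvidenceItem]) -> list[EvidenceItem]:
    """Orient two-sided evidence so local <= remote and drop the mirrored
    duplicate each fragment's other read produces."""
    out: list[EvidenceItem] = []
    seen: set[tuple] = set()
    for it in items:
        if it.remote is None:
            out.append(it)
            continue
        local, remote = it.local, it.remote
        lm, rm = it.local_mapq, it.remote_mapq
        if (remote.chrom, remote.lo) < (local.chrom, local.lo):
            local, remote = remote, local
            lm, rm = (rm if rm is not None else lm), lm
        key = (
            it.fragment_id,
            it.kind,
            local.chrom, remote.chrom, local.dir, remote.dir,
            local.lo if it.kind is not EvidenceKind.DISCORDANT_PAIR else 0,
        )
        if key in seen:
            continue
        seen.add(key)
        view = EvidenceItem(
            it.fragment_id, it.sample, it.kind, local, remote,
            seq=it.seq, anchor_seq=it.anchor_seq,
            local_mapq=lm, remote_mapq=rm,
            read_names=it.read_names, read_strand=it.read_strand,
            anchor_lo=it.anchor_lo, anchor_hi=it.anchor_hi,
        )
        view.quality = it.quality
        out.append(view)
    return out


# --------------------------------------------------------------------------
# junctions from contigs


def _junction_from_hits(a, b, chain: SplitAlignmentChain, i: int):
    b1 = (
        Breakend(a.chrom, a.ref_hi, HEAD)
        if a.strand == "+"
        else Breakend(a.chrom, a.ref_lo, TAIL)
    )
    b2 = (
        Breakend(b.chrom, b.ref_lo, TAIL)
        if b.strand == "+"
        else Breakend(b.chrom, b.ref_hi, HEAD)
    )
    return b1, b2, chain.gap_seq(i)


def canonical_junction(
    b1: Breakend, b2: Breakend, insert: str, ref: Reference
) -> tuple[Breakend, Breakend, str, int, int, str]:
    """Order breakends and left-normalise through the homology interval.

    Returns (b1, b2, insert, n_left_remaining, homlen, homseq) with the
    junction at its leftmost placement in derivative orientation and
    b1 <= b2.
    """
    if (b2.chrom, b2.pos, b2.dir.value) < (b1.chrom, b1.pos, b1.dir.value):
        b1, b2 = b2, b1
        insert = revcomp(insert) if b1.dir is b2.dir else insert
    n_l, n_r, homseq = exact_homology(b1, b2, insert, ref)
    # shift to the leftmost placement (derivative orientation: s = -n_l)
    if n_l:
        s = -n_l
        p1 = b1.pos + s if b1.dir is HEAD else b1.pos - s
        p2 = b2.pos + s if b2.dir is TAIL else b2.pos - s
        b1 = Breakend(b1.chrom, p1, b1.dir)
        b2 = Breakend(b2.chrom, p2, b2.dir)
    return b1, b2, insert, n_l, n_l + n_r, homseq


def _ref_offsets(dir_: Direction, homlen: int, side: int) -> tuple[int, int]:
    """CIPOS offsets in reference coordinates for a left-normalised
    junction with ``homlen`` bases of homology.

    Sliding the junction right by s moves the derivative-left breakend
    (+s for HEAD, -s for TAIL) and the derivative-right breakend (+s for
    TAIL, -s for HEAD)."""
    if homlen == 0:
        return (0, 0)
    positive = (dir_ is HEAD) if side == 1 else (dir_ is TAIL)
    return (0, homlen) if positive else (-homlen, 0)


def contig_hom_interval(
    contig: AssemblyContig, n_l: int, n_r: int
) -> tuple[int, int]:
    """Homology interval in contig base coordinates (empty encoded with
    lo > hi at the junction)."""
    jb = contig.junction_base
    if n_l + n_r == 0:
        return (jb + 1, jb)
    if contig.dir is HEAD:
        return (jb - n_l + 1, jb + n_r)
    return (jb - n_r, jb + n_l - 1)


# --------------------------------------------------------------------------
# pipeline


@dataclass
class CallParams:
    k: int = DEFAULT_K
    min_fragments: int = 2
    min_event_size: int = 10
    tumour_name: str = "tumour"
    normal_name: str = "normal"
    realign_soft_clips: bool = True


@dataclass
class PipelineResult:
    calls: list[CallBase]
    filters: dict[str, sf.FilterResult]
    links: list[PhaseLink]
    collapsed: list[str]
    contigs: list[AssemblyContig]
    chains: list[SplitAlignmentChain]
    metrics: dict[str, LibraryMetrics]
    reference: Reference
    samples: list[str]

    def high_confidence(self) -> list[CallBase]:
        return [
            c for c in self.calls
            if self.filters[c.id].status is sf.Status.PASS and c.id not in self.collapsed
        ]

    def low_confidence(self) -> list[CallBase]:
        return [
            c for c in self.calls
            if self.filters[c.id].status is not sf.Status.HARD_FILTERED
        ]


def call_somatic(
    tumour_sam: Union[str, Path],
    normal_sam: Union[str, Path],
    reference: Union[str, Path, Reference],
    params: Optional[CallParams] = None,
    pon: Optional[sf.PanelOfNormals] = None,
) -> PipelineResult:
    params = params or CallParams()
    ref = reference if isinstance(reference, dict) else load_fasta(reference)
    aligner = SeedAligner()
    samples = [params.tumour_name, params.normal_name]
    metrics = {
        params.tumour_name: estimate_metrics_from_sam(tumour_sam),
        params.normal_name: estimate_metrics_from_sam(normal_sam),
    }
    m = metrics[params.tumour_name]
    items = extract_evidence(
        tumour_sam, m, params.tumour_name,
        reference=ref if params.realign_soft_clips else None,
        aligner=aligner if params.realign_soft_clips else None,
    )
    items += extract_evidence(
        normal_sam, metrics[params.normal_name], params.normal_name,
        reference=ref if params.realign_soft_clips else None,
        aligner=aligner if params.realign_soft_clips else None,
    )
    for it in items:
        it.quality = evidence_quality(it, metrics.get(it.sample, m))

    contigs = assemble(items, m, k=params.k)
    contigs = extend_contigs(contigs, params.k, max_len=int(1.5 * m.max_fragment))
    chains: list[SplitAlignmentChain] = []
    contig_by_id = {c.id: c for c in contigs}
    chain_by_contig: dict[str, SplitAlignmentChain] = {}
    for contig in contigs:
        chain = compound_realign(contig, aligner, ref)
        if chain is None:
            continue
        chain = adjust_split_bounds(chain, ref)
        chains.append(chain)
        chain_by_contig[contig.id] = chain

    candidates, chain_junctions = _build_candidates(
        chains, contig_by_id, ref, m, params
    )
    calling_items = canonical_two_sided(items)
    candidates += enumerate_candidates(calling_items)
    allocate_evidence(candidates, calling_items, m)
    fragment_sample = {}
    for it in items:
        fragment_sample[it.fragment_id] = it.sample
    for contig in contigs:
        fragment_sample.update(contig.fragment_samples)
    discordant_frags = {
        it.fragment_id
        for it in items
        if it.kind in (EvidenceKind.DISCORDANT_PAIR, EvidenceKind.UNMAPPED_MATE)
    }
    calls = call_variants(
        candidates, samples, fragment_sample,
        min_fragments=params.min_fragments,
        min_event_size=params.min_event_size,
        discordant_frags=discordant_frags,
    )
    cand_by_call: dict[str, Candidate] = {
        c.id: c.candidate for c in calls  # type: ignore[attr-defined]
    }
    _drop_shadowed_imprecise(calls, cand_by_call)
    _annotate_homology(calls, cand_by_call, ref)
    _merge_duplicate_breakpoints(calls, cand_by_call)
    _count_reference_support(
        calls,
        cand_by_call,
        {params.tumour_name: tumour_sam, params.normal_name: normal_sam},
        metrics,
    )
    links, collapsed = _phase(calls, chains, chain_junctions, contig_by_id, m)
    filters = sf.apply_somatic_filters(
        calls, params.tumour_name, params.normal_name,
        links=links, pon=pon, reference=ref,
    )
    for cid in collapsed:
        fr = filters.get(cid)
        if fr is not None and fr.status is not sf.Status.HARD_FILTERED:
            reasons = fr.reasons + ["transitive"]
            filters[cid] = sf.FilterResult(sf.Status.LOW_CONFIDENCE, reasons)
    return PipelineResult(
        calls=calls,
        filters=filters,
        links=links,
        collapsed=collapsed,
        contigs=contigs,
        chains=chains,
        metrics=metrics,
        reference=ref,
        samples=samples,
    )


def _build_candidates(
    chains: list[SplitAlignmentChain],
    contig_by_id: dict[str, AssemblyContig],
    ref: Reference,
    metrics: LibraryMetrics,
    params: CallParams,
) -> tuple[list[Candidate], dict[str, list[tuple[Breakend, Breakend, str]]]]:
    """Precise breakpoint and single-breakend candidates from realigned
    contigs; junctions deduplicated across contigs that assemble the same
    break from either side."""
    by_junction: dict[tuple, Candidate] = {}
    singles: list[Candidate] = []
    chain_junctions: dict[str, list[tuple[Breakend, Breakend, str]]] = {}
    n = 0
    for chain in chains:
        contig = contig_by_id[chain.contig_id]
        juncs = []
        for i in range(len(chain.hits) - 1):
            a, b = chain.hits[i], chain.hits[i + 1]
            b1, b2, ins = _junction_from_hits(a, b, chain, i)
            b1, b2, ins, n_l, homlen, homseq = canonical_junction(b1, b2, ins, ref)
            juncs.append((b1, b2, ins))
            key = (b1.chrom, b1.pos, b1.dir, b2.chrom, b2.pos, b2.dir, ins)
            cand = by_junction.get(key)
            if cand is None:
                ci = _ref_offsets(b1.dir, homlen, 1)
                cir = _ref_offsets(b2.dir, homlen, 2)
                cand = Candidate(
                    id=f"pc{n}",
                    local=BreakendInterval(
                        b1.chrom, b1.pos + ci[0], b1.pos + ci[1], b1.dir
                    ),
                    remote=BreakendInterval(
                        b2.chrom, b2.pos + cir[0], b2.pos + cir[1], b2.dir
                    ),
                    precise=True,
                    b1=b1,
                    b2=b2,
                    insert_seq=ins,
                )
                cand.homlen = homlen  # type: ignore[attr-defined]
                cand.homseq = homseq  # type: ignore[attr-defined]
                by_junction[key] = cand
                n += 1
            hom_iv = _hom_for_contig(contig, homlen)
            cand.contig_homology[contig.id] = hom_iv
            if _contig_is_local(contig, cand.b1):
                if contig not in cand.contigs:
                    cand.contigs.append(contig)
            elif contig not in cand.remote_contigs:
                cand.remote_contigs.append(contig)
        chain_junctions[chain.contig_id] = juncs
        # single breakend: anchored alignment with an unalignable breakend
        if not juncs and len(chain.hits) >= 1 and chain.unaligned:
            be, seq = _single_breakend_from_chain(chain, contig)
            if be is not None and len(seq) >= 1:
                cand = Candidate(
                    id=f"sb{len(singles)}",
                    local=BreakendInterval(be.chrom, be.pos, be.pos, be.dir),
                    precise=True,
                    breakend_seq=seq,
                    bealn=[
                        f"{h.chrom}:{h.ref_lo}|{h.strand}|{h.query_len}M|{h.mapq}"
                        for h in getattr(chain, "bealn", [])[:8]
                    ],
                    contigs=[contig],
                )
                cand.contig_homology[contig.id] = (
                    contig.junction_base + 1,
                    contig.junction_base,
                )
                singles.append(cand)
    return list(by_junction.values()) + singles, chain_junctions


def _hom_for_contig(contig: AssemblyContig, homlen: int) -> tuple[int, int]:
    """Conservative (symmetric) homology window around the contig junction
    used for the per-base fragment spanning test."""
    jb = contig.junction_base
    if homlen == 0:
        return (jb + 1, jb)
    return (jb - homlen, jb + homlen)


def _contig_is_local(contig: AssemblyContig, b1: Breakend) -> bool:
    return (
        contig.chrom == b1.chrom
        and contig.dir is b1.dir
        and abs(contig.pos - b1.pos) <= 2000
    )


def _single_breakend_from_chain(chain: SplitAlignmentChain, contig: AssemblyContig):
    hit = max(chain.hits, key=lambda h: h.score)
    if hit.strand != "+":
        return None, ""
    q_lo, q_hi = hit.query_lo, hit.query_hi
    left_un = [u for u in chain.unaligned if u[1] < q_lo]
    right_un = [u for u in chain.unaligned if u[0] > q_hi]
    if contig.dir is HEAD and right_un:
        be = Breakend(hit.chrom, hit.ref_hi, HEAD)
        seq = chain.query[q_hi:]
        return be, seq
    if contig.dir is TAIL and left_un:
        be = Breakend(hit.chrom, hit.ref_lo, TAIL)
        seq = chain.query[: q_lo - 1]
        return be, seq
    return None, ""


def _drop_shadowed_imprecise(calls: list[CallBase], cand_by_call) -> None:
    """Remove imprecise breakpoint calls whose both breakends fall inside
    the fragment-size neighbourhood of one precise call with matching
    orientations (residual unallocated noise around a called junction)."""
    precise = [c for c in calls if isinstance(c, BreakpointCall) and c.precise]
    precise_bes: list[Breakend] = []
    for c in calls:
        if not c.imprecise:
            if isinstance(c, BreakpointCall):
                precise_bes += [c.b1, c.b2]
            else:
                precise_bes.append(c.be)
    to_drop: set[str] = set()
    for c in calls:
        if not c.imprecise:
            continue
        if isinstance(c, BreakpointCall):
            for p in precise:
                if _same_junction_neighbourhood(c, p):
                    to_drop.add(c.id)
                    break
        else:
            lo = c.be.pos + c.cipos[0] - 150
            hi = c.be.pos + c.cipos[1] + 150
            for b in precise_bes:
                if b.chrom == c.be.chrom and b.dir is c.be.dir and lo <= b.pos <= hi:
                    to_drop.add(c.id)
                    break
    calls[:] = [c for c in calls if c.id not in to_drop]


def _same_junction_neighbourhood(imp: BreakpointCall, prec: BreakpointCall) -> bool:
    def near(a: Breakend, b: Breakend, iv: tuple[int, int]) -> bool:
        return a.chrom == b.chrom and a.dir is b.dir and (
            b.pos + iv[0] - 2 <= a.pos <= b.pos + iv[1] + 2
        )

    return (
        near(prec.b1, imp.b1, imp.cipos) and near(prec.b2, imp.b2, imp.cirpos)
    ) or (
        near(prec.b1, imp.b2, imp.cirpos) and near(prec.b2, imp.b1, imp.cipos)
    )


def _merge_duplicate_breakpoints(calls: list[CallBase], cand_by_call) -> None:
    seen: dict[tuple, CallBase] = {}
    out = []
    for c in calls:
        if isinstance(c, BreakpointCall):
            key = (
                c.b1.chrom, c.b1.pos, c.b1.dir, c.b2.chrom, c.b2.pos, c.b2.dir,
                c.insert_seq, c.precise,
            )
        else:
            key = (c.be.chrom, c.be.pos, c.be.dir, getattr(c, "breakend_seq", ""))
        if key in seen:
            continue
        seen[key] = c
        out.append(c)
    calls[:] = out


def _annotate_homology(
    calls: list[CallBase], cand_by_call: dict[str, Candidate], ref: Reference
) -> None:
    for c in calls:
        if isinstance(c, BreakpointCall) and c.precise:
            n_l, n_r, homseq = exact_homology(c.b1, c.b2, c.insert_seq, ref)
            homlen = n_l + n_r
            c.homlen = homlen
            c.homseq = homseq
            c.cipos = _ref_offsets(c.b1.dir, homlen, 1)
            c.cirpos = _ref_offsets(c.b2.dir, homlen, 2)
            il, ir = inexact_homology(c.b1, c.b2, c.insert_seq, ref)
            # derivative-orientation extensions -> reference-coordinate offsets
            c.ihompos = (-il, ir) if c.b1.dir is HEAD else (-ir, il)


def _count_reference_support(
    calls: list[CallBase],
    cand_by_call: dict[str, Candidate],
    sams: dict[str, Union[str, Path]],
    metrics: dict[str, LibraryMetrics],
) -> None:
    """One pass per sample: REF counts reads spanning the full homology
    interval of a call breakend; REFPAIR counts concordant pairs whose
    fragment (but neither read) spans it.  Reads supporting the variant
    are excluded."""
    from .calling import unique_fragments

    intervals: dict[str, tuple[list[int], list[tuple[int, int, CallBase]]]] = {}
    tmp: dict[str, list[tuple[int, int, CallBase]]] = defaultdict(list)
    supporting: dict[str, set[str]] = {}
    for c in calls:
        b = c.b1 if isinstance(c, BreakpointCall) else c.be
        ci = c.cipos
        lo, hi = b.pos + ci[0], b.pos + ci[1] + 1
        tmp[b.chrom].append((lo, hi, c))
        cand = cand_by_call.get(c.id)
        names: set[str] = set()
        if cand is not None:
            for frag in unique_fragments(cand):
                names.add(frag.split(":", 1)[1])
        supporting[c.id] = names
    for chrom, ivs in tmp.items():
        ivs.sort(key=lambda t: t[0])
        intervals[chrom] = ([t[0] for t in ivs], ivs)
    for sample, sam in sams.items():
        hi_cap = metrics[sample].concordant_hi
        with pysam.AlignmentFile(str(sam), "r") as fh:
            refnames = list(fh.references)
            for rec in fh:
                if (
                    rec.is_unmapped
                    or rec.is_secondary
                    or rec.is_supplementary
                    or rec.is_duplicate
                    or rec.mapping_quality < MIN_MAPQ
                ):
                    continue
                chrom = refnames[rec.reference_id]
                if chrom not in intervals:
                    continue
                starts, ivs = intervals[chrom]
                r_lo = rec.reference_start + 1
                r_hi = rec.reference_end or r_lo
                frag_hi = None
                if 0 < rec.template_length <= hi_cap:
                    frag_hi = r_lo + rec.template_length - 1
                span_hi = max(r_hi, frag_hi or 0)
                # candidate calls whose interval starts within the span
                for k in range(bisect_left(starts, r_lo), bisect_right(starts, span_hi)):
                    lo, hi, c = ivs[k]
                    if rec.query_name in supporting[c.id]:
                        continue
                    has_clip = rec.cigartuples and (
                        rec.cigartuples[0][0] in (4, 5)
                        or rec.cigartuples[-1][0] in (4, 5)
                    )
                    bd = c.breakdown(sample)
                    if r_lo <= lo and r_hi >= hi and not has_clip:
                        bd.REF += 1
                        bd.RF += 1
                    elif frag_hi is not None and r_lo <= lo and frag_hi >= hi:
                        bd.REFPAIR += 1


def _phase(
    calls: list[CallBase],
    chains: list[SplitAlignmentChain],
    chain_junctions: dict[str, list[tuple[Breakend, Breakend, str]]],
    contig_by_id: dict[str, AssemblyContig],
    metrics: LibraryMetrics,
) -> tuple[list[PhaseLink], list[str]]:
    call_by_junction: dict[tuple, str] = {}
    for c in calls:
        if isinstance(c, BreakpointCall):
            key = (c.b1.chrom, c.b1.pos, c.b1.dir, c.b2.chrom, c.b2.pos, c.b2.dir)
            call_by_junction[key] = c.id
    chains_with_calls = []
    for chain in chains:
        juncs = chain_junctions.get(chain.contig_id, [])
        ids = [
            call_by_junction.get((b1.chrom, b1.pos, b1.dir, b2.chrom, b2.pos, b2.dir))
            for b1, b2, _ in juncs
        ]
        chains_with_calls.append((chain, ids))
    links = phasing_mod.assembly_links(chains_with_calls, calls)
    anchor_extent: dict[str, tuple[str, int, int]] = {}
    for c in calls:
        ext = None
        for bid in c.beids:
            contig = contig_by_id.get(bid)
            if contig is None:
                continue
            a_len = len(contig.anchor_seq)
            if contig.dir is HEAD:
                lo, hi = contig.pos - a_len + 1, contig.pos
            else:
                lo, hi = contig.pos, contig.pos + a_len - 1
            if ext is None:
                ext = (contig.chrom, lo, hi)
            else:
                ext = (ext[0], min(ext[1], lo), max(ext[2], hi))
        if ext is not None:
            anchor_extent[c.id] = ext
    links += phasing_mod.sc_trans_links(
        calls, anchor_extent, neighbourhood=int(1.5 * metrics.max_fragment)
    )
    bps = [c for c in calls if isinstance(c, BreakpointCall)]
    t_links, collapsed = phasing_mod.transitive_collapse(bps)
    links += t_links
    return links, collapsed
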