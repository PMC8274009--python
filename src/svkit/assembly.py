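"""Positional de Bruijn graph breakend assembly.

Evidence reads near a putative junction are decomposed into kmers whose
placement is constrained by the anchoring alignment: kmers from anchored
bases occupy exact junction-relative positions (one node per offset), while
kmers at or beyond the junction -- clipped bases and unmapped-mate
sequence, whose true offset is unknown -- share a single positional bucket.
Assembly follows maximal-weight extensions through the bucket; revisiting a
node (an unresolved repeat loop, e.g. a polyA run or satellite unit shorter
than k) truncates the contig.

All assembly is performed in a HEAD-canonical orientation (novel sequence
to the right of the junction); TAIL windows are reverse-complemented in and
out.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .evidence import LibraryMetrics
from .model import (
    HEAD,
    TAIL,
    AssemblyContig,
    Direction,
    EvidenceItem,
    EvidenceKind,
    revcomp,
)

log = logging.getLogger(__name__)

DEFAULT_K = 25
MAX_ANCHOR_BP = 300
PATH_COUNT_LIMIT = 50_000
PATH_LIMIT_STRIKES = 3
CLUSTER_GAP = 8  # bp slack when grouping clip positions into one junction

ASSEMBLY_KINDS = (
    EvidenceKind.SOFT_CLIP,
    EvidenceKind.SPLIT_READ,
    EvidenceKind.UNMAPPED_MATE,
)


@dataclass
class _Contribution:
    """One read's input to a HEAD-canonical window: anchored bases ending
    at the junction plus novel bases following it."""

    fragment_id: str
    sample: str
    kind: EvidenceKind
    anchor: str  # ends at the junction
    novel: str  # starts just past the junction
    anchored: bool  # exact junction-relative placement known


def _canonical(item: EvidenceItem, window_dir: Direction) -> _Contribution:
    anchored = item.kind is not EvidenceKind.UNMAPPED_MATE
    if window_dir is HEAD:
        anchor, novel = item.anchor_seq, item.seq
    else:
        anchor, novel = revcomp(item.anchor_seq), revcomp(item.seq)
    return _Contribution(
        item.fragment_id, item.sample, item.kind, anchor[-MAX_ANCHOR_BP:], novel, anchored
    )


@dataclass
class _BucketNode:
    weight: int = 0
    fragments: set = field(default_factory=set)


class PositionalGraph:
    """De Bruijn graph of one junction window (HEAD-canonical space)."""

    def __init__(self, k: int):
        self.k = k
        # anchored nodes: (offset, kmer) -> weight/fragments; offset is the
        # junction-relative start (negative, kmer fully before the junction)
        self.anchored: dict[tuple[int, str], _BucketNode] = defaultdict(_BucketNode)
        # bucket nodes: kmer -> node (position only constrained to the window)
        self.bucket: dict[str, _BucketNode] = defaultdict(_BucketNode)
        self.anchor_cols: dict[int, Counter] = defaultdict(Counter)
        self.contributions: list[_Contribution] = []

    def add(self, contrib: _Contribution) -> None:
        self.contributions.append(contrib)
        k = self.k
        seq = contrib.anchor + contrib.novel
        a = len(contrib.anchor)
        if contrib.anchored:
            for off in range(-a, 0):
                self.anchor_cols[off][seq[a + off]] += 1
        for s in range(0, len(seq) - k + 1):
            kmer = seq[s : s + k]
            off = s - a  # junction-relative start offset
            if contrib.anchored and off + k <= 0:
                node = self.anchored[(off, kmer)]
            else:
                node = self.bucket[kmer]
            node.weight += 1
            node.fragments.add(contrib.fragment_id)


def build_graph(
    evidence: Iterable[EvidenceItem],
    k: int = DEFAULT_K,
    metrics: Optional[LibraryMetrics] = None,
    window_dir: Direction = HEAD,
) -> PositionalGraph:
    """Build the positional graph for one genomic window and direction."""
    g = PositionalGraph(k)
    for item in evidence:
        if item.kind not in ASSEMBLY_KINDS:
            continue
        g.add(_canonical(item, window_dir))
    return g


def _consensus_anchor(g: PositionalGraph) -> str:
    out = []
    off = -1
    while off >= -MAX_ANCHOR_BP:
        col = g.anchor_cols.get(off)
        if not col:
            break
        out.append(max(col.items(), key=lambda kv: (kv[1], kv[0]))[0])
        off -= 1
    return "".join(reversed(out))


def assemble_graph(
    g: PositionalGraph,
    metrics: LibraryMetrics,
    chrom: str,
    pos: int,
    dir_: Direction,
    contig_id: str,
    max_len: Optional[int] = None,
) -> Optional[AssemblyContig]:
    """Extract the maximal-weight breakend contig from a window graph.

    Returns None for reference-only windows or contigs exceeding 1.5x the
    maximum fragment size.  Ties between equally weighted extensions are
    broken lexicographically on the kmer, so assembly is order-independent.
    """
    k = g.k
    anchor = _consensus_anchor(g)
    if len(anchor) < k - 1:
        return None
    breakend: list[str] = []
    visited: set[str] = set()
    truncated = False
    # per-fragment contig base interval (1-based over anchor+breakend)
    support: dict[str, list[int]] = {}
    cur = anchor[-(k - 1) :]
    limit = max_len if max_len is not None else int(1.5 * metrics.max_fragment)
    alt_paths = 1
    while True:
        cands = [
            (node.weight, kmer)
            for kmer, node in g.bucket.items()
            if kmer.startswith(cur)
        ]
        if not cands:
            break
        cands.sort(key=lambda t: (-t[0], t[1]))
        alt_paths *= len(cands)
        if len(cands) > 1 and cands[0][0] == cands[1][0]:
            # equally-weighted alternative extensions: an unresolved branch
            # (e.g. a repeat loop shorter than k) -- truncate rather than guess
            truncated = True
            break
        _, kmer = cands[0]
        if kmer in visited:
            truncated = True
            break
        visited.add(kmer)
        breakend.append(kmer[-1])
        node = g.bucket[kmer]
        cpos = len(anchor) + len(breakend)  # last base of this kmer
        for frag in node.fragments:
            iv = support.setdefault(frag, [cpos - k + 1, cpos])
            iv[0] = min(iv[0], cpos - k + 1)
            iv[1] = max(iv[1], cpos)
        if len(anchor) + len(breakend) > limit:
            return None
        cur = kmer[1:]
    if not breakend:
        return None  # reference-supporting only
    g.last_alt_paths = alt_paths  # type: ignore[attr-defined]
    # anchored fragments also support their anchor span
    a = len(anchor)
    samples: dict[str, str] = {}
    kinds: dict[str, EvidenceKind] = {}
    for contrib in g.contributions:
        frag = contrib.fragment_id
        samples[frag] = contrib.sample
        kinds.setdefault(frag, contrib.kind)
        if contrib.anchored and contrib.anchor:
            lo = a - len(contrib.anchor) + 1
            iv = support.setdefault(frag, [lo, a])
            iv[0] = min(iv[0], lo)
            # novel bases the read carries that made it into the consensus
            matched = _match_len(contrib.novel, "".join(breakend))
            iv[1] = max(iv[1], a + matched)
    support_map = {f: (iv[0], iv[1]) for f, iv in support.items()}
    bseq = "".join(breakend)
    if dir_ is TAIL:
        anchor_out, bseq_out = revcomp(anchor), revcomp(bseq)
        ln = len(anchor) + len(bseq)
        support_map = {
            f: (ln - hi + 1, ln - lo + 1) for f, (lo, hi) in support_map.items()
        }
    else:
        anchor_out, bseq_out = anchor, bseq
    return AssemblyContig(
        id=contig_id,
        chrom=chrom,
        pos=pos,
        dir=dir_,
        anchor_seq=anchor_out,
        breakend_seq=bseq_out,
        support=support_map,
        fragment_samples=samples,
        fragment_kinds=kinds,
        truncated=truncated,
    )


def _match_len(novel: str, consensus: str) -> int:
    n = 0
    for a, b in zip(novel, consensus):
        if a != b:
            break
        n += 1
    return n


def cluster_windows(
    items: list[EvidenceItem], metrics: LibraryMetrics
) -> list[tuple[str, Direction, int, list[EvidenceItem]]]:
    """Group evidence into per-junction assembly windows.

    Precisely placed items (clips / split reads) cluster by breakend
    position with a small homology slack; unmapped-mate items join every
    cluster their placement interval is compatible with.
    """
    precise: dict[tuple[str, Direction], list[EvidenceItem]] = defaultdict(list)
    fuzzy: dict[tuple[str, Direction], list[EvidenceItem]] = defaultdict(list)
    for it in items:
        key = (it.local.chrom, it.local.dir)
        if it.kind in (EvidenceKind.SOFT_CLIP, EvidenceKind.SPLIT_READ):
            precise[key].append(it)
        elif it.kind is EvidenceKind.UNMAPPED_MATE:
            fuzzy[key].append(it)
    windows = []
    for key, its in precise.items():
        chrom, dir_ = key
        its.sort(key=lambda it: it.local.lo)
        cluster: list[EvidenceItem] = []
        for it in its:
            if cluster and it.local.lo - cluster[-1].local.lo > CLUSTER_GAP:
                windows.append(_finish_window(chrom, dir_, cluster, fuzzy.get(key, ())))
                cluster = []
            cluster.append(it)
        if cluster:
            windows.append(_finish_window(chrom, dir_, cluster, fuzzy.get(key, ())))
    windows.sort(key=lambda w: (w[0], w[2], w[1].value))
    return windows


def _finish_window(chrom, dir_, cluster, fuzzy):
    pos = Counter(it.local.lo for it in cluster).most_common(1)[0][0]
    members = list(cluster)
    for it in fuzzy:
        if it.local.lo <= pos <= it.local.hi:
            members.append(it)
    return (chrom, dir_, pos, members)


def assemble(
    items: list[EvidenceItem],
    metrics: LibraryMetrics,
    k: int = DEFAULT_K,
) -> list[AssemblyContig]:
    """Assemble all SV-supporting evidence into breakend contigs."""
    contigs = []
    strikes = 0
    for n, (chrom, dir_, pos, members) in enumerate(cluster_windows(items, metrics)):
        g = build_graph(members, k=k, metrics=metrics, window_dir=dir_)
        contig = assemble_graph(
            g, metrics, chrom, pos, dir_, contig_id=f"asm{n}_{chrom}_{pos}{dir_.value}"
        )
        if contig is None:
            continue
        if getattr(g, "last_alt_paths", 1) > PATH_COUNT_LIMIT:
            strikes += 1
            if strikes >= PATH_LIMIT_STRIKES:
                log.warning("assembly window flushed after %d path-count strikes", strikes)
                break
        contigs.append(contig)
    return contigs


def extend_contigs(
    contigs: list[AssemblyContig], k: int, max_len: int
) -> list[AssemblyContig]:
    """Extend each contig's breakend sequence through overlapping contigs.

    When rearrangements cluster, reads primary-aligned inside a short DNA
    segment assemble into their own window; their contigs overlap the
    neighbouring windows' breakend consensus.  Chaining contigs through
    (k-1)-overlaps reconstructs a consensus spanning several junctions,
    which compound realignment then turns into a >= 3-alignment chain
    (the basis of cis phasing).
    """
    out = []
    for contig in contigs:
        if contig.dir is HEAD:
            seq = contig.sequence
        else:
            seq = revcomp(contig.sequence)
        used = {contig.id}
        extra_support: dict[str, tuple[int, int]] = {}
        extra_samples: dict[str, str] = {}
        extra_kinds: dict[str, EvidenceKind] = {}
        extended = False
        for _ in range(6):
            if len(seq) >= max_len:
                break
            tail = seq[-(k - 1) :]
            best = None
            for other in contigs:
                if other.id in used:
                    continue
                for flip in (False, True):
                    s = other.sequence if not flip else revcomp(other.sequence)
                    i = s.find(tail)
                    if i == -1 or i + k - 1 >= len(s):
                        continue
                    gain = len(s) - (i + k - 1)
                    if best is None or gain > best[0]:
                        best = (gain, other, s, i, flip)
            if best is None:
                break
            gain, other, s, i, flip = best
            offset = len(seq) - (i + k - 1)  # other coords -> merged coords
            seq = seq + s[i + k - 1 :]
            used.add(other.id)
            for frag, (lo, hi) in other.support.items():
                if flip:
                    ln = len(other.sequence)
                    lo, hi = ln - hi + 1, ln - lo + 1
                extra_support[frag] = (max(1, lo + offset), hi + offset)
                extra_samples[frag] = other.fragment_samples.get(frag, "")
                if frag in other.fragment_kinds:
                    extra_kinds[frag] = other.fragment_kinds[frag]
            extended = True
        if not extended:
            out.append(contig)
            continue
        if contig.dir is HEAD:
            anchor = contig.anchor_seq
            breakend = seq[len(anchor) :]
            support = dict(contig.support)
            support.update(extra_support)
        else:
            anchor = contig.anchor_seq
            breakend = revcomp(seq)[: len(seq) - len(anchor)]
            ln = len(seq)
            support = dict(contig.support)
            support.update(
                {f: (ln - hi + 1, ln - lo + 1) for f, (lo, hi) in extra_support.items()}
            )
        merged = AssemblyContig(
            id=contig.id,
            chrom=contig.chrom,
            pos=contig.pos,
            dir=contig.dir,
            anchor_seq=anchor,
            breakend_seq=breakend,
            support=support,
            fragment_samples={**contig.fragment_samples, **extra_samples},
            fragment_kinds={**contig.fragment_kinds, **extra_kinds},
            truncated=contig.truncated,
        )
        out.append(merged)
    return out


def fragment_supports_breakpoint(
    contig: AssemblyContig, fragment_id: str, homology: tuple[int, int]
) -> bool:
    """True iff the fragment's per-base support extends at least one base
    beyond the homology interval (contig coordinates) on both sides.

    An empty homology interval is the junction base itself: pass
    ``(j, j)`` with lo > hi convention not needed -- use ``(j+1, j)`` to
    denote emptiness at base j+0.5; the fragment must then cover j and j+1.
    """
    if fragment_id not in contig.support:
        raise KeyError(f"fragment {fragment_id} not in contig {contig.id}")
    lo, hi = contig.support[fragment_id]
    h_lo, h_hi = homology
    if h_lo > h_hi:  # empty homology at the junction between h_hi and h_lo
        return lo <= h_hi and hi >= h_lo
    return lo <= h_lo - 1 and hi >= h_hi + 1
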