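"""Library metric estimation and extraction of SV-supporting evidence.

Admission rules applied here:

* soft/hard clips shorter than 5 bp and indels under 5 bp are treated as
  consistent with the reference;
* reads with mapping quality below 20 are treated as unmapped and
  contribute only as unmapped mates of their (well-mapped) partner;
* duplicate and secondary/supplementary records are never emitted;
* low-entropy reads and adapter soft clips are suppressed;
* evidence in extreme-coverage pileups (> 50,000x by default) is dropped.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .model import (
    HEAD,
    TAIL,
    BreakendInterval,
    Direction,
    EvidenceItem,
    EvidenceKind,
    revcomp,
)

log = logging.getLogger(__name__)

MIN_CLIP_BP = 5
MIN_INDEL_BP = 5
MIN_MAPQ = 20
DEFAULT_ENTROPY_THRESHOLD = 0.5
DEFAULT_COVERAGE_THRESHOLD = 50_000
CONCORDANT_CENTRAL_MASS = 0.995

# Illumina TruSeq / Nextera adapter starts
DEFAULT_ADAPTERS = (
    "AGATCGGAAGAGC",  # TruSeq universal
    "CTGTCTCTTATACACATCT",  # Nextera
)

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class SAEntry:
    """One supplementary alignment of a chimeric read.

    Internal convention: ``cigar`` is expressed in the orientation of the
    *stored* primary sequence and ``strand`` is the reference strand that
    the stored sequence aligns to at ``chrom:pos`` ('+' = forward).  SAM
    ``SA`` tags (sequenced-read orientation) are converted on ingest.
    """

    chrom: str
    pos: int
    strand: str
    cigar: tuple[tuple[str, int], ...]
    mapq: int


@dataclass
class ReadRecord:
    """Minimal alignment record (SAM semantics, 1-based positions)."""

    name: str
    chrom: str
    pos: int
    strand: str
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    seq: str
    is_read1: bool = True
    mate_chrom: Optional[str] = None
    mate_pos: int = 0
    mate_strand: str = "+"
    mate_mapped: bool = True
    mate_mapq: Optional[int] = None
    tlen: int = 0
    is_duplicate: bool = False
    is_secondary: bool = False
    sa: tuple[SAEntry, ...] = ()

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if self.seq and consumed != len(self.seq):
            raise ValueError(
                f"CIGAR consumes {consumed} bases but sequence has {len(self.seq)}"
            )

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS) - 1

    @property
    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0

    @property
    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] in "SH" else 0


@dataclass
class LibraryMetrics:
    """Empirical library profile estimated from the first reads of a file."""

    fragment_size_hist: dict[int, float]
    concordant_lo: int
    concordant_hi: int
    max_fragment: int
    cigar_rates: dict[tuple[str, int], float]
    unmapped_mate_rate: float
    discordant_rate: float
    read_length: int
    n_reads: int
    n_pairs: int

    @property
    def rate_floor(self) -> float:
        return 1.0 / max(1, self.n_reads)

    def fragment_tail_prob(self, tlen: int) -> float:
        """P(|fragment| at least as extreme as tlen) under the empirical
        distribution; used to score within-range discordant pairs."""
        sizes = np.array(sorted(self.fragment_size_hist))
        probs = np.array([self.fragment_size_hist[s] for s in sizes])
        upper = probs[sizes >= tlen].sum()
        lower = probs[sizes <= tlen].sum()
        return max(self.rate_floor, min(upper, lower))

    def to_dict(self) -> dict:
        return {
            "fragment_size_hist": {str(k): v for k, v in self.fragment_size_hist.items()},
            "concordant_lo": self.concordant_lo,
            "concordant_hi": self.concordant_hi,
            "max_fragment": self.max_fragment,
            "cigar_rates": {f"{op}:{ln}": r for (op, ln), r in self.cigar_rates.items()},
            "unmapped_mate_rate": self.unmapped_mate_rate,
            "discordant_rate": self.discordant_rate,
            "read_length": self.read_length,
            "n_reads": self.n_reads,
            "n_pairs": self.n_pairs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryMetrics":
        cig = {}
        for key, r in d["cigar_rates"].items():
            op, ln = key.split(":")
            cig[(op, int(ln))] = r
        return cls(
            fragment_size_hist={int(k): v for k, v in d["fragment_size_hist"].items()},
            concordant_lo=d["concordant_lo"],
            concordant_hi=d["concordant_hi"],
            max_fragment=d["max_fragment"],
            cigar_rates=cig,
            unmapped_mate_rate=d["unmapped_mate_rate"],
            discordant_rate=d.get("discordant_rate", 0.0),
            read_length=d["read_length"],
            n_reads=d["n_reads"],
            n_pairs=d["n_pairs"],
        )


def _quantile_index(q: float, n: int) -> int:
    """Index into a sorted sample for quantile q: ceil(q*n), 1-based."""
    return min(n - 1, max(0, math.ceil(q * n) - 1))


def estimate_library_metrics(
    reads: Iterable[ReadRecord],
    max_reads: int = 10_000_000,
    central_mass: float = CONCORDANT_CENTRAL_MASS,
) -> LibraryMetrics:
    """Estimate the fragment-size distribution and per-read CIGAR operator
    rates from the first ``max_reads`` records.

    Concordant bounds cover the central ``central_mass`` (default 99.5%) of
    proper-pair template lengths: the 0.25% and 99.75% empirical quantiles.
    """
    tlens: list[int] = []
    cigar_counts: Counter = Counter()
    n_mapped = 0
    n_unmapped_mate = 0
    n_geom_discordant = 0  # different chromosome or same-strand pair
    read_lengths: Counter = Counter()
    for i, r in enumerate(reads):
        if i >= max_reads:
            break
        if r.is_duplicate or r.is_secondary:
            continue
        n_mapped += 1
        read_lengths[len(r.seq)] += 1
        for op, ln in r.cigar:
            if op in "SHID":
                cigar_counts[("S" if op == "H" else op, ln)] += 1
        if not r.mate_mapped:
            n_unmapped_mate += 1
        elif r.mate_chrom != r.chrom or r.strand == r.mate_strand:
            n_geom_discordant += 1
        # proper-ish pair: both mapped, same chromosome, FR, positive tlen
        # counted once from the leftmost read
        if (
            r.mate_mapped
            and r.mate_chrom == r.chrom
            and r.strand != r.mate_strand
            and r.tlen > 0
        ):
            tlens.append(r.tlen)
    if not tlens:
        raise ValueError("cannot estimate fragment distribution: no proper pairs")
    tlens.sort()
    # robust trimming: template lengths an order of magnitude beyond the
    # median are chimeric/SV-spanning, not library fragments
    med = tlens[len(tlens) // 2]
    tlens = [t for t in tlens if t <= 10 * med]
    n = len(tlens)
    tail = (1.0 - central_mass) / 2.0
    lo = tlens[_quantile_index(tail, n)]
    hi = tlens[_quantile_index(1.0 - tail, n)]
    n_len_discordant = sum(1 for t in tlens if t < lo or t > hi) * 2
    discordant_rate = (n_geom_discordant + n_len_discordant) / max(1, n_mapped)
    hist_counts = Counter(tlens)
    hist = {k: v / n for k, v in hist_counts.items()}
    rates = {k: v / max(1, n_mapped) for k, v in cigar_counts.items()}
    return LibraryMetrics(
        fragment_size_hist=hist,
        concordant_lo=lo,
        concordant_hi=hi,
        max_fragment=hi,
        cigar_rates=rates,
        unmapped_mate_rate=n_unmapped_mate / max(1, n_mapped),
        discordant_rate=discordant_rate,
        read_length=read_lengths.most_common(1)[0][0],
        n_reads=n_mapped,
        n_pairs=n,
    )


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits per base) of the base composition."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def is_adapter_clip(
    clip_seq: str,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.0,
) -> bool:
    """True iff a prefix of an adapter matches the clip end-anchored with a
    mismatch rate <= ``max_mismatch_rate`` over >= ``min_overlap`` bases.

    Both orientations of the clip are checked (left-side clips present the
    adapter reverse-complemented).
    """
    if not clip_seq:
        return False
    for cand in (clip_seq.upper(), revcomp(clip_seq.upper())):
        for adapter in adapters:
            n = min(len(cand), len(adapter))
            if n < min_overlap:
                continue
            mism = sum(1 for a, b in zip(cand[:n], adapter[:n]) if a != b)
            if mism <= max_mismatch_rate * n:
                return True
    return False


def looks_like_adapter(clip_seq: str, adapters: Sequence[str] = DEFAULT_ADAPTERS) -> bool:
    """Default adapter rule: exact 6 bp overlap, or >= 12 bp at <= 10%."""
    return is_adapter_clip(clip_seq, adapters, 6, 0.0) or is_adapter_clip(
        clip_seq, adapters, 12, 0.10
    )


def _sa_query_interval(entry: SAEntry) -> tuple[int, int]:
    """Query interval (1-based, stored-sequence orientation) covered by a
    supplementary alignment."""
    lead = entry.cigar[0][1] if entry.cigar[0][0] in "SH" else 0
    aligned = sum(n for op, n in entry.cigar if op in "MI=X")
    return lead + 1, lead + aligned


def _remote_from_sa(entry: SAEntry, local_dir: Direction) -> BreakendInterval:
    """Breakend implied on the far side of a split alignment.

    For a HEAD local breakend (clip to the right of the anchor) the clipped
    bases *enter* the remote locus: forward-strand alignments are entered
    at their left edge (remote TAIL), reverse-strand at their right edge
    (remote HEAD); mirrored for TAIL local breakends.
    """
    ref_end = entry.pos + sum(n for op, n in entry.cigar if op in _REF_OPS) - 1
    forward = entry.strand == "+"
    entering = local_dir is HEAD
    if entering == forward:
        return BreakendInterval(entry.chrom, entry.pos, entry.pos, TAIL)
    return BreakendInterval(entry.chrom, ref_end, ref_end, HEAD)


def classify_read(
    read: ReadRecord,
    metrics: LibraryMetrics,
    mate_seq: Optional[str] = None,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    sample: str = "sample",
    mate_is_low_mapq: Optional[bool] = None,
) -> list[EvidenceItem]:
    """Classify one mapped primary read into its evidence contributions.

    Unclassifiable reads yield the empty list.  Reads with mapq < 20 are
    treated as unmapped here (their partner picks them up as UNMAPPED_MATE).
    """
    out: list[EvidenceItem] = []
    if read.is_duplicate or read.is_secondary:
        return out
    if read.mapq < MIN_MAPQ:
        return out
    if read.seq and sequence_entropy(read.seq) < entropy_threshold:
        return out
    frag = f"{sample}:{read.name}"
    names = (read.name,)

    mate_low = mate_is_low_mapq
    if mate_low is None:
        mate_low = read.mate_mapq is not None and read.mate_mapq < MIN_MAPQ
    mate_unmapped_like = (not read.mate_mapped) or mate_low

    # -- split reads -------------------------------------------------------
    sa_ok = bool(read.sa) and all(e.mapq >= MIN_MAPQ for e in read.sa)
    clip_items: list[tuple[Direction, int, str, str]] = []  # dir,pos,clip,anchor
    aligned_lo = read.clip_left + 1
    aligned_hi = len(read.seq) - read.clip_right
    if read.clip_right >= MIN_CLIP_BP:
        clip = read.seq[aligned_hi:]
        anchor = read.seq[max(0, aligned_lo - 1) : aligned_hi]
        clip_items.append((HEAD, read.ref_end, clip, anchor))
    if read.clip_left >= MIN_CLIP_BP:
        clip = read.seq[: read.clip_left]
        anchor = read.seq[aligned_lo - 1 : aligned_hi]
        clip_items.append((TAIL, read.pos, clip, anchor))

    for dir_, pos, clip, anchor in clip_items:
        if clip and looks_like_adapter(clip, adapters):
            continue
        local = BreakendInterval(read.chrom, pos, pos, dir_)
        if sa_ok:
            # attribute the clip to the SA segment covering that query side
            entry = _pick_sa_for_side(read, dir_)
            if entry is not None:
                out.append(
                    EvidenceItem(
                        frag, sample, EvidenceKind.SPLIT_READ,
                        local, _remote_from_sa(entry, dir_),
                        seq=clip, anchor_seq=anchor,
                        local_mapq=read.mapq, remote_mapq=entry.mapq,
                        read_names=names, read_strand=read.strand,
                        anchor_lo=read.pos, anchor_hi=read.ref_end,
                    )
                )
                continue
        if read.sa:
            continue  # chimeric but ambiguous side / low-mapq chain: no item
        out.append(
            EvidenceItem(
                frag, sample, EvidenceKind.SOFT_CLIP,
                local, None, seq=clip, anchor_seq=anchor,
                local_mapq=read.mapq, read_names=names, read_strand=read.strand,
                anchor_lo=read.pos, anchor_hi=read.ref_end,
            )
        )

    # -- indels ------------------------------------------------------------
    ref_cursor = read.pos
    q_cursor = 0
    for op, ln in read.cigar:
        if op in "M=X":
            ref_cursor += ln
            q_cursor += ln
        elif op in "SH":
            q_cursor += ln if op == "S" else 0
        elif op == "I":
            if ln >= MIN_INDEL_BP:
                left = ref_cursor - 1
                out.append(
                    EvidenceItem(
                        frag, sample, EvidenceKind.INDEL,
                        BreakendInterval(read.chrom, left, left, HEAD),
                        BreakendInterval(read.chrom, left + 1, left + 1, TAIL),
                        seq=read.seq[q_cursor : q_cursor + ln],
                        local_mapq=read.mapq, remote_mapq=read.mapq,
                        read_names=names, read_strand=read.strand,
                        anchor_lo=read.pos, anchor_hi=read.ref_end,
                    )
                )
            q_cursor += ln
        elif op in "DN":
            if op == "D" and ln >= MIN_INDEL_BP:
                left = ref_cursor - 1
                out.append(
                    EvidenceItem(
                        frag, sample, EvidenceKind.INDEL,
                        BreakendInterval(read.chrom, left, left, HEAD),
                        BreakendInterval(read.chrom, left + ln + 1, left + ln + 1, TAIL),
                        local_mapq=read.mapq, remote_mapq=read.mapq,
                        read_names=names, read_strand=read.strand,
                        anchor_lo=read.pos, anchor_hi=read.ref_end,
                    )
                )
            ref_cursor += ln

    # -- read-pair evidence ------------------------------------------------
    if mate_unmapped_like:
        local = _pair_interval(read, metrics)
        if local is not None:
            bseq = ""
            if mate_seq:
                raw = mate_seq if read.mate_strand == "+" or not read.mate_mapped else revcomp(mate_seq)
                # breakend-ordered: HEAD side continues right on the derivative
                bseq = revcomp(raw) if local.dir is HEAD else raw
            out.append(
                EvidenceItem(
                    frag, sample, EvidenceKind.UNMAPPED_MATE,
                    local, None, seq=bseq,
                    local_mapq=read.mapq, read_names=names, read_strand=read.strand,
                    anchor_lo=read.pos, anchor_hi=read.ref_end,
                )
            )
    elif read.mate_mapped and _is_discordant(read, metrics):
        local = _pair_interval(read, metrics)
        remote = _mate_interval(read, metrics)
        if local is not None and remote is not None:
            out.append(
                EvidenceItem(
                    frag, sample, EvidenceKind.DISCORDANT_PAIR,
                    local, remote,
                    local_mapq=read.mapq,
                    remote_mapq=read.mate_mapq if read.mate_mapq is not None else read.mapq,
                    read_names=names, read_strand=read.strand,
                    anchor_lo=read.pos, anchor_hi=read.ref_end,
                )
            )
    return out


def _pick_sa_for_side(read: ReadRecord, dir_: Direction) -> Optional[SAEntry]:
    """SA entry whose query interval lies on the clipped side (the one
    closest to the anchor when the chain has several segments)."""
    aligned_lo = read.clip_left + 1
    aligned_hi = len(read.seq) - read.clip_right
    best = None
    for entry in read.sa:
        qlo, qhi = _sa_query_interval(entry)
        if dir_ is HEAD and qlo > aligned_hi - 1:
            if best is None or qlo < _sa_query_interval(best)[0]:
                best = entry
        elif dir_ is TAIL and qhi < aligned_lo + 1:
            if best is None or qhi > _sa_query_interval(best)[1]:
                best = entry
    return best


def _is_discordant(read: ReadRecord, metrics: LibraryMetrics) -> bool:
    if read.mate_chrom != read.chrom:
        return True
    if read.strand == read.mate_strand:
        return True
    t = abs(read.tlen)
    return t < metrics.concordant_lo or t > metrics.concordant_hi


def _pair_interval(read: ReadRecord, metrics: LibraryMetrics) -> Optional[BreakendInterval]:
    """Interval in which the junction anchored by this read must lie."""
    span = read.ref_end - read.pos + 1
    width = metrics.concordant_hi - span
    if width < 0:
        width = 0
    if read.strand == "+":
        return BreakendInterval(read.chrom, read.ref_end, read.ref_end + width, HEAD)
    return BreakendInterval(read.chrom, read.pos - width, read.pos, TAIL)


def _mate_interval(read: ReadRecord, metrics: LibraryMetrics) -> Optional[BreakendInterval]:
    rl = metrics.read_length
    width = max(0, metrics.concordant_hi - rl)
    ms = read.mate_pos
    me = ms + rl - 1
    if read.mate_strand == "+":
        return BreakendInterval(read.mate_chrom, me, me + width, HEAD)
    return BreakendInterval(read.mate_chrom, ms - width, ms, TAIL)


def exclude_high_coverage(
    evidence: Iterable[EvidenceItem],
    depth: dict[str, np.ndarray],
    threshold: int = DEFAULT_COVERAGE_THRESHOLD,
) -> Iterator[EvidenceItem]:
    """Drop evidence whose local breakend sits in a pileup deeper than
    ``threshold``; depth arrays are 1-based indexed (index 0 unused)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dropped = 0
    for item in evidence:
        arr = depth.get(item.local.chrom)
        pos = min(item.local.lo, len(arr) - 1) if arr is not None else 0
        if arr is not None and arr[pos] > threshold:
            dropped += 1
            continue
        yield item
    if dropped:
        log.info("excluded %d evidence items in >%dx pileups", dropped, threshold)


def realign_soft_clips(read: ReadRecord, aligner, reference) -> ReadRecord:
    """Convert a plain soft-clipped read into a chimeric split read when its
    clipped bases align uniquely (effective mapq >= 20).

    ``aligner`` follows the align_homology engine contract.  The read is
    returned unchanged when the clip is ambiguous or adapter-derived.
    """
    if read.sa or (read.clip_left < MIN_CLIP_BP and read.clip_right < MIN_CLIP_BP):
        return read
    entries: list[SAEntry] = []
    for side, clip_len in (("right", read.clip_right), ("left", read.clip_left)):
        if clip_len < MIN_CLIP_BP:
            continue
        clip = read.seq[-clip_len:] if side == "right" else read.seq[:clip_len]
        if looks_like_adapter(clip):
            continue
        hits = aligner.align(clip, reference)
        if not hits:
            continue
        best = hits[0]
        if best.mapq < MIN_MAPQ:
            continue
        aligned = best.query_hi - best.query_lo + 1
        # clip-local -> stored-sequence coordinates
        offset = len(read.seq) - clip_len if side == "right" else 0
        pre = offset + best.query_lo - 1
        post = len(read.seq) - (offset + best.query_hi)
        cigar = tuple(
            (op, n)
            for op, n in (("S", pre), ("M", aligned), ("S", post))
            if n > 0
        )
        entries.append(
            SAEntry(best.chrom, best.ref_lo, best.strand, cigar, best.mapq)
        )
    if not entries:
        return read
    from dataclasses import replace

    return replace(read, sa=read.sa + tuple(entries))
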