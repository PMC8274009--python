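"""Synthetic tumour/normal genome and read simulation, plus truth matching.

The simulator emulates the read-level signatures a somatic SV caller
consumes: paired-end fragments with a Gaussian size distribution,
soft-clipped/split reads at junctions (with SA chains), discordant pairs,
mapq-0 placement of reads wholly inside repeat arrays (the single-breakend
case), tumour purity mixing and uniform substitution errors.  Reads are
emitted truth-placed as coordinate-sorted SAM, so no external aligner is
needed and output is deterministic under the seed.

Default read parameters mirror a standard 2x150 bp Illumina WGS library
(fragment mean 500 bp, s.d. 100 bp) with a 60x tumour and 40x matched
normal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .model import HEAD, TAIL, Breakend, BreakpointCall, Direction, SingleBreakendCall, revcomp

SA_MIN_BP = 20  # shortest read piece reported as a supplementary alignment
BASES = np.frombuffer(b"ACGT", dtype="S1")


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RepeatArray:
    """A tandem repeat array (e.g. a satellite): ``copies`` x ``unit_len``
    starting at ``start`` on ``chrom``; reads wholly inside it are placed
    at an arbitrary unit with mapq 0."""

    chrom: str
    start: int
    unit_len: int = 171
    copies: int = 50

    @property
    def end(self) -> int:
        return self.start + self.unit_len * self.copies - 1


@dataclass(frozen=True)
class SVSpec:
    """One planted rearrangement.

    ``type``: DEL, DUP, INV, INS, TRA, FOLDBACK, BND_INTO_REPEAT or
    CLUSTERED_CHAIN.  ``pos`` is the last reference base before the first
    junction.  CHAIN donors are (chrom, start, length) segments inserted
    between ``pos`` and ``pos+1``.
    """

    type: str
    chrom: str
    pos: int
    size: int = 0
    chrom2: Optional[str] = None
    pos2: int = 0
    donors: tuple[tuple[str, int, int], ...] = ()
    germline: bool = False


@dataclass
class SimConfig:
    seed: int = 1
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    repeats: tuple[RepeatArray, ...] = ()
    svs: tuple[SVSpec, ...] = ()
    read_length: int = 150
    coverage_tumour: float = 60.0
    coverage_normal: float = 40.0
    fragment_mean: int = 500
    fragment_sd: int = 100
    base_error: float = 0.0
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


class TruthClass(enum.Enum):
    MATCH_BREAKPOINT = "breakpoint"
    MATCH_BREAKEND = "breakend"
    ONE_SIDE_CORRECT = "one_side"
    FALSE_NEGATIVE = "fn"


@dataclass
class TruthSV:
    type: str
    b1: Breakend
    b2: Optional[Breakend]
    size: int
    expect: str  # BREAKPOINT | SINGLE_BREAKEND
    insert_len: int = 0

    def row(self) -> str:
        b2 = self.b2
        return "\t".join(
            [
                self.b1.chrom, str(self.b1.pos), self.b1.dir.value,
                b2.chrom if b2 else ".", str(b2.pos) if b2 else ".",
                b2.dir.value if b2 else ".",
                self.type, str(self.size), self.expect,
            ]
        )

    @classmethod
    def parse(cls, line: str) -> "TruthSV":
        f = line.rstrip("\n").split("\t")
        b2 = None
        if f[3] != ".":
            b2 = Breakend(f[3], int(f[4]), Direction(f[5]))
        return cls(f[6], Breakend(f[0], int(f[1]), Direction(f[2])), b2, int(f[7]), f[8])


TRUTH_HEADER = "chrom1\tpos1\tdir1\tchrom2\tpos2\tdir2\ttype\tsize\texpect"


# --------------------------------------------------------------------------
# genome construction


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int  # inclusive
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Insert:
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


Part = Union[Segment, Insert]


def random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    ref: dict[str, str] = {}
    for chrom, length in config.chrom_lengths.items():
        seq = rng.choice(BASES, size=length)
        ref[chrom] = b"".join(seq.tolist()).decode()
    for rep in config.repeats:
        unit = b"".join(rng.choice(BASES, size=rep.unit_len).tolist()).decode()
        arr = (unit * rep.copies)[: rep.unit_len * rep.copies]
        s = ref[rep.chrom]
        if rep.end > len(s):
            raise ValueError("repeat array exceeds chromosome")
        ref[rep.chrom] = s[: rep.start - 1] + arr + s[rep.end :]
    return ref


def _apply_inline(
    chrom: str, length: int, svs: list[SVSpec], rng: np.random.Generator
) -> tuple[list[Part], list[TruthSV]]:
    """Apply DEL/DUP/INV/INS/CLUSTERED_CHAIN to one chromosome."""
    parts: list[Part] = []
    truth: list[TruthSV] = []
    cursor = 1
    for sv in sorted(svs, key=lambda s: s.pos):
        if sv.pos < cursor:
            raise ValueError(f"overlapping rearrangements at {chrom}:{sv.pos}")
        t = sv.type
        if t == "DEL":
            parts.append(Segment(chrom, cursor, sv.pos))
            cursor = sv.pos + sv.size + 1
            truth.append(
                TruthSV("DEL", Breakend(chrom, sv.pos, HEAD),
                        Breakend(chrom, cursor, TAIL), sv.size, "BREAKPOINT")
            )
        elif t == "DUP":
            dup_lo, dup_hi = sv.pos + 1, sv.pos + sv.size
            parts.append(Segment(chrom, cursor, dup_hi))
            parts.append(Segment(chrom, dup_lo, dup_hi))
            cursor = dup_hi + 1
            truth.append(
                TruthSV("DUP", Breakend(chrom, dup_hi, HEAD),
                        Breakend(chrom, dup_lo, TAIL), sv.size, "BREAKPOINT")
            )
        elif t == "INV":
            inv_lo, inv_hi = sv.pos + 1, sv.pos + sv.size
            parts.append(Segment(chrom, cursor, sv.pos))
            parts.append(Segment(chrom, inv_lo, inv_hi, "-"))
            cursor = inv_hi + 1
            truth.append(
                TruthSV("INV", Breakend(chrom, sv.pos, HEAD),
                        Breakend(chrom, inv_hi, HEAD), sv.size, "BREAKPOINT")
            )
            truth.append(
                TruthSV("INV", Breakend(chrom, inv_lo, TAIL),
                        Breakend(chrom, inv_hi + 1, TAIL), sv.size, "BREAKPOINT")
            )
        elif t == "INS":
            ins = b"".join(rng.choice(BASES, size=sv.size).tolist()).decode()
            parts.append(Segment(chrom, cursor, sv.pos))
            parts.append(Insert(ins))
            cursor = sv.pos + 1
            truth.append(
                TruthSV("INS", Breakend(chrom, sv.pos, HEAD),
                        Breakend(chrom, sv.pos + 1, TAIL), sv.size,
                        "BREAKPOINT", insert_len=sv.size)
            )
        elif t == "CLUSTERED_CHAIN":
            parts.append(Segment(chrom, cursor, sv.pos))
            prev = Breakend(chrom, sv.pos, HEAD)
            for d_chrom, d_start, d_len in sv.donors:
                parts.append(Segment(d_chrom, d_start, d_start + d_len - 1))
                truth.append(
                    TruthSV("BND", prev, Breakend(d_chrom, d_start, TAIL),
                            d_len, "BREAKPOINT")
                )
                prev = Breakend(d_chrom, d_start + d_len - 1, HEAD)
            truth.append(
                TruthSV("BND", prev, Breakend(chrom, sv.pos + 1, TAIL), 0, "BREAKPOINT")
            )
            cursor = sv.pos + 1
        else:  # pragma: no cover
            raise ValueError(f"not an inline rearrangement: {t}")
    parts.append(Segment(chrom, cursor, length))
    return parts, truth


INLINE_TYPES = {"DEL", "DUP", "INV", "INS", "CLUSTERED_CHAIN"}


def build_derivatives(
    config: SimConfig, ref: dict[str, str], rng: np.random.Generator, germline: bool
) -> tuple[list[list[Part]], list[TruthSV]]:
    """Build the rearranged haplotype: one derivative molecule per
    chromosome (inline SVs applied) plus extra molecules for restructuring
    events (translocations, foldbacks, breaks into repeats)."""
    svs = [s for s in config.svs if s.germline == germline]
    molecules: list[list[Part]] = []
    truth: list[TruthSV] = []
    by_chrom: dict[str, list[SVSpec]] = {}
    restructuring: list[SVSpec] = []
    for sv in svs:
        if sv.type in INLINE_TYPES:
            by_chrom.setdefault(sv.chrom, []).append(sv)
        else:
            restructuring.append(sv)
    handled: set[str] = set()
    for sv in restructuring:
        if sv.chrom in by_chrom or (sv.chrom2 or sv.chrom) in by_chrom:
            raise ValueError("restructuring and inline SVs may not share a chromosome")
        t = sv.type
        L1 = len(ref[sv.chrom])
        if t == "TRA":
            L2 = len(ref[sv.chrom2])
            molecules.append(
                [Segment(sv.chrom, 1, sv.pos), Segment(sv.chrom2, sv.pos2, L2)]
            )
            molecules.append([Segment(sv.chrom, sv.pos + 1, L1)])
            molecules.append([Segment(sv.chrom2, 1, sv.pos2 - 1)])
            truth.append(
                TruthSV("TRA", Breakend(sv.chrom, sv.pos, HEAD),
                        Breakend(sv.chrom2, sv.pos2, TAIL), 0, "BREAKPOINT")
            )
            handled |= {sv.chrom, sv.chrom2}
        elif t == "FOLDBACK":
            molecules.append(
                [Segment(sv.chrom, 1, sv.pos),
                 Segment(sv.chrom, 1, sv.pos - sv.size, "-")]
            )
            molecules.append([Segment(sv.chrom, sv.pos + 1, L1)])
            truth.append(
                TruthSV("INV", Breakend(sv.chrom, sv.pos, HEAD),
                        Breakend(sv.chrom, sv.pos - sv.size, HEAD), sv.size,
                        "BREAKPOINT")
            )
            handled.add(sv.chrom)
        elif t == "BND_INTO_REPEAT":
            take = min(len(ref[sv.chrom2]) - sv.pos2 + 1, 6000)
            molecules.append(
                [Segment(sv.chrom, 1, sv.pos),
                 Segment(sv.chrom2, sv.pos2, sv.pos2 + take - 1)]
            )
            molecules.append([Segment(sv.chrom, sv.pos + 1, L1)])
            truth.append(
                TruthSV("BND_INTO_REPEAT", Breakend(sv.chrom, sv.pos, HEAD),
                        Breakend(sv.chrom2, sv.pos2, TAIL), 0, "SINGLE_BREAKEND")
            )
            handled.add(sv.chrom)
        else:
            raise ValueError(f"unknown rearrangement type {t}")
    for chrom, length in config.chrom_lengths.items():
        if chrom in handled:
            continue
        parts, t = _apply_inline(chrom, len(ref[chrom]), by_chrom.get(chrom, []), rng)
        molecules.append(parts)
        truth.extend(t)
    return molecules, truth


def molecule_seq(parts: Sequence[Part], ref: dict[str, str]) -> str:
    out = []
    for p in parts:
        if isinstance(p, Insert):
            out.append(p.seq)
        elif p.strand == "+":
            out.append(ref[p.chrom][p.start - 1 : p.end])
        else:
            out.append(revcomp(ref[p.chrom][p.start - 1 : p.end]))
    return "".join(out)


# --------------------------------------------------------------------------
# read simulation


@dataclass
class _Piece:
    """A maximal run of a read mapping contiguously to the reference."""

    q_lo: int  # 0-based half-open interval on the molecule-forward read
    q_hi: int
    chrom: Optional[str]
    ref_lo: int  # 1-based inclusive
    ref_hi: int
    strand: str  # relative to molecule-forward
    mapq: int

    @property
    def length(self) -> int:
        return self.q_hi - self.q_lo


def _project(
    parts: Sequence[Part],
    offsets: list[int],
    a: int,
    b: int,
    repeats: Sequence[RepeatArray],
    rng: np.random.Generator,
) -> list[_Piece]:
    """Map molecule interval [a, b) (0-based) onto reference pieces."""
    pieces: list[_Piece] = []
    for i, part in enumerate(parts):
        p_lo, p_hi = offsets[i], offsets[i] + part.length
        lo, hi = max(a, p_lo), min(b, p_hi)
        if lo >= hi:
            continue
        if isinstance(part, Insert):
            pieces.append(_Piece(lo - a, hi - a, None, 0, 0, "+", 0))
            continue
        if part.strand == "+":
            r_lo = part.start + (lo - p_lo)
            r_hi = part.start + (hi - p_lo) - 1
            strand = "+"
        else:
            r_hi = part.end - (lo - p_lo)
            r_lo = part.end - (hi - p_lo) + 1
            strand = "-"
        mapq, r_lo, r_hi = _mapq_for(part.chrom, r_lo, r_hi, repeats, rng)
        pieces.append(_Piece(lo - a, hi - a, part.chrom, r_lo, r_hi, strand, mapq))
    return pieces


def _mapq_for(
    chrom: str, r_lo: int, r_hi: int, repeats: Sequence[RepeatArray],
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """mapq 0 with arbitrary-unit placement for pieces wholly inside a
    repeat array; mapq 60 otherwise."""
    for rep in repeats:
        if chrom == rep.chrom and r_lo >= rep.start and r_hi <= rep.end:
            unit = int(rng.integers(0, rep.copies))
            off = (r_lo - rep.start) % rep.unit_len
            span = r_hi - r_lo
            new_lo = rep.start + unit * rep.unit_len + off
            if new_lo + span > rep.end:
                new_lo = rep.start + off
            return 0, new_lo, new_lo + span
    return 60, r_lo, r_hi


@dataclass
class _SimRead:
    name: str
    is_read1: bool
    seq_forward: str  # molecule-forward orientation
    sequenced_reverse: bool  # True for the fragment-right read
    pieces: list[_Piece]

    primary: Optional[_Piece] = None


def _pick_primary(pieces: list[_Piece]) -> Optional[_Piece]:
    mapped = [p for p in pieces if p.chrom is not None]
    if not mapped:
        return None
    return max(mapped, key=lambda p: (p.mapq > 0, p.length))


def _cigar_and_sa(read: _SimRead) -> tuple[str, int, list[str], str, int, int]:
    """Primary CIGAR/pos plus SA tag strings (standard SAM convention)."""
    p = read.primary
    stored_forward = p.strand == "+"  # stored seq orientation vs molecule
    L = len(read.seq_forward)

    def cigar_for(piece: _Piece) -> str:
        pre = piece.q_lo
        post = L - piece.q_hi
        if piece.strand == "-":
            pre, post = post, pre
        parts = []
        if pre:
            parts.append(f"{pre}S")
        parts.append(f"{piece.q_hi - piece.q_lo}M")
        if post:
            parts.append(f"{post}S")
        return "".join(parts)

    # reverse flag: sequenced orientation differs from stored orientation
    flag_reverse = read.sequenced_reverse == stored_forward
    sa_tags = []
    for piece in read.pieces:
        if piece is p or piece.chrom is None or piece.length < SA_MIN_BP:
            continue
        if piece.mapq < 20:
            continue
        # strand letter is relative to the sequenced read
        seq_strand = "-" if (read.sequenced_reverse == (piece.strand == "+")) else "+"
        sa_tags.append(
            f"{piece.chrom},{piece.ref_lo},{seq_strand},{cigar_for(piece)},{piece.mapq},0"
        )
    return cigar_for(p), p.ref_lo, sa_tags, ("-" if flag_reverse else "+"), p.mapq, L


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    subs = rng.choice(BASES, size=len(hits))
    for i, pos in enumerate(hits):
        if subs[i] == arr[pos]:
            subs[i] = BASES[(np.where(BASES == arr[pos])[0][0] + 1) % 4]
        arr[pos] = subs[i]
    return arr.tobytes().decode()


def _simulate_molecule_reads(
    parts: Sequence[Part],
    ref: dict[str, str],
    config: SimConfig,
    coverage: float,
    rng: np.random.Generator,
    name_prefix: str,
    repeats: Sequence[RepeatArray],
) -> list[_SimRead]:
    seq = molecule_seq(parts, ref)
    L = len(seq)
    rl = config.read_length
    if L < 2 * rl + 10:
        return []
    offsets = []
    off = 0
    for p in parts:
        offsets.append(off)
        off += p.length
    n_frag = int(math.ceil(L * coverage / (2.0 * rl)))
    reads: list[_SimRead] = []
    sizes = rng.normal(config.fragment_mean, config.fragment_sd, size=n_frag)
    sizes = np.clip(np.round(sizes), 2 * rl, max(2 * rl, min(L, config.fragment_mean + 5 * config.fragment_sd))).astype(int)
    starts = rng.integers(0, np.maximum(1, L - sizes + 1))
    for i in range(n_frag):
        s, fs = int(starts[i]), int(sizes[i])
        name = f"{name_prefix}{i:07d}"
        r1 = (s, s + rl)
        r2 = (s + fs - rl, s + fs)
        r1_first = bool(rng.integers(0, 2))
        for which, (a, b) in enumerate((r1, r2)):
            fwd = _apply_errors(seq[a:b], config.base_error, rng)
            reads.append(
                _SimRead(
                    name=name,
                    is_read1=(which == 0) == r1_first,
                    seq_forward=fwd,
                    sequenced_reverse=(which == 1),
                    pieces=_project(parts, offsets, a, b, repeats, rng),
                )
            )
    return reads


def _emit_sam(
    reads: list[_SimRead],
    ref: dict[str, str],
    path: Path,
    sample: str,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.items()],
        "RG": [{"ID": sample, "SM": sample}],
    }
    tid = {c: i for i, c in enumerate(ref)}
    by_name: dict[tuple[str, bool], _SimRead] = {}
    for r in reads:
        r.primary = _pick_primary(r.pieces)
        by_name[(r.name, r.is_read1)] = r
    records = []
    for r in reads:
        if r.primary is None:
            continue
        cigar, pos, sa_tags, strand, mapq, L = _cigar_and_sa(r)
        a = pysam.AlignedSegment()
        a.query_name = r.name
        stored = r.seq_forward if r.primary.strand == "+" else revcomp(r.seq_forward)
        a.query_sequence = stored
        a.query_qualities = pysam.qualitystring_to_array("I" * L)
        a.cigarstring = cigar
        a.reference_id = tid[r.primary.chrom]
        a.reference_start = pos - 1
        a.mapping_quality = mapq
        flag = 1  # paired
        if strand == "-":
            flag |= 16
        if r.is_read1:
            flag |= 64
        else:
            flag |= 128
        mate = by_name.get((r.name, not r.is_read1))
        mp = mate.primary if mate else None
        if mp is None:
            flag |= 8
            a.next_reference_id = tid[r.primary.chrom]
            a.next_reference_start = pos - 1
        else:
            _, m_pos, _, m_strand, m_mapq, _ = _cigar_and_sa(mate)
            a.next_reference_id = tid[mp.chrom]
            a.next_reference_start = m_pos - 1
            if m_strand == "-":
                flag |= 32
            a.set_tag("MQ", m_mapq)
            a.set_tag("MC", f"{mp.q_hi - mp.q_lo}M")
            if mp.chrom == r.primary.chrom:
                left = min(pos, m_pos)
                right = max(pos + (r.primary.length) - 1, m_pos + mp.length - 1)
                tlen = right - left + 1
                a.template_length = tlen if pos <= m_pos else -tlen
        a.flag = flag | (a.flag & ~0)
        if sa_tags:
            a.set_tag("SA", ";".join(t + ";" for t in sa_tags).replace(";;", ";"))
        a.set_tag("RG", sample)
        records.append(a)
    records.sort(key=lambda x: (x.reference_id, x.reference_start, x.query_name))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in records:
            out.write(a)


def write_fasta(ref: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


@dataclass
class SimResult:
    reference: Path
    normal_sam: Path
    tumour_sam: Path
    truth_tsv: Path
    truth: list[TruthSV]
    ref: dict[str, str]


def simulate(config: SimConfig, out_dir: Union[str, Path]) -> SimResult:
    """Generate reference FASTA, tumour and normal SAMs, and a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref = random_genome(config, rng)
    somatic_parts, somatic_truth = build_derivatives(config, ref, rng, germline=False)
    germline_parts, germline_truth = build_derivatives(config, ref, rng, germline=True)
    has_germline = any(s.germline for s in config.svs)

    ref_molecules = [[Segment(c, 1, len(s))] for c, s in ref.items()]
    normal_haps = germline_parts if has_germline else ref_molecules

    # normal: two haplotypes -> half coverage each (reference + germline hap)
    normal_reads: list[_SimRead] = []
    for i, mol in enumerate(ref_molecules):
        normal_reads += _simulate_molecule_reads(
            mol, ref, config, config.coverage_normal / 2.0, rng, f"n_r{i}_", config.repeats
        )
    for i, mol in enumerate(normal_haps):
        normal_reads += _simulate_molecule_reads(
            mol, ref, config, config.coverage_normal / 2.0, rng, f"n_g{i}_", config.repeats
        )
    # tumour: somatic derivative carries any germline SVs' chromosome too;
    # tumour cells = ref hap + derivative hap, diluted by purity
    pi = config.purity
    cov_t = config.coverage_tumour
    tumour_reads: list[_SimRead] = []
    for i, mol in enumerate(ref_molecules):
        tumour_reads += _simulate_molecule_reads(
            mol, ref, config, cov_t * (1 - pi / 2.0), rng, f"t_r{i}_", config.repeats
        )
    tumour_hap = somatic_parts + (germline_parts if has_germline else [])
    for i, mol in enumerate(somatic_parts):
        tumour_reads += _simulate_molecule_reads(
            mol, ref, config, cov_t * pi / 2.0, rng, f"t_d{i}_", config.repeats
        )
    if has_germline:
        for i, mol in enumerate(germline_parts):
            tumour_reads += _simulate_molecule_reads(
                mol, ref, config, cov_t * pi / 2.0, rng, f"t_g{i}_", config.repeats
            )

    fasta = out / "ref.fa"
    write_fasta(ref, fasta)
    normal_sam = out / "normal.sam"
    tumour_sam = out / "tumour.sam"
    _emit_sam(normal_reads, ref, normal_sam, "normal")
    _emit_sam(tumour_reads, ref, tumour_sam, "tumour")
    truth = somatic_truth
    truth_tsv = out / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for t in truth:
            fh.write(t.row() + "\n")
    return SimResult(fasta, normal_sam, tumour_sam, truth_tsv, truth, ref)


def downsample_mix(
    tumour_sam: Union[str, Path],
    normal_sam: Union[str, Path],
    purity: float,
    seed: int,
    out_path: Union[str, Path],
) -> Path:
    """In-silico purity downsampling: keep each tumour fragment with
    probability ``purity``, replacing dropped fragments with unused
    normal-haplotype fragments."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(tumour_sam), "r") as fh:
        header = fh.header.to_dict()
        t_records = list(fh)
    with pysam.AlignmentFile(str(normal_sam), "r") as fh:
        n_records = list(fh)
    t_names = sorted({r.query_name for r in t_records})
    keep = {name for name in t_names if rng.random() < purity}
    n_dropped = len(t_names) - len(keep)
    n_names = sorted({r.query_name for r in n_records})
    backfill = set(
        rng.choice(n_names, size=min(n_dropped, len(n_names)), replace=False).tolist()
    )
    records = [r for r in t_records if r.query_name in keep]
    for r in n_records:
        if r.query_name in backfill:
            r.query_name = "mix_" + r.query_name
            records.append(r)
    records.sort(key=lambda x: (x.reference_id, x.reference_start, x.query_name))
    out_path = Path(out_path)
    with pysam.AlignmentFile(str(out_path), "w", header=header) as out:
        for r in records:
            out.write(r)
    return out_path


# --------------------------------------------------------------------------
# truth matching


@dataclass
class MatchResult:
    per_truth: list[TruthClass]
    tp_calls: list[str]
    fp_calls: list[str]
    ignored_calls: list[str]

    @property
    def sensitivity(self) -> float:
        n = len(self.per_truth)
        hit = sum(
            1 for c in self.per_truth
            if c in (TruthClass.MATCH_BREAKPOINT, TruthClass.MATCH_BREAKEND)
        )
        return hit / n if n else float("nan")

    @property
    def precision(self) -> float:
        denom = len(self.tp_calls) + len(self.fp_calls)
        return len(self.tp_calls) / denom if denom else float("nan")


def _be_match(b: Breakend, t: Breakend, margin: int) -> bool:
    return b.chrom == t.chrom and b.dir is t.dir and abs(b.pos - t.pos) <= margin


def _bp_matches_truth(
    call: BreakpointCall, t: TruthSV, margin: int, dup_ins_margin: int
) -> bool:
    if t.b2 is None:
        return False
    direct = (_be_match(call.b1, t.b1, margin) and _be_match(call.b2, t.b2, margin)) or (
        _be_match(call.b1, t.b2, margin) and _be_match(call.b2, t.b1, margin)
    )
    if direct:
        if {t.type, call.svtype} == {"DUP", "INS"} or (
            t.type == "INS" and call.svtype == "DUP"
        ) or (t.type == "DUP" and call.svtype == "INS"):
            size_call = call.event_size or len(call.insert_seq)
            if abs(size_call - t.size) > dup_ins_margin:
                return False
        return True
    # tandem-duplication vs insertion representation at the same locus
    if t.type in ("DUP", "INS") and call.svtype in ("DUP", "INS", "DEL"):
        size_call = call.event_size if call.event_size is not None else 0
        if call.insert_seq:
            size_call = max(size_call, len(call.insert_seq))
        near = _be_match(call.b1, t.b1, margin) or _be_match(call.b2, t.b2, margin)
        if near and abs(size_call - t.size) <= dup_ins_margin:
            return True
    return False


def match_calls(
    calls: Sequence[Union[BreakpointCall, SingleBreakendCall]],
    truth: Sequence[TruthSV],
    margin: int = 100,
    dup_ins_margin: int = 25,
    min_size: int = 50,
) -> MatchResult:
    """Classify calls against a truth set.

    A 100 bp margin is allowed around junction positions; duplications
    match insertions when sizes agree within 25 bp; of several calls
    matching one truth entry only the highest-QUAL is a TP (the others are
    ignored, not FPs); false positives smaller than ``min_size`` are
    dropped after matching.
    """
    order = sorted(range(len(calls)), key=lambda i: -calls[i].qual)
    per_truth = [TruthClass.FALSE_NEGATIVE] * len(truth)
    truth_taken: dict[int, str] = {}
    tp, fp, ignored = [], [], []
    for idx in order:
        call = calls[idx]
        best_ti = None
        best_cls = None
        for ti, t in enumerate(truth):
            if isinstance(call, BreakpointCall):
                if _bp_matches_truth(call, t, margin, dup_ins_margin):
                    cls = TruthClass.MATCH_BREAKPOINT
                elif t.b2 is not None and (
                    _be_match(call.b1, t.b1, margin)
                    or _be_match(call.b2, t.b2, margin)
                    or _be_match(call.b1, t.b2, margin)
                    or _be_match(call.b2, t.b1, margin)
                ):
                    cls = TruthClass.ONE_SIDE_CORRECT
                else:
                    continue
            else:
                if _be_match(call.be, t.b1, margin) or (
                    t.b2 is not None and _be_match(call.be, t.b2, margin)
                ):
                    cls = TruthClass.MATCH_BREAKEND
                else:
                    continue
            if best_cls is None or _cls_rank(cls) < _cls_rank(best_cls):
                best_ti, best_cls = ti, cls
        if best_ti is None:
            if (
                isinstance(call, BreakpointCall)
                and call.is_intrachromosomal
                and call.event_size is not None
                and call.event_size < min_size
            ):
                ignored.append(call.id)  # sub-threshold FP dropped post-matching
            else:
                fp.append(call.id)
            continue
        if best_ti in truth_taken:
            ignored.append(call.id)
            continue
        truth_taken[best_ti] = call.id
        if _cls_rank(best_cls) < _cls_rank(per_truth[best_ti]):
            per_truth[best_ti] = best_cls
        if best_cls in (TruthClass.MATCH_BREAKPOINT, TruthClass.MATCH_BREAKEND):
            tp.append(call.id)
        else:
            fp.append(call.id)  # one side correct: still a mis-localised call
    return MatchResult(per_truth, tp, fp, ignored)


def _cls_rank(cls: TruthClass) -> int:
    return {
        TruthClass.MATCH_BREAKPOINT: 0,
        TruthClass.MATCH_BREAKEND: 1,
        TruthClass.ONE_SIDE_CORRECT: 2,
        TruthClass.FALSE_NEGATIVE: 3,
    }[cls]
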