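"""Core domain types shared across the toolkit.

Coordinate convention: 1-based inclusive positions throughout (SAM/VCF
style); all intervals are closed ``[lo, hi]``.

Breakend direction encoding:

* ``HEAD`` -- the anchored (reference-supporting) bases lie at coordinates
  less than or equal to the breakend position; novel sequence continues to
  the *right* of the breakend on the derivative chromosome.  Corresponds to
  the ``+`` orientation / ``t[p[`` style VCF alleles.
* ``TAIL`` -- anchored bases lie at coordinates greater than or equal to
  the breakend; novel sequence continues to the *left*.  Corresponds to the
  ``-`` orientation / ``]p]t`` style alleles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Direction(enum.Enum):
    HEAD = "+"
    TAIL = "-"

    def flipped(self) -> "Direction":
        return Direction.TAIL if self is Direction.HEAD else Direction.HEAD

    def __repr__(self) -> str:  # compact in test output
        return self.name


HEAD = Direction.HEAD
TAIL = Direction.TAIL


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a junction: a locus plus the direction in which the
    anchored sequence extends."""

    chrom: str
    pos: int
    dir: Direction = field(compare=False)

    def shifted(self, delta: int) -> "Breakend":
        return replace(self, pos=self.pos + delta)


@dataclass(frozen=True)
class BreakendInterval:
    """A breakend whose exact position is only known to lie in [lo, hi]."""

    chrom: str
    lo: int
    hi: int
    dir: Direction

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"empty breakend interval [{self.lo},{self.hi}]")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def overlaps(self, other: "BreakendInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.dir is other.dir
            and self.lo <= other.hi
            and other.lo <= self.hi
        )

    def intersect(self, other: "BreakendInterval") -> "BreakendInterval":
        return BreakendInterval(
            self.chrom, max(self.lo, other.lo), min(self.hi, other.hi), self.dir
        )

    def contains(self, pos: int) -> bool:
        return self.lo <= pos <= self.hi


class EvidenceKind(enum.Enum):
    SPLIT_READ = "SR"
    SOFT_CLIP = "SC"
    INDEL = "INDEL"
    DISCORDANT_PAIR = "DP"
    UNMAPPED_MATE = "UM"


@dataclass
class EvidenceItem:
    """A single read / read pair's contribution to a putative breakend.

    The clique-calling atom.  ``local`` is always present; ``remote`` only
    for evidence kinds that place both sides (split reads, indels,
    discordant pairs).
    """

    fragment_id: str
    sample: str
    kind: EvidenceKind
    local: BreakendInterval
    remote: Optional[BreakendInterval] = None
    seq: str = ""  # clipped / mate / inserted sequence, breakend-ordered
    anchor_seq: str = ""  # reference-supporting bases adjacent to the junction
    quality: float = 0.0
    local_mapq: int = 0
    remote_mapq: Optional[int] = None
    read_names: tuple[str, ...] = ()
    read_strand: str = "+"  # sequenced strand of the anchoring read (for SB)
    # span of the anchoring alignment on the reference (for DP interval width
    # and SC anchoring-cigar computation)
    anchor_lo: int = 0
    anchor_hi: int = 0

    def __post_init__(self) -> None:
        both_sided = self.kind in (
            EvidenceKind.SPLIT_READ,
            EvidenceKind.INDEL,
            EvidenceKind.DISCORDANT_PAIR,
        )
        if both_sided and self.remote is None:
            raise ValueError(f"{self.kind} evidence requires a remote breakend")
        if self.kind in (EvidenceKind.SOFT_CLIP, EvidenceKind.UNMAPPED_MATE):
            if self.remote is not None:
                raise ValueError(f"{self.kind} evidence must not have a remote breakend")


@dataclass
class AssemblyContig:
    """Breakend consensus: anchoring reference bases plus novel sequence.

    ``sequence`` is anchor+breakend in HEAD orientation (anchor first) and
    breakend+anchor for TAIL.  ``support`` maps fragment id -> closed
    interval of contig bases (1-based) that fragment contributed to.
    """

    id: str
    chrom: str
    pos: int  # junction position on the reference (last anchored base)
    dir: Direction
    anchor_seq: str
    breakend_seq: str
    support: dict[str, tuple[int, int]] = field(default_factory=dict)
    fragment_samples: dict[str, str] = field(default_factory=dict)
    fragment_kinds: dict[str, EvidenceKind] = field(default_factory=dict)
    truncated: bool = False

    @property
    def sequence(self) -> str:
        if self.dir is HEAD:
            return self.anchor_seq + self.breakend_seq
        return self.breakend_seq + self.anchor_seq

    @property
    def junction_base(self) -> int:
        """Contig base index (1-based) of the last anchored base."""
        if self.dir is HEAD:
            return len(self.anchor_seq)
        return len(self.breakend_seq) + 1


@dataclass
class AlignmentHit:
    query_lo: int  # 1-based closed interval on the query
    query_hi: int
    chrom: str
    ref_lo: int
    ref_hi: int
    strand: str  # '+' or '-'
    score: float
    mapq: int

    @property
    def query_len(self) -> int:
        return self.query_hi - self.query_lo + 1


@dataclass
class SplitAlignmentChain:
    """Compound realignment of a contig: ordered hits over disjoint query
    intervals, with unaligned inter-hit gaps recorded as insert sequence."""

    contig_id: str
    query: str
    hits: list[AlignmentHit]
    # unaligned terminal segments (query intervals), e.g. an ambiguous
    # breakend sequence
    unaligned: list[tuple[int, int]] = field(default_factory=list)

    def gap_seq(self, i: int) -> str:
        """Insert sequence between hit i and hit i+1."""
        a, b = self.hits[i], self.hits[i + 1]
        return self.query[a.query_hi : b.query_lo - 1]


@dataclass
class SupportBreakdown:
    """Per-sample evidence ledger for one call (VCF FORMAT fields)."""

    AS_: int = 0
    RAS: int = 0
    CAS: int = 0
    ASSR: int = 0
    ASRP: int = 0
    SR: int = 0
    RP: int = 0
    IC: int = 0
    BA: int = 0
    BASSR: int = 0
    BASRP: int = 0
    BSC: int = 0
    BUM: int = 0
    ASQ: float = 0.0
    RASQ: float = 0.0
    CASQ: float = 0.0
    SRQ: float = 0.0
    RPQ: float = 0.0
    IQ: float = 0.0
    BAQ: float = 0.0
    BSCQ: float = 0.0
    BUMQ: float = 0.0
    BANRP: int = 0
    BANSR: int = 0
    BANRPQ: float = 0.0
    BANSRQ: float = 0.0
    REF: int = 0
    REFPAIR: int = 0
    RF: int = 0
    VF: int = 0
    BVF: int = 0

    @property
    def qual(self) -> float:
        """Breakpoint-supporting quality (QUAL contribution)."""
        return self.ASQ + self.RASQ + self.CASQ + self.SRQ + self.RPQ + self.IQ

    @property
    def bqual(self) -> float:
        """Breakend-supporting quality (BQ contribution)."""
        return self.BAQ + self.BSCQ + self.BUMQ


_FLOAT_FIELDS = {
    "ASQ", "RASQ", "CASQ", "SRQ", "RPQ", "IQ", "BAQ", "BSCQ", "BUMQ",
    "BANRPQ", "BANSRQ",
}


def breakdown_fields() -> list[str]:
    """Ledger field names in canonical order (VCF spelling, AS not AS_)."""
    out = []
    for f in SupportBreakdown.__dataclass_fields__:
        out.append("AS" if f == "AS_" else f)
    return out


def breakdown_is_float(name: str) -> bool:
    return name in _FLOAT_FIELDS


@dataclass
class CallBase:
    id: str
    qual: float = 0.0
    breakdowns: dict[str, SupportBreakdown] = field(default_factory=dict)
    filters: list[str] = field(default_factory=list)
    event: str = ""
    beids: list[str] = field(default_factory=list)
    sb: Optional[float] = None
    cq: Optional[float] = None
    mq: Optional[float] = None
    mqn: Optional[int] = None
    mqx: Optional[int] = None

    def breakdown(self, sample: str) -> SupportBreakdown:
        return self.breakdowns.setdefault(sample, SupportBreakdown())

    @property
    def total(self) -> SupportBreakdown:
        tot = SupportBreakdown()
        for bd in self.breakdowns.values():
            for f in SupportBreakdown.__dataclass_fields__:
                setattr(tot, f, getattr(tot, f) + getattr(bd, f))
        return tot


@dataclass
class BreakpointCall(CallBase):
    """A novel adjacency joining two reference loci."""

    b1: Breakend = None  # type: ignore[assignment]
    b2: Breakend = None  # type: ignore[assignment]
    insert_seq: str = ""
    precise: bool = True
    # offsets relative to (b1.pos, b2.pos); closed intervals
    cipos: tuple[int, int] = (0, 0)
    cirpos: tuple[int, int] = (0, 0)
    ihompos: tuple[int, int] = (0, 0)
    homlen: int = 0
    homseq: str = ""
    sc: str = ""

    @property
    def imprecise(self) -> bool:
        return not self.precise

    @property
    def is_intrachromosomal(self) -> bool:
        return self.b1.chrom == self.b2.chrom

    @property
    def svtype(self) -> str:
        """Local shape classification: DEL / DUP / INV / BND."""
        if not self.is_intrachromosomal:
            return "BND"
        lo, hi = sorted((self.b1, self.b2), key=lambda b: b.pos)
        if lo.dir is hi.dir:
            return "INV"
        if lo.dir is HEAD:  # HEAD low, TAIL high: deletion-like
            return "DEL"
        return "DUP"

    @property
    def event_size(self) -> Optional[int]:
        """Affected bases: deleted/duplicated span or inserted length
        (whichever is larger), inverted span for INV; None for
        interchromosomal junctions."""
        if not self.is_intrachromosomal:
            return None
        span = abs(self.b2.pos - self.b1.pos)
        t = self.svtype
        if t == "DEL":
            return max(span - 1, len(self.insert_seq))
        if t == "DUP":
            return max(span + 1, len(self.insert_seq))
        return span

    @property
    def inversion_like(self) -> bool:
        return self.is_intrachromosomal and self.b1.dir is self.b2.dir


@dataclass
class SingleBreakendCall(CallBase):
    """A variant with only one uniquely placeable side; the assembled
    breakend sequence extends into ambiguous or absent sequence."""

    be: Breakend = None  # type: ignore[assignment]
    breakend_seq: str = ""
    precise: bool = True
    cipos: tuple[int, int] = (0, 0)
    bealn: list[str] = field(default_factory=list)

    @property
    def imprecise(self) -> bool:
        return not self.precise


class LinkKind(enum.Enum):
    ASSEMBLY_CIS = "asm_cis"
    ASSEMBLY_TRANS = "asm_trans"
    TRANSITIVE = "transitive"
    SC_TRANS = "sc_trans"
    EQUIVALENT = "eq"


@dataclass(frozen=True)
class PhaseLink:
    kind: LinkKind
    members: tuple[str, str]  # call ids, ordered
    link_id: str
    provenance: str = ""


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
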