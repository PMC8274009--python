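"""Copy-number / SV cross-validation.

Every copy-number transition should be explained by an SV breakend, so the
fraction of unexplained transitions estimates the caller's false negative
rate (FNR).  Conversely, isolated SVs should produce a copy-number change
matching the variant copy number inferred from their allele fraction; calls
with essentially no copy-number change but substantial inferred copy
number are likely false positives, giving an FDR estimate.

Also houses the BLAT-style scoring used to assign centromeric single
breakends to their most likely centromere::

    score = (1000 - ((9 - floor(Qsize/100))*mismatch + Qcount + Tcount))
            * min(match/Qsize, 1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .model import Breakend, BreakpointCall, CallBase, SingleBreakendCall

DEFAULT_EXCLUSION_MARGIN = 100_000
DEFAULT_ISOLATION_BP = 3000
CN_CHANGE_MIN = 0.1
VAF_CN_MIN = 0.25
CENTROMERE_MIN_SCORE = 900
CENTROMERE_MARGIN = 25


@dataclass(frozen=True)
class CNSegment:
    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")


@dataclass(frozen=True)
class CNTransition:
    chrom: str
    pos: int  # boundary between adjacent segments
    delta: float
    cn_left: float
    cn_right: float


def read_segments_tsv(path: Union[str, Path]) -> list[CNSegment]:
    """chrom<TAB>start<TAB>end<TAB>copyNumber, with optional header."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or f[0].startswith("#") or f[0] == "chrom":
                continue
            out.append(CNSegment(f[0], int(f[1]), int(f[2]), float(f[3])))
    return out


def transitions_from_segments(segments: Sequence[CNSegment]) -> list[CNTransition]:
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    out = []
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping segments on {chrom}")
            delta = b.copy_number - a.copy_number
            if abs(delta) > 0:
                out.append(CNTransition(chrom, b.start, delta, a.copy_number, b.copy_number))
    return out


@dataclass
class TransitionBreakdown:
    breakpoint_explained: int
    breakend_explained: int
    unexplained: int
    excluded: int

    @property
    def total_assessed(self) -> int:
        return self.breakpoint_explained + self.breakend_explained + self.unexplained

    @property
    def fnr(self) -> float:
        n = self.total_assessed
        return self.unexplained / n if n else float("nan")


def _call_positions(calls: Sequence[CallBase]) -> tuple[list[Breakend], list[Breakend]]:
    bp, be = [], []
    for c in calls:
        if isinstance(c, BreakpointCall):
            bp += [c.b1, c.b2]
        elif isinstance(c, SingleBreakendCall):
            be.append(c.be)
    return bp, be


def match_transitions(
    transitions: Sequence[CNTransition],
    calls: Sequence[CallBase],
    margin: int = 0,
    exclusions: Sequence[tuple[str, int, int]] = (),
    exclusion_margin: int = DEFAULT_EXCLUSION_MARGIN,
) -> TransitionBreakdown:
    """Assign each transition to breakpoint-explained / breakend-explained
    / unexplained (breakpoint takes precedence); transitions in or within
    ``exclusion_margin`` of an excluded region (centromeres, reference
    gaps) are removed from the denominator."""
    bp_pos, be_pos = _call_positions(calls)
    n_bp = n_be = n_un = n_ex = 0
    for t in transitions:
        if any(
            t.chrom == chrom and lo - exclusion_margin <= t.pos <= hi + exclusion_margin
            for chrom, lo, hi in exclusions
        ):
            n_ex += 1
            continue
        if any(b.chrom == t.chrom and abs(b.pos - t.pos) <= margin for b in bp_pos):
            n_bp += 1
        elif any(b.chrom == t.chrom and abs(b.pos - t.pos) <= margin for b in be_pos):
            n_be += 1
        else:
            n_un += 1
    return TransitionBreakdown(n_bp, n_be, n_un, n_ex)


@dataclass
class VafConsistency:
    call_id: str
    observed_change: float
    inferred_cn: float
    inconsistent: bool


def vaf_consistency_fdr(
    calls: Sequence[CallBase],
    segments: Sequence[CNSegment],
    purity: float,
    vafs: dict[str, float],
    isolation: int = DEFAULT_ISOLATION_BP,
) -> tuple[list[VafConsistency], float]:
    """Per-call VAF/copy-number consistency and the FDR estimate.

    Only isolated calls (no other call breakend within ``isolation`` bp)
    are assessed.  The VAF-inferred variant copy number is
    ``VAF * flanking total copy number / purity``; a call is flagged
    inconsistent when the observed copy-number change is below 0.1 while
    the inferred copy number is at least 0.25.
    """
    positions: list[Breakend] = []
    for c in calls:
        bp, be = _call_positions([c])
        positions += bp + be
    assessed: list[VafConsistency] = []
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for s_list in by_chrom.values():
        s_list.sort(key=lambda s: s.start)
    for c in calls:
        anchors, singles = _call_positions([c])
        anchor = (anchors + singles)[0]
        others = [
            p for p in positions
            if p.chrom == anchor.chrom and p is not anchor and 0 < abs(p.pos - anchor.pos) <= isolation
        ]
        if others:
            continue
        segs = by_chrom.get(anchor.chrom, [])
        left = right = None
        for s in segs:
            if s.start <= anchor.pos - 2 <= s.end:
                left = s
            if s.start <= anchor.pos + 2 <= s.end:
                right = s
        if left is None or right is None:
            continue
        observed = abs(right.copy_number - left.copy_number)
        total_cn = (left.copy_number + right.copy_number) / 2.0
        inferred = vafs.get(c.id, 0.0) * total_cn / purity
        assessed.append(
            VafConsistency(
                c.id, observed, inferred,
                inconsistent=(observed < CN_CHANGE_MIN and inferred >= VAF_CN_MIN),
            )
        )
    n = len(assessed)
    fdr = sum(1 for a in assessed if a.inconsistent) / n if n else float("nan")
    return assessed, fdr


@dataclass(frozen=True)
class BlatScoreInput:
    Qsize: int
    match: int
    mismatch: int
    Qcount: int
    Tcount: int

    def __post_init__(self) -> None:
        if self.match + self.mismatch > self.Qsize:
            raise ValueError("match + mismatch cannot exceed Qsize")
        if min(self.Qsize, self.match, self.mismatch, self.Qcount, self.Tcount) < 0:
            raise ValueError("counts must be non-negative")


def blat_like_score(inp: BlatScoreInput) -> float:
    """The BLAT-style alignment score used for centromere assignment."""
    penalty = (9 - math.floor(inp.Qsize / 100)) * inp.mismatch + inp.Qcount + inp.Tcount
    return (1000.0 - penalty) * min(inp.match / inp.Qsize, 1.0)


def assign_centromere(
    alignments: Sequence[tuple[str, BlatScoreInput]],
    min_score: float = CENTROMERE_MIN_SCORE,
    margin: float = CENTROMERE_MARGIN,
) -> Optional[str]:
    """Most likely centromeric partner chromosome, or None.

    The winning chromosome's best score must reach ``min_score`` and beat
    the best score on any other chromosome by at least ``margin``."""
    if not alignments:
        raise ValueError("at least one candidate alignment required")
    best_by_chrom: dict[str, float] = {}
    for chrom, inp in alignments:
        s = blat_like_score(inp)
        if s > best_by_chrom.get(chrom, -math.inf):
            best_by_chrom[chrom] = s
    ranked = sorted(best_by_chrom.items(), key=lambda kv: -kv[1])
    best_chrom, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else -math.inf
    if best >= min_score and best - second >= margin:
        return best_chrom
    return None
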