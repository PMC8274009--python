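"""Somatic classification of raw calls: hard filters, the enumerated
low-confidence rules, panel-of-normals filtering, simple-event
annotations, and the quality filter with phase-link rescue.

All thresholds follow the published defaults: 3% normal support, 1000 bp
short del/dup window, 8 normal fragments, 0.5% tumour allele fraction,
16 bp poly-C/G, 0.95 strand bias, 50 bp homology, 6 bp inexact homology,
2 bp PON match margin, PON QUAL floors 75/428, and quality floors 350
(breakpoints) / 1000 (single breakends).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .model import (
    HEAD,
    TAIL,
    Breakend,
    BreakpointCall,
    CallBase,
    LinkKind,
    PhaseLink,
    SingleBreakendCall,
    revcomp,
)

NORMAL_SUPPORT_FRACTION = 0.03
SHORT_EVENT_BP = 1000
MIN_NORMAL_COVERAGE = 8
MIN_TUMOUR_AF = 0.005
POLY_GC_RUN = 16
STRAND_BIAS_MAX = 0.95
MAX_HOMLEN = 50
MAX_IHOM = 50
DEL_IHOM_MIN = 6
DEL_IHOM_RANGE = (100, 800)
INV_HOM_MAX_SIZE = 40
INV_HOM_MIN = 6
PSEUDO_DEL_SLACK = 5
PON_MARGIN = 2
PON_QUAL_BP = 75
PON_QUAL_BE = 428
QUAL_FLOOR_BP = 350
QUAL_FLOOR_BE = 1000
EVENT_MARGIN = 35
EVENT_SUPPORT_RATIO = 3.0
EQUIV_MARGIN = 5
EQUIV_EDIT_RATE = 0.1
EQUIV_MIN_SEQ = 20


class Status(enum.Enum):
    HARD_FILTERED = "hard"
    LOW_CONFIDENCE = "low"
    PASS = "pass"


@dataclass
class FilterResult:
    status: Status
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status is not Status.PASS and not self.reasons:
            raise ValueError("non-PASS result requires reasons")


Call = Union[BreakpointCall, SingleBreakendCall]


def _is_short_deldup(call: CallBase) -> bool:
    return (
        isinstance(call, BreakpointCall)
        and call.svtype in ("DEL", "DUP")
        and call.is_intrachromosomal
        and abs(call.b2.pos - call.b1.pos) < SHORT_EVENT_BP
    )


def supporting_fragments(call: CallBase, sample: str) -> int:
    bd = call.breakdowns.get(sample)
    if bd is None:
        return 0
    return bd.VF if isinstance(call, BreakpointCall) else bd.BVF


def vaf(call: CallBase, sample: str) -> float:
    """Variant allele fraction: VF / (VF + REF + REFPAIR) for breakpoints,
    BVF / (BVF + REF) for single breakends."""
    bd = call.breakdowns.get(sample)
    if bd is None:
        return 0.0
    if isinstance(call, BreakpointCall):
        denom = bd.VF + bd.REF + bd.REFPAIR
        return bd.VF / denom if denom else 0.0
    denom = bd.BVF + bd.REF
    return bd.BVF / denom if denom else 0.0


def normal_coverage(call: CallBase, normal: str) -> int:
    bd = call.breakdowns.get(normal)
    if bd is None:
        return 0
    if isinstance(call, BreakpointCall):
        return bd.VF + bd.REF + bd.REFPAIR
    return bd.BVF + bd.REF


def hard_filter(call: Call, tumour: str, normal: str) -> Optional[FilterResult]:
    """Normal-support hard filters; None when the call survives."""
    t = supporting_fragments(call, tumour)
    n = supporting_fragments(call, normal)
    if t + n > 0 and n / (t + n) >= NORMAL_SUPPORT_FRACTION:
        return FilterResult(Status.HARD_FILTERED, ["normalSupport"])
    if _is_short_deldup(call):
        nbd = call.breakdowns.get(normal)
        if nbd is not None and nbd.SR > 0:
            return FilterResult(Status.HARD_FILTERED, ["shortSRNormal"])
    return None


def _poly_gc_run(seq: str, n: int = POLY_GC_RUN) -> bool:
    return "C" * n in seq.upper() or "G" * n in seq.upper()


def _edit_distance(a: str, b: str) -> int:
    try:
        import edlib

        return edlib.align(a, b)["editDistance"]
    except ImportError:  # pragma: no cover
        # Levenshtein DP fallback
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


def classify_confidence(
    call: Call,
    tumour: str,
    normal: str,
    reference: Optional[dict] = None,
) -> list[str]:
    """Triggered low-confidence rule identifiers (empty = none)."""
    reasons: list[str] = []
    tbd = call.breakdowns.get(tumour)
    nbd = call.breakdowns.get(normal)
    if call.imprecise:
        reasons.append("imprecise")
    if normal_coverage(call, normal) < MIN_NORMAL_COVERAGE:
        reasons.append("normalCoverage")
    if vaf(call, tumour) < MIN_TUMOUR_AF:
        reasons.append("lowAF")
    short_dd = _is_short_deldup(call)
    if isinstance(call, SingleBreakendCall):
        if tbd is None or tbd.BASRP == 0:
            reasons.append("noAssemblyRP")
        if _poly_gc_run(call.breakend_seq):
            reasons.append("polyGC")
    else:
        bias = max(call.sb, 1 - call.sb) if call.sb is not None else 0.0
        if short_dd and bias >= STRAND_BIAS_MAX:
            reasons.append("strandBias")
        if call.homlen > MAX_HOMLEN:
            reasons.append("homology")
        ihom_w = call.ihompos[1] - call.ihompos[0]
        if not short_dd and ihom_w > MAX_IHOM:
            reasons.append("inexactHomology")
        if short_dd and (tbd is None or tbd.SR + tbd.ASSR == 0):
            reasons.append("noSR")
        if not short_dd and (tbd is None or tbd.RP + tbd.ASRP == 0):
            reasons.append("noRP")
        if short_dd and nbd is not None and nbd.SR > 0:
            reasons.append("normalSR")
        if (
            call.svtype == "DEL"
            and DEL_IHOM_RANGE[0] <= abs(call.b2.pos - call.b1.pos) - 1 <= DEL_IHOM_RANGE[1]
            and ihom_w >= DEL_IHOM_MIN
        ):
            reasons.append("delIhom")
        if (
            call.inversion_like
            and abs(call.b2.pos - call.b1.pos) <= INV_HOM_MAX_SIZE
            and call.homlen >= INV_HOM_MIN
        ):
            reasons.append("invHom")
        if call.svtype == "DEL" and not call.imprecise:
            del_len = abs(call.b2.pos - call.b1.pos) - 1
            ins_len = len(call.insert_seq)
            if (
                del_len < SHORT_EVENT_BP
                and del_len > 0
                and abs(ins_len - del_len) <= PSEUDO_DEL_SLACK
            ):
                exempt = False
                if reference is not None and ins_len > 0:
                    lo = min(call.b1.pos, call.b2.pos)
                    hi = max(call.b1.pos, call.b2.pos)
                    deleted = reference.get(call.b1.chrom, "")[lo : hi - 1]
                    if deleted:
                        n = min(len(deleted), ins_len)
                        d_fwd = _edit_distance(call.insert_seq, deleted) / n
                        d_rc = _edit_distance(call.insert_seq, revcomp(deleted)) / n
                        exempt = d_fwd >= 0.5 and d_rc < 0.2
                if not exempt:
                    reasons.append("pseudoDeletion")
    return reasons


# --------------------------------------------------------------------------
# panel of normals


@dataclass
class PanelOfNormals:
    breakpoints: dict[tuple, int] = field(default_factory=dict)
    breakends: dict[tuple, int] = field(default_factory=dict)

    def add_call(self, call: Call) -> None:
        if isinstance(call, BreakpointCall):
            key = _bp_key(call.b1, call.b2)
            self.breakpoints[key] = self.breakpoints.get(key, 0) + 1
        else:
            key = (call.be.chrom, call.be.pos, call.be.dir.value)
            self.breakends[key] = self.breakends.get(key, 0) + 1


def _bp_key(b1: Breakend, b2: Breakend) -> tuple:
    a = (b1.chrom, b1.pos, b1.dir.value)
    b = (b2.chrom, b2.pos, b2.dir.value)
    return (a, b) if a <= b else (b, a)


def build_pon(
    normal_call_sets: Sequence[Sequence[Call]],
    qual_bp: float = PON_QUAL_BP,
    qual_be: float = PON_QUAL_BE,
) -> PanelOfNormals:
    """Aggregate normal calls into a PON: imprecise calls excluded, QUAL
    floors 75 (breakpoints) / 428 (single breakends), FILTER ignored.
    Callers should pass only the first sample per patient."""
    pon = PanelOfNormals()
    for callset in normal_call_sets:
        for call in callset:
            if call.imprecise:
                continue
            floor = qual_bp if isinstance(call, BreakpointCall) else qual_be
            if call.qual < floor:
                continue
            pon.add_call(call)
    return pon


def pon_filter(call: Call, pon: PanelOfNormals, margin: int = PON_MARGIN) -> bool:
    """True iff a PON entry of matching type and orientation lies within
    ``margin`` bp (both breakends must match for breakpoints)."""
    if isinstance(call, BreakpointCall):
        for (a, b) in pon.breakpoints:
            for (e1, e2) in ((a, b), (b, a)):
                if (
                    _near(call.b1, e1, margin)
                    and _near(call.b2, e2, margin)
                ):
                    return True
        return False
    for e in pon.breakends:
        if _near(call.be, e, margin):
            return True
    return False


def _near(b: Breakend, entry: tuple, margin: int) -> bool:
    chrom, pos, d = entry
    return b.chrom == chrom and b.dir.value == d and abs(b.pos - pos) <= margin


# --------------------------------------------------------------------------
# simple-event annotation


@dataclass(frozen=True)
class EventAnnotation:
    kind: str  # EQUIVALENT | SIMPLE_INVERSION | TEMPLATED_INSERTION | RECIPROCAL_TRANSLOCATION
    members: tuple[str, str]


def _call_breakends(call: Call) -> list[Breakend]:
    if isinstance(call, BreakpointCall):
        return [call.b1, call.b2]
    return [call.be]


def _breakend_seq_for_equiv(call: Call, reference: Optional[dict]) -> str:
    if isinstance(call, SingleBreakendCall):
        return call.breakend_seq
    if reference is None:
        return ""
    # reference sequence at the partner breakend, read in derivative order
    b2 = call.b2
    seq = reference.get(b2.chrom, "")
    n = EQUIV_MIN_SEQ
    if b2.dir is TAIL:
        return seq[b2.pos - 1 : b2.pos - 1 + n]
    return revcomp(seq[max(0, b2.pos - n) : b2.pos])


def _total_support(call: Call) -> int:
    tot = call.total
    return tot.VF if isinstance(call, BreakpointCall) else tot.BVF


def annotate_events(
    calls: Sequence[Call], reference: Optional[dict] = None
) -> list[EventAnnotation]:
    """Equivalence and simple-event annotations.

    Equivalence is evaluated independently; among the simple-event kinds a
    pair receives at most one annotation, tested in the order reciprocal
    translocation -> templated insertion -> simple inversion.
    """
    out: list[EventAnnotation] = []
    taken: set[tuple[str, str]] = set()
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            pair = (a.id, b.id)
            # --- equivalence ------------------------------------------------
            if _equivalent(a, b, reference):
                out.append(EventAnnotation("EQUIVALENT", pair))
            if pair in taken:
                continue
            ratio_ok = _support_ratio_ok(a, b)
            if not ratio_ok:
                continue
            kind = _simple_event_kind(a, b)
            if kind is not None:
                out.append(EventAnnotation(kind, pair))
                taken.add(pair)
    return out


def _equivalent(a: Call, b: Call, reference) -> bool:
    close = any(
        ba.chrom == bb.chrom and ba.dir is bb.dir and abs(ba.pos - bb.pos) <= EQUIV_MARGIN
        for ba in _call_breakends(a)
        for bb in _call_breakends(b)
    )
    if not close:
        return False
    sa = _breakend_seq_for_equiv(a, reference)
    sb = _breakend_seq_for_equiv(b, reference)
    n = min(len(sa), len(sb))
    if n == 0:
        return False
    return _edit_distance(sa[:n], sb[:n]) / n <= EQUIV_EDIT_RATE


def _support_ratio_ok(a: Call, b: Call) -> bool:
    va, vb = _total_support(a), _total_support(b)
    if va == 0 or vb == 0:
        return False
    return max(va, vb) / min(va, vb) <= EVENT_SUPPORT_RATIO


def _paired_close(a: Call, b: Call, opposite: bool) -> bool:
    """Breakends of a and b pair off within the margin; ``opposite``
    requires opposite orientations at each pairing."""
    bas, bbs = _call_breakends(a), _call_breakends(b)
    if len(bas) != len(bbs):
        return False
    import itertools

    for perm in itertools.permutations(range(len(bbs))):
        ok = True
        for i, j in enumerate(perm):
            ba, bb = bas[i], bbs[j]
            if ba.chrom != bb.chrom or abs(ba.pos - bb.pos) > EVENT_MARGIN:
                ok = False
                break
            if opposite and ba.dir is bb.dir:
                ok = False
                break
            if not opposite and ba.dir is not bb.dir:
                ok = False
                break
        if ok:
            return True
    return False


def _simple_event_kind(a: Call, b: Call) -> Optional[str]:
    a_bp = isinstance(a, BreakpointCall)
    b_bp = isinstance(b, BreakpointCall)
    if a_bp and b_bp:
        interchrom = not a.is_intrachromosomal and not b.is_intrachromosomal
        if interchrom and _paired_close(a, b, opposite=True):
            return "RECIPROCAL_TRANSLOCATION"
    if not (a_bp and b_bp):
        if _paired_close_single(a, b):
            return "TEMPLATED_INSERTION"
    if a_bp and b_bp:
        if (
            a.inversion_like
            and b.inversion_like
            and a.b1.dir is not b.b1.dir
            and _paired_close(a, b, opposite=True)
        ):
            return "SIMPLE_INVERSION"
    return None


def _paired_close_single(a: Call, b: Call) -> bool:
    """Breakend/breakpoint or breakend/breakend adjacency with opposite
    orientations within the margin."""
    for ba in _call_breakends(a):
        for bb in _call_breakends(b):
            if (
                ba.chrom == bb.chrom
                and abs(ba.pos - bb.pos) <= EVENT_MARGIN
                and ba.dir is not bb.dir
            ):
                return True
    return False


# --------------------------------------------------------------------------
# quality filter + rescue, final classification


def quality_filter_with_rescue(
    calls: Sequence[Call],
    links: Sequence[PhaseLink],
    qual_bp: float = QUAL_FLOOR_BP,
    qual_be: float = QUAL_FLOOR_BE,
) -> dict[str, bool]:
    """Quality pass/fail per call id with phase-link rescue.

    Sub-threshold calls linked (by anything other than equivalence) to a
    passing call pass regardless of their own quality; the rescue closure
    is a fixed point over the link graph, so it is order-independent."""
    passing = {
        c.id: c.qual >= (qual_bp if isinstance(c, BreakpointCall) else qual_be)
        for c in calls
    }
    adj: dict[str, set[str]] = {c.id: set() for c in calls}
    for l in links:
        if l.kind is LinkKind.EQUIVALENT:
            continue
        a, b = l.members
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    changed = True
    while changed:
        changed = False
        for cid, nbrs in adj.items():
            if not passing[cid] and any(passing[n] for n in nbrs):
                passing[cid] = True
                changed = True
    return passing


def apply_somatic_filters(
    calls: Sequence[Call],
    tumour: str,
    normal: str,
    links: Sequence[PhaseLink] = (),
    pon: Optional[PanelOfNormals] = None,
    reference: Optional[dict] = None,
) -> dict[str, FilterResult]:
    """Full somatic classification of a call set."""
    results: dict[str, FilterResult] = {}
    survivors: list[Call] = []
    for call in calls:
        hard = hard_filter(call, tumour, normal)
        if hard is not None:
            results[call.id] = hard
            continue
        survivors.append(call)
    reasons_by_id: dict[str, list[str]] = {}
    for call in survivors:
        reasons = classify_confidence(call, tumour, normal, reference)
        if pon is not None and pon_filter(call, pon):
            reasons.append("PON")
        reasons_by_id[call.id] = reasons
    qual_pass = quality_filter_with_rescue(
        [c for c in survivors], links
    )
    for call in survivors:
        reasons = reasons_by_id[call.id]
        if not qual_pass[call.id]:
            reasons.append("lowQual")
        if reasons:
            results[call.id] = FilterResult(Status.LOW_CONFIDENCE, reasons)
        else:
            results[call.id] = FilterResult(Status.PASS)
    return results


def emit_call_sets(
    calls: Sequence[Call], results: dict[str, FilterResult]
) -> tuple[list[Call], list[Call]]:
    """(high-confidence, low-confidence) output sets: high = PASS only;
    low = everything except normal-support hard failures."""
    high = [c for c in calls if results[c.id].status is Status.PASS]
    low = [
        c
        for c in calls
        if results[c.id].status is not Status.HARD_FILTERED
    ]
    return high, low
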