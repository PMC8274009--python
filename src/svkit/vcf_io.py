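"""VCF 4.2 reading and writing with breakpoint (BND bracket notation) and
single-breakend ('.'-allele) records and the full evidence ledger.

Breakpoints are written as reciprocal mate pairs (ids ``<id>o1``/``<id>o2``
with PARID cross-references).  Direction-to-allele mapping:

======== ========= =====================
local    remote    ALT
======== ========= =====================
HEAD     TAIL      ``t[chr:pos[``
HEAD     HEAD      ``t]chr:pos]``
TAIL     HEAD      ``]chr:pos]t``
TAIL     TAIL      ``[chr:pos[t``
HEAD     (none)    ``t.`` (sequence extends right)
TAIL     (none)    ``.t``
======== ========= =====================

Float ledger fields are written (and re-read) rounded to two decimals, so
``read(write(x))`` reproduces ``x`` field for field.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam

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
    SupportBreakdown,
    breakdown_fields,
    breakdown_is_float,
)

Call = Union[BreakpointCall, SingleBreakendCall]

_INFO_DEFS = [
    ("SVTYPE", "1", "String", "Type of structural variant"),
    ("MATEID", ".", "String", "ID of mate breakend"),
    ("PARID", ".", "String", "ID of partner breakend"),
    ("EVENT", "1", "String", "ID of associated event"),
    ("IMPRECISE", "0", "Flag", "Imprecise structural variation"),
    ("CIPOS", "2", "Integer", "Confidence interval around POS"),
    ("CIRPOS", "2", "Integer", "Confidence interval around remote breakend POS"),
    ("IHOMPOS", "2", "Integer", "Interval of inexact homology around the breakend"),
    ("HOMLEN", ".", "Integer", "Length of base pair identical micro-homology"),
    ("HOMSEQ", ".", "String", "Sequence of base pair identical micro-homology"),
    ("SC", "1", "String", "CIGAR of the anchoring supporting interval"),
    ("BEID", ".", "String", "Identifiers of supporting assembly contigs"),
    ("BEIDL", ".", "Integer", "Local contig base offset of the breakend"),
    ("BEIDH", ".", "Integer", "Remote contig base offset of the breakend"),
    ("BEALN", ".", "String", "Candidate alignments of the breakend sequence"),
    ("CQ", "1", "Float", "Quality score prior to evidence reallocation"),
    ("SB", "1", "Float", "Strand bias of supporting reads"),
    ("MQ", "1", "Float", "Mean MAPQ of supporting reads"),
    ("MQN", "1", "Integer", "Min MAPQ of supporting reads"),
    ("MQX", "1", "Integer", "Max MAPQ of supporting reads"),
    ("LINKED_BY", ".", "String", "Phasing / event links involving this variant"),
]


def _header_text(samples: Sequence[str], contigs: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=svkit"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##ALT=<ID=BND,Description="Breakend">')
    for fid, num, typ, desc in _INFO_DEFS:
        lines.append(f'##INFO=<ID={fid},Number={num},Type={typ},Description="{desc}">')
    for f in breakdown_fields():
        typ = "Float" if breakdown_is_float(f) else "Integer"
        lines.append(
            f'##FORMAT=<ID={f},Number=1,Type={typ},Description="Evidence ledger field {f}">'
        )
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols += list(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _fmt_float(x: float) -> str:
    return f"{round(x + 0.0, 2):g}"


def _alt(
    ref_base: str, dir_: Direction, partner: Optional[Breakend], insert: str, be_seq: str
) -> str:
    if partner is None:
        if dir_ is HEAD:
            return f"{ref_base}{be_seq}."
        return f".{be_seq}{ref_base}"
    loc = f"{partner.chrom}:{partner.pos}"
    bracket = f"[{loc}[" if partner.dir is TAIL else f"]{loc}]"
    if dir_ is HEAD:
        return f"{ref_base}{insert}{bracket}"
    return f"{bracket}{insert}{ref_base}"


def _info_str(pairs: list[tuple[str, Optional[str]]]) -> str:
    parts = []
    for k, v in pairs:
        if v is None:
            continue
        parts.append(k if v == "" else f"{k}={v}")
    return ";".join(parts) if parts else "."


def _breakdown_cols(call: CallBase, samples: Sequence[str]) -> list[str]:
    cols = []
    for s in samples:
        bd = call.breakdowns.get(s, SupportBreakdown())
        vals = []
        for f in breakdown_fields():
            v = getattr(bd, "AS_" if f == "AS" else f)
            vals.append(_fmt_float(v) if breakdown_is_float(f) else str(int(v)))
        cols.append(":".join(vals))
    return cols


def write_vcf(
    calls: Sequence[Call],
    path: Union[str, Path],
    samples: Sequence[str],
    contigs: dict[str, int],
    reference: Optional[dict] = None,
    filters: Optional[dict] = None,
    links: Sequence[PhaseLink] = (),
) -> None:
    """Write calls as VCF 4.2; breakpoints emit reciprocal mate records."""
    link_by_call: dict[str, list[str]] = {}
    for l in links:
        for m in l.members:
            link_by_call.setdefault(m, []).append(l.link_id)
    rows = []
    for call in calls:
        filt = "PASS"
        if filters and call.id in filters:
            fr = filters[call.id]
            filt = "PASS" if not fr.reasons else ";".join(fr.reasons)
        fmt = ":".join(breakdown_fields())
        common_info: list[tuple[str, Optional[str]]] = [
            ("SVTYPE", "BND"),
            ("EVENT", call.event or call.id),
            ("IMPRECISE", "" if getattr(call, "precise", True) is False else None),
            ("HOMSEQ", getattr(call, "homseq", "") or None),
            ("HOMLEN", str(call.homlen) if isinstance(call, BreakpointCall) and call.homlen else None),
            ("SC", getattr(call, "sc", "") or None),
            ("BEID", ",".join(call.beids) or None),
            ("CQ", _fmt_float(call.cq) if call.cq is not None else None),
            ("SB", _fmt_float(call.sb) if call.sb is not None else None),
            ("MQ", _fmt_float(call.mq) if call.mq is not None else None),
            ("MQN", str(call.mqn) if call.mqn is not None else None),
            ("MQX", str(call.mqx) if call.mqx is not None else None),
            ("LINKED_BY", ",".join(sorted(set(link_by_call.get(call.id, [])))) or None),
        ]
        qual = _fmt_float(call.qual)
        cols_fmt = _breakdown_cols(call, samples)
        if isinstance(call, BreakpointCall):
            ih = call.ihompos
            for which, (b, partner, ci, cir) in enumerate(
                [
                    (call.b1, call.b2, call.cipos, call.cirpos),
                    (call.b2, call.b1, call.cirpos, call.cipos),
                ]
            ):
                rid = f"{call.id}o{which + 1}"
                parid = f"{call.id}o{2 - which}"
                ref_base = _ref_base(reference, b)
                ins = call.insert_seq if which == 0 else _mate_insert(call)
                info = _info_str(
                    [
                        ("MATEID", parid),
                        ("PARID", parid),
                        ("CIPOS", f"{ci[0]},{ci[1]}"),
                        ("CIRPOS", f"{cir[0]},{cir[1]}"),
                        ("IHOMPOS", f"{ih[0]},{ih[1]}"),
                    ]
                    + common_info
                )
                rows.append(
                    (
                        b.chrom, b.pos, rid, ref_base,
                        _alt(ref_base, b.dir, partner, ins, ""),
                        qual, filt, info, fmt, cols_fmt,
                    )
                )
        else:
            b = call.be
            ref_base = _ref_base(reference, b)
            info = _info_str(
                [
                    ("CIPOS", f"{call.cipos[0]},{call.cipos[1]}"),
                    ("BEALN", ",".join(call.bealn) or None),
                ]
                + common_info
            )
            rows.append(
                (
                    b.chrom, b.pos, call.id, ref_base,
                    _alt(ref_base, b.dir, None, "", call.breakend_seq),
                    qual, filt, info, fmt, cols_fmt,
                )
            )
    order = {c: i for i, c in enumerate(contigs)}
    rows.sort(key=lambda r: (order.get(r[0], 999), r[1], r[2]))
    with open(path, "w") as fh:
        fh.write(_header_text(samples, contigs))
        for r in rows:
            fh.write(
                "\t".join(
                    [r[0], str(r[1]), r[2], r[3], r[4], r[5], r[6], r[7], r[8]]
                    + r[9]
                )
                + "\n"
            )


def _mate_insert(call: BreakpointCall) -> str:
    # the same inserted bases seen from the partner breakend
    from .model import revcomp

    if call.b1.dir is call.b2.dir:
        return revcomp(call.insert_seq)
    return call.insert_seq


def _ref_base(reference: Optional[dict], b: Breakend) -> str:
    if reference is None:
        return "N"
    seq = reference.get(b.chrom)
    if seq is None or not 1 <= b.pos <= len(seq):
        return "N"
    return seq[b.pos - 1]


_BND_RE = re.compile(
    r"^(?P<t1>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<t2>[ACGTNacgtn]*)$"
)
_SINGLE_RE = re.compile(r"^(\.[ACGTNacgtn]+|[ACGTNacgtn]+\.)$")


def parse_breakend_alt(alt: str) -> tuple[Optional[Breakend], Direction, str, str]:
    """Parse a breakend ALT allele.

    Returns (partner breakend or None, local direction, inserted/breakend
    sequence sans the reference base, full matched text kind)."""
    m = _BND_RE.match(alt)
    if m:
        t1, t2 = m.group("t1"), m.group("t2")
        local_dir = HEAD if t1 else TAIL
        remote_dir = TAIL if m.group("b1") == "[" else HEAD
        partner = Breakend(m.group("chrom"), int(m.group("pos")), remote_dir)
        ins = t1[1:] if t1 else t2[:-1]
        return partner, local_dir, ins, "BND"
    if _SINGLE_RE.match(alt):
        if alt.endswith("."):
            return None, HEAD, alt[1:-1], "single"
        return None, TAIL, alt[1:-1], "single"
    raise ValueError(f"unsupported ALT allele: {alt}")


def read_vcf(path: Union[str, Path]) -> tuple[list[Call], list[PhaseLink]]:
    """Read a breakend VCF back into call objects.

    Mates are re-paired via PARID/MATEID; an orphan mate record is kept as
    a single breakend flagged ``orphan`` in its filters.  Cis phase links
    are rebuilt from shared assembly identifiers (BEID)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    records = {}
    for rec in vf:
        records[rec.id] = rec
    calls: list[Call] = []
    done: set[str] = set()
    beid_map: dict[str, list[str]] = {}
    for rid in sorted(records):
        rec = records[rid]
        if rid in done:
            continue
        alt = rec.alts[0]
        partner_be, local_dir, ins, kind = parse_breakend_alt(alt)
        info = rec.info
        parid = _info_get(info, "PARID") or _info_get(info, "MATEID")
        if (
            kind == "BND"
            and parid
            and parid in records
            and parid < rid
            and parid not in done
        ):
            continue  # handled from the lower-id mate
        if kind == "BND" and parid and parid in records:
            mate = records[parid]
            done.add(parid)
            m_partner, m_dir, m_ins, _ = parse_breakend_alt(mate.alts[0])
            call = BreakpointCall(
                id=_strip_mate_suffix(rid),
                b1=Breakend(rec.chrom, rec.pos, local_dir),
                b2=Breakend(mate.chrom, mate.pos, m_dir),
                insert_seq=ins,
                precise="IMPRECISE" not in info,
            )
            call.cipos = _pair(_info_raw(info, "CIPOS"))
            call.cirpos = _pair(_info_raw(info, "CIRPOS"))
            call.ihompos = _pair(_info_raw(info, "IHOMPOS"))
            call.homlen = int(_first(_info_raw(info, "HOMLEN")) or 0)
            call.homseq = str(_first(_info_raw(info, "HOMSEQ")) or "")
            call.sc = str(_info_raw(info, "SC") or "")
        else:
            call = SingleBreakendCall(
                id=rid if kind != "BND" else _strip_mate_suffix(rid),
                be=Breakend(rec.chrom, rec.pos, local_dir),
                breakend_seq=ins,
                precise="IMPRECISE" not in info,
            )
            call.cipos = _pair(_info_raw(info, "CIPOS"))
            call.bealn = [str(x) for x in _tuple(_info_raw(info, "BEALN"))]
            if kind == "BND":
                call.filters.append("orphan")
        done.add(rid)
        call.qual = round(rec.qual if rec.qual is not None else 0.0, 2)
        call.event = str(_info_raw(info, "EVENT") or "")
        call.beids = [str(x) for x in _tuple(_info_raw(info, "BEID"))]
        for b in call.beids:
            beid_map.setdefault(b, []).append(call.id)
        call.cq = _opt_float(_info_raw(info, "CQ"))
        call.sb = _opt_float(_info_raw(info, "SB"))
        call.mq = _opt_float(_info_raw(info, "MQ"))
        call.mqn = _opt_int(_info_raw(info, "MQN"))
        call.mqx = _opt_int(_info_raw(info, "MQX"))
        if rec.filter.keys() and list(rec.filter.keys()) != ["PASS"]:
            call.filters.extend(k for k in rec.filter.keys())
        for s in samples:
            bd = SupportBreakdown()
            fmt = rec.samples[s]
            for f in breakdown_fields():
                v = fmt.get(f)
                if v is None:
                    continue
                attr = "AS_" if f == "AS" else f
                if breakdown_is_float(f):
                    setattr(bd, attr, round(float(v), 2))
                else:
                    setattr(bd, attr, int(v))
            call.breakdowns[s] = bd
        calls.append(call)
    links: list[PhaseLink] = []
    for beid, members in beid_map.items():
        uniq = sorted(set(members))
        for i in range(len(uniq) - 1):
            links.append(
                PhaseLink(
                    LinkKind.ASSEMBLY_CIS,
                    (uniq[i], uniq[i + 1]),
                    link_id=f"{beid}.cis{i}",
                    provenance=beid,
                )
            )
    return calls, links


def _strip_mate_suffix(rid: str) -> str:
    return re.sub(r"o[12]$", "", rid)


def _info_raw(info, key):
    """INFO access tolerant of fields undeclared in foreign headers."""
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


def _info_get(info, key):
    return _first(_info_raw(info, key))


def _first(v):
    if v is None:
        return None
    if isinstance(v, tuple):
        return v[0] if v else None
    return v


def _tuple(v):
    if v is None:
        return ()
    if isinstance(v, tuple):
        return v
    return (v,)


def _pair(v) -> tuple[int, int]:
    if v is None:
        return (0, 0)
    t = _tuple(v)
    if len(t) == 2:
        return (int(t[0]), int(t[1]))
    return (0, 0)


def _opt_float(v) -> Optional[float]:
    x = _first(v)
    return None if x is None else round(float(x), 2)


def _opt_int(v) -> Optional[int]:
    x = _first(v)
    return None if x is None else int(x)


def export_bedpe(calls: Sequence[Call], path: Union[str, Path]) -> None:
    """Breakpoint calls as BEDPE (0-based half-open per convention)."""
    with open(path, "w") as fh:
        for c in calls:
            if not isinstance(c, BreakpointCall):
                continue
            fh.write(
                "\t".join(
                    [
                        c.b1.chrom, str(c.b1.pos - 1), str(c.b1.pos),
                        c.b2.chrom, str(c.b2.pos - 1), str(c.b2.pos),
                        c.id, _fmt_float(c.qual),
                        c.b1.dir.value, c.b2.dir.value,
                    ]
                )
                + "\n"
            )
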