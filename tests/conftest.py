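"""Shared fixtures: small random references, read-record factories and a
cached mixed-SV simulation used by the integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from svkit.evidence import LibraryMetrics, ReadRecord


def make_metrics(
    lo: int = 300,
    hi: int = 700,
    read_length: int = 150,
    n_reads: int = 100_000,
    clip_rates: dict | None = None,
) -> LibraryMetrics:
    hist = {500: 1.0}
    return LibraryMetrics(
        fragment_size_hist=hist,
        concordant_lo=lo,
        concordant_hi=hi,
        max_fragment=hi,
        cigar_rates=clip_rates or {},
        unmapped_mate_rate=1e-4,
        discordant_rate=1e-3,
        read_length=read_length,
        n_reads=n_reads,
        n_pairs=n_reads // 2,
    )


def make_read(
    name: str = "r1",
    chrom: str = "chr1",
    pos: int = 1000,
    cigar: str = "150M",
    seq: str | None = None,
    mapq: int = 60,
    strand: str = "+",
    **kw,
) -> ReadRecord:
    import re

    ops = tuple((op, int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar))
    if seq is None:
        qlen = sum(n for op, n in ops if op in "MIS=X")
        rng = np.random.default_rng(abs(hash(name)) % (2**31))
        seq = "".join(rng.choice(list("ACGT"), size=qlen))
    kw.setdefault("mate_chrom", chrom)
    kw.setdefault("mate_pos", pos + 350)
    kw.setdefault("mate_strand", "-" if strand == "+" else "+")
    kw.setdefault("tlen", 500)
    return ReadRecord(
        name=name, chrom=chrom, pos=pos, strand=strand, cigar=ops,
        mapq=mapq, seq=seq, **kw,
    )


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def mixed_sim(tmp_path_factory):
    """A 20-junction somatic simulation shared by integration tests:
    DEL/DUP/INV/INS in unique sequence plus a translocation and a foldback,
    60x tumour / 40x normal, purity 1, error-free reads."""
    from svkit.sim_eval import SimConfig, SVSpec, simulate

    svs = []
    pos = 8000
    plan = [
        ("DEL", 500), ("DUP", 300), ("INV", 400), ("INS", 100),
        ("DEL", 80), ("DUP", 60), ("DEL", 1500), ("INS", 90),
        ("INV", 250), ("DEL", 5000), ("DUP", 800), ("DEL", 55),
        ("INS", 70), ("DUP", 120), ("DEL", 2500), ("DUP", 2000),
    ]
    for t, s in plan:
        svs.append(SVSpec(t, "chr1", pos, size=s))
        pos += 9000
    svs.append(SVSpec("TRA", "chr2", 15_000, chrom2="chr3", pos2=20_000))
    svs.append(SVSpec("FOLDBACK", "chr4", 20_000, size=600))
    cfg = SimConfig(
        seed=20260921,
        chrom_lengths={
            "chr1": 9000 * len(plan) + 10_000,
            "chr2": 30_000,
            "chr3": 35_000,
            "chr4": 32_000,
        },
        svs=tuple(svs),
        coverage_tumour=60,
        coverage_normal=40,
        purity=1.0,
    )
    out = tmp_path_factory.mktemp("mixed_sim")
    return simulate(cfg, out)


@pytest.fixture(scope="session")
def mixed_result(mixed_sim):
    from svkit.pipeline import call_somatic

    return call_somatic(mixed_sim.tumour_sam, mixed_sim.normal_sam, mixed_sim.ref)
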