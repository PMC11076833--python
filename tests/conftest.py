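"""Shared fixtures: hand-built BAMs and session-scoped simulated loci."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from svlens.ingest import ReadSegment
from svlens.simulate import SimConfig, simulate_cohort, simulate_locus

QUERY_OPS = set("MIS=X")


def query_len(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in QUERY_OPS:
                total += int(num)
            num = ""
    return total


def write_bam(path: Path, contigs: dict[str, int], records: list[dict]) -> Path:
    """Write a sorted+indexed BAM from plain dict records.

    Record keys: name, chrom, pos, cigar, [flag], [mapq], [seq], [qual],
    [tags] (list of (tag, value, type)).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
    }
    tids = {c: i for i, c in enumerate(contigs)}
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment()
            a.query_name = r["name"]
            a.reference_id = tids[r["chrom"]]
            a.reference_start = r["pos"]
            a.cigarstring = r["cigar"]
            a.mapping_quality = r.get("mapq", 60)
            a.flag = r.get("flag", 0)
            qlen = query_len(r["cigar"])
            a.query_sequence = r.get("seq", "A" * qlen)
            qual = r.get("qual")
            if qual is not None:
                if isinstance(qual, int):
                    qual = [qual] * qlen
                a.query_qualities = qual
            for tag, value, vtype in r.get("tags", []):
                a.set_tag(tag, value, vtype)
            fh.write(a)
    pysam.sort("--no-PG", "-o", str(path), str(tmp))
    tmp.unlink()
    pysam.index(str(path))
    return path


def make_segment(
    read_name: str = "r",
    chrom: str = "chr1",
    ref_start: int = 0,
    ref_end: int = 100,
    query_start: int = 0,
    query_end: int = 100,
    strand: str = "+",
    cigar: list[tuple[int, int]] | None = None,
    **kw,
) -> ReadSegment:
    defaults = dict(mapq=60, mean_baseq=30.0, identity=0.99, is_supplementary=False)
    defaults.update(kw)
    return ReadSegment(
        read_name=read_name, chrom=chrom, ref_start=ref_start, ref_end=ref_end,
        query_start=query_start, query_end=query_end, strand=strand,
        cigar=cigar or [(0, query_end - query_start)], **defaults,
    )


@pytest.fixture(scope="session")
def het_del_locus(tmp_path_factory):
    cfg = SimConfig(seed=11, ref_length=30_000, depth=25, read_length=10_000,
                    sv_specs=[("DEL", 15_000, 900, "0/1")])
    return simulate_locus(cfg, tmp_path_factory.mktemp("het_del"), name="hetdel")


@pytest.fixture(scope="session")
def tra_locus(tmp_path_factory):
    cfg = SimConfig(seed=13, ref_length=30_000, depth=25, read_length=10_000,
                    sv_specs=[("TRA", 15_000, 0, "0/1")])
    return simulate_locus(cfg, tmp_path_factory.mktemp("tra"), name="tra")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Ten loci (two per SV type) at moderate depth for pipeline tests."""
    tpl = SimConfig(seed=17, ref_length=30_000, depth=25, read_length=10_000)
    return simulate_cohort(10, tpl, seed=17,
                           out_dir=tmp_path_factory.mktemp("small_cohort"))


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """The genotype-recovery study conditions: 100 loci (20 per type,
    het/hom mixed), depth 30x, 10 kb reads, 0.2% substitution error."""
    tpl = SimConfig(seed=1, ref_length=30_000, depth=30, read_length=10_000,
                    error_rate=0.002)
    return simulate_cohort(100, tpl, seed=1,
                           out_dir=tmp_path_factory.mktemp("study_cohort"))
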