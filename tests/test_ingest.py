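"""Region parsing, quality/identity metrics, and filtered BAM loading."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from svlens.ingest import (
    FilterConfig,
    RegionParseError,
    RegionSpec,
    WHOLE_CHROM_END,
    alignment_identity,
    load_region_reads,
    mean_base_quality,
    parse_region,
    segment_from_record,
    segment_passes,
)

from conftest import write_bam


@pytest.mark.parametrize(
    "text,expected",
    [
        ("chr1:1-10", ("chr1", 0, 10)),
        ("chrX:1,000-2,000", ("chrX", 999, 2000)),
        ("ctg5", ("ctg5", 0, WHOLE_CHROM_END)),
    ],
)
def test_parse_region_valid(text, expected):
    r = parse_region(text)
    assert (r.chrom, r.start, r.end) == expected


@pytest.mark.parametrize("text", ["chr2:200-100", "chr1:abc-200", ":", ""])
def test_parse_region_invalid(text):
    with pytest.raises((RegionParseError, ValueError)):
        parse_region(text)


def test_region_spec_rejects_empty_interval():
    with pytest.raises(ValueError):
        RegionSpec("chr1", 10, 10)


def test_mean_base_quality_basics_and_oracle():
    assert mean_base_quality([20] * 50) == 20.0
    assert mean_base_quality([10, 30]) == 20.0
    assert mean_base_quality(None) == float("inf")  # absent qualities pass
    rng = np.random.default_rng(42)
    quals = rng.integers(0, 60, size=1000).tolist()
    assert mean_base_quality(quals) == pytest.approx(sum(quals) / len(quals))


def test_alignment_identity_examples_and_oracle():
    cigar = [(0, 100)]  # 100M
    assert alignment_identity(cigar, 0) == 1.0
    assert alignment_identity(cigar, 40) == pytest.approx(0.60)
    # random CIGAR + NM vs the brute-force (alen - NM)/alen oracle
    rng = np.random.default_rng(7)
    for _ in range(50):
        ops = []
        for _k in range(rng.integers(1, 8)):
            ops.append((int(rng.choice([0, 1, 2, 4])), int(rng.integers(1, 500))))
        alen = sum(ln for op, ln in ops if op in (0, 1, 2))
        if alen == 0:
            continue
        nm = int(rng.integers(0, alen))
        assert alignment_identity(ops, nm) == pytest.approx((alen - nm) / alen)


def test_alignment_identity_without_nm_uses_match_fraction():
    cigar = [(0, 60), (1, 20), (0, 20)]  # 60M 20I 20M
    assert alignment_identity(cigar, None) == pytest.approx(80 / 100)


def _threshold_bam(tmp_path):
    """Reads straddling each evidence threshold (Q20, 60% identity, 100 bp)."""
    contigs = {"chr1": 10_000}
    recs = [
        dict(name="ok", chrom="chr1", pos=1000, cigar="200M", qual=30,
             tags=[("NM", 2, "i")]),
        dict(name="low_q", chrom="chr1", pos=1000, cigar="200M", qual=19,
             tags=[("NM", 2, "i")]),
        dict(name="edge_q", chrom="chr1", pos=1000, cigar="200M", qual=20,
             tags=[("NM", 0, "i")]),
        dict(name="low_ident", chrom="chr1", pos=1100, cigar="200M", qual=30,
             tags=[("NM", 90, "i")]),       # identity 0.55
        dict(name="edge_ident", chrom="chr1", pos=1100, cigar="200M", qual=30,
             tags=[("NM", 80, "i")]),       # identity 0.60 passes at equality
        dict(name="short", chrom="chr1", pos=1200, cigar="99M", qual=30,
             tags=[("NM", 0, "i")]),
        dict(name="edge_len", chrom="chr1", pos=1200, cigar="100M", qual=30,
             tags=[("NM", 0, "i")]),
    ]
    return write_bam(tmp_path / "thr.bam", contigs, recs), recs, contigs


def test_step1_filters_match_brute_force(tmp_path):
    bam, recs, contigs = _threshold_bam(tmp_path)
    cfg = FilterConfig()
    region = RegionSpec("chr1", 0, 10_000)
    got = {g.read_name for g in load_region_reads(bam, region, cfg)}

    # independent brute-force pass over all records
    expected = set()
    with pysam.AlignmentFile(str(bam)) as af:
        for rec in af.fetch():
            seg = segment_from_record(rec)
            if (seg.mean_baseq >= 20 and seg.identity >= 0.60
                    and seg.ref_span >= 100):
                expected.add(rec.query_name)
    assert got == expected
    assert got == {"ok", "edge_q", "edge_ident", "edge_len"}


def test_filtering_is_monotone(tmp_path):
    bam, _recs, _contigs = _threshold_bam(tmp_path)
    region = RegionSpec("chr1", 0, 10_000)
    base = FilterConfig()
    n0 = len(load_region_reads(bam, region, base))
    for stricter in [
        FilterConfig(min_mean_baseq=25),
        FilterConfig(min_identity=0.8),
        FilterConfig(min_map_len=150),
        FilterConfig(min_mapq=70),
    ]:
        assert len(load_region_reads(bam, region, stricter)) <= n0


def test_empty_region_returns_no_groups(tmp_path):
    bam, _r, _c = _threshold_bam(tmp_path)
    assert load_region_reads(bam, RegionSpec("chr1", 9000, 9500)) == []


def test_missing_index_is_explicit(tmp_path):
    bam, _r, _c = _threshold_bam(tmp_path)
    for idx in (bam.with_suffix(".bam.bai"), bam.with_suffix(".bai")):
        if idx.exists():
            idx.unlink()
    with pytest.raises(FileNotFoundError, match="index"):
        load_region_reads(bam, RegionSpec("chr1", 0, 100))


def test_supplementary_partner_fetched_via_sa(tra_locus):
    """A translocation read queried on one chromosome brings in its mate-side
    supplementary segment, so both chromosomes appear in one group."""
    region = RegionSpec("tra", 14_000, 16_000)
    groups = load_region_reads(tra_locus.bam, region)
    split = [g for g in groups if len({s.chrom for s in g.segments}) == 2]
    assert split, "expected split translocation reads"
    for g in split:
        assert {s.chrom for s in g.segments} == {"tra", "tra_B"}
        starts = [s.query_start for s in g.segments]
        assert starts == sorted(starts)


def test_segments_sorted_and_strand_corrected(het_del_locus):
    groups = load_region_reads(het_del_locus.bam, RegionSpec("hetdel", 14_000, 16_000))
    assert groups
    for g in groups:
        qs = [s.query_start for s in g.segments]
        assert qs == sorted(qs)
        for a, b in zip(g.segments, g.segments[1:]):
            assert b.query_start >= a.query_end  # trimmed non-overlapping
        for s in g.segments:
            assert 0 <= s.query_start < s.query_end <= g.read_length


def test_segment_passes_respects_mapq():
    from conftest import make_segment

    seg = make_segment(mapq=5)
    assert segment_passes(seg, FilterConfig())
    assert not segment_passes(seg, FilterConfig(min_mapq=10))
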