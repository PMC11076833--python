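"""Force-calling: windows, informative-read screening, AF thresholds, VCF I/O."""

from __future__ import annotations

import pysam
import pytest

from svlens.breakpoints import Breakpoint, ReadStructure, classify_read_structure
from svlens.genotype import (
    GenotypeConfig,
    SvQuery,
    assign_genotype,
    collect_informative_reads,
    evaluation_window,
    genotype_query,
    genotype_vcf,
    queries_from_bed,
    queries_from_vcf,
)
from svlens.ingest import ReadGroup, RegionSpec, load_region_reads

from conftest import make_segment


def test_evaluation_window_padding_and_clipping():
    cfg = GenotypeConfig()
    (w,) = evaluation_window(SvQuery("chr1", 10_000, 12_000, "DEL", 2000), cfg)
    assert (w.chrom, w.start, w.end) == ("chr1", 9_000, 13_000)
    (w,) = evaluation_window(SvQuery("chr2", 500, 501, "INS", 100), cfg)
    assert (w.start, w.end) == (0, 1_500)
    ws = evaluation_window(
        SvQuery("chr3", 5_000, 5_001, "TRA", 0, mate_chrom="chr9", mate_pos=70_000), cfg)
    assert [(w.chrom, w.start, w.end) for w in ws] == [
        ("chr3", 4_000, 6_000), ("chr9", 69_000, 71_000)]


@pytest.mark.parametrize(
    "n_support,n_ref,expected",
    [
        (3, 7, "0/0"),    # af exactly 0.30: "exceeds" is strict
        (31, 69, "0/1"),  # af 0.31
        (8, 2, "0/1"),    # af exactly 0.80: "surpasses" is strict
        (81, 19, "1/1"),  # af 0.81
        (9, 1, "1/1"),
        (5, 5, "0/1"),
        (0, 10, "0/0"),
        (0, 0, "./."),
    ],
)
def test_assign_genotype_threshold_semantics(n_support, n_ref, expected):
    res = assign_genotype(n_support, n_ref)
    assert res.genotype == expected
    if n_support + n_ref:
        assert res.af == pytest.approx(n_support / (n_support + n_ref))


def test_assign_genotype_monotone_in_support():
    order = {"0/0": 0, "0/1": 1, "1/1": 2}
    for n_ref in (1, 5, 20):
        prev = -1
        for n_support in range(0, 60):
            g = assign_genotype(n_support, n_ref).genotype
            assert order[g] >= prev
            prev = order[g]


def test_raising_thresholds_never_adds_hom_calls():
    counts = [(i, 20 - i) for i in range(21)]
    loose = GenotypeConfig(het_af=0.3, hom_af=0.8)
    tight = GenotypeConfig(het_af=0.4, hom_af=0.9)
    n_loose = sum(assign_genotype(s, r, loose).genotype == "1/1" for s, r in counts)
    n_tight = sum(assign_genotype(s, r, tight).genotype == "1/1" for s, r in counts)
    assert n_tight <= n_loose


def _del_query():
    return SvQuery("chr1", 10_000, 12_000, "DEL", 2_000, id="q1")


def _group(name, start, end, read_length=20_000):
    seg = make_segment(name, "chr1", start, end, 0, end - start,
                       cigar=[(0, end - start)])
    return ReadGroup(name, [seg], read_length)


def _del_structure(name, pos_a, pos_b):
    return ReadStructure(name, "DEL", [
        Breakpoint("chr1", pos_a, "chr1", pos_b, "++", "split", "DEL", pos_b - pos_a)
    ], pos_b - pos_a)


def test_low_coverage_read_is_excluded():
    g = _group("shallow", 11_200, 13_500)  # covers 40% of the DEL interval
    sup, ref = collect_informative_reads([g], [], _del_query())
    assert "shallow" not in sup | ref


def test_breakpoint_disparity_demotes_support():
    q = _del_query()
    near = _group("near", 8_000, 14_000)
    far = _group("far", 8_000, 14_000)
    sts = [_del_structure("near", 10_050, 12_050),
           _del_structure("far", 11_200, 13_200)]  # 1200 bp off the query start
    sup, ref = collect_informative_reads([near, far], sts, q)
    assert sup == {"near"}
    assert ref == {"far"}


def test_del_length_agreement_required():
    q = _del_query()
    g = _group("nested", 8_000, 14_000)
    # breakpoints within tolerance but the event is 6x the query length
    st = ReadStructure("nested", "DEL", [
        Breakpoint("chr1", 9_900, "chr1", 12_900, "++", "split", "DEL", 12_000)
    ], 12_000)
    sup, ref = collect_informative_reads([g], [st], q)
    assert sup == set() and ref == {"nested"}


def test_clip_evidence_supports_insertion():
    q = SvQuery("chr1", 10_000, 10_001, "INS", 1_500, id="ins")
    g = _group("clipped", 9_400, 10_000)
    from svlens.breakpoints import CigarEvent

    st = ReadStructure("clipped", "REF", [], 0, True,
                       [CigarEvent("CLIP", 10_000, 400, "right")])
    sup, _ref = collect_informative_reads([g], [st], q)
    assert sup == {"clipped"}


def test_genotype_query_recovers_het_deletion(het_del_locus):
    m = het_del_locus.manifest[0]
    q = SvQuery(m["contig"], m["pos"], m["pos"] + m["length"], "DEL",
                m["length"], id=m["id"])
    res = genotype_query(het_del_locus.bam, q)
    assert res.genotype == "0/1"
    assert 0.3 < res.af <= 0.8
    assert res.n_support + res.n_ref > 10


def test_genotype_vcf_round_trip(small_cohort, tmp_path):
    out = tmp_path / "called.vcf"
    results = genotype_vcf(str(small_cohort.bam), str(small_cohort.vcf), out)
    assert len(results) == len(small_cohort.manifest)
    with pysam.VariantFile(str(out)) as vf:
        recs = list(vf)
    assert len(recs) == len(small_cohort.manifest)
    truth = {m["id"]: m["genotype"] for m in small_cohort.manifest}
    n_match = 0
    for rec in recs:
        sample = rec.samples[0]
        assert sample["DV"] is not None and sample["DR"] is not None
        gt = "/".join("." if a is None else str(a) for a in sample["GT"])
        if gt == truth[rec.id]:
            n_match += 1
    assert n_match >= 9  # 10 moderate-depth loci


def test_genotype_vcf_empty_input(tmp_path):
    empty = tmp_path / "empty.vcf"
    empty.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=1000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    bam_dir = tmp_path
    from conftest import write_bam
    bam = write_bam(bam_dir / "e.bam", {"chr1": 1000}, [])
    out = tmp_path / "out.vcf"
    results = genotype_vcf(str(bam), str(empty), out)
    assert results == []
    with pysam.VariantFile(str(out)) as vf:
        assert "DV" in vf.header.formats
        assert list(vf) == []


def test_bnd_record_genotyped_via_tra_path(tra_locus, tmp_path):
    m = tra_locus.manifest[0]
    cand = tmp_path / "bnd.vcf"
    cand.write_text(
        "##fileformat=VCFv4.2\n"
        f'##contig=<ID={m["contig"]},length=30000>\n'
        f'##contig=<ID={m["mate_contig"]},length=30000>\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        f'{m["contig"]}\t{m["pos"] + 1}\tbnd1\tN\tN[{m["mate_contig"]}:{m["mate_pos"] + 1}[\t.\t.\tSVTYPE=BND\n'
    )
    queries = queries_from_vcf(cand)
    assert queries[0].sv_type == "TRA"
    assert queries[0].mate_chrom == m["mate_contig"]
    out = tmp_path / "bnd_out.vcf"
    results = genotype_vcf(str(tra_locus.bam), str(cand), out)
    assert results[0][0].genotype == m["genotype"]


def test_unparseable_svtype_passes_through(tmp_path, small_cohort):
    cand = tmp_path / "odd.vcf"
    cand.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=locus0000,length=30000>\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "locus0000\t100\todd1\tA\tT\t.\t.\tSVTYPE=WEIRD\n"
    )
    out = tmp_path / "odd_out.vcf"
    results = genotype_vcf(str(small_cohort.bam), str(cand), out)
    assert results[0][0].genotype == "./."
    with pysam.VariantFile(str(out)) as vf:
        recs = list(vf)
    assert len(recs) == 1


def test_queries_from_bed_columns(tmp_path):
    bed = tmp_path / "cand.bed"
    bed.write_text("chr1\t100\t300\tDEL\t200\nchr2\t500\t900\n")
    qs = queries_from_bed(bed)
    assert qs[0].sv_type == "DEL" and qs[0].sv_length == 200
    assert qs[1].sv_type == "REGION" and (qs[1].start, qs[1].end) == (500, 900)
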