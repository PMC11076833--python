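"""CIGAR event extraction, split-adjacency classification, and clustering."""

from __future__ import annotations

import numpy as np
import pytest

from svlens.breakpoints import (
    cigar_events,
    classify_read_structure,
    cluster_breakpoints,
    split_breakpoints,
    ReadStructure,
    Breakpoint,
)
from svlens.ingest import ReadGroup

from conftest import make_segment

L = 50  # minimum SV length used throughout


def cigar_walk_oracle(cigar, ref_start, min_len):
    """Independent CIGAR consumer: returns (kind, ref_pos, length) events."""
    out = []
    ref = ref_start
    for i, (op, ln) in enumerate(cigar):
        if op == 2 and ln >= min_len:  # D
            out.append(("DEL", ref, ln))
        elif op == 1 and ln >= min_len:  # I
            out.append(("INS", ref, ln))
        elif op in (4, 5) and ln >= min_len and i in (0, len(cigar) - 1):
            out.append(("CLIP", ref_start if i == 0 else None, ln))
        if op in (0, 2, 3, 7, 8):
            ref += ln
    # fix right-clip positions
    fixed = []
    for kind, pos, ln in out:
        fixed.append((kind, ref if pos is None else pos, ln))
    return fixed


@pytest.mark.parametrize(
    "cigar,ref_start,expected",
    [
        ([(0, 100)], 1000, []),
        ([(0, 50), (2, 60), (0, 50)], 1000, [("DEL", 1050, 60)]),
        ([(4, 80), (0, 100)], 1000, [("CLIP", 1000, 80)]),
        ([(0, 100), (1, 70), (0, 100)], 500, [("INS", 600, 70)]),
        ([(0, 100), (2, 49), (0, 100)], 0, []),  # below threshold
    ],
)
def test_cigar_events_against_walk_oracle(cigar, ref_start, expected):
    ref_end = ref_start + sum(ln for op, ln in cigar if op in (0, 2, 3, 7, 8))
    qlen = sum(ln for op, ln in cigar if op in (0, 1, 4, 7, 8))
    seg = make_segment(ref_start=ref_start, ref_end=ref_end, query_end=qlen, cigar=cigar)
    got = [(e.kind, e.ref_pos, e.length) for e in cigar_events(seg, L)]
    assert got == expected
    assert got == cigar_walk_oracle(cigar, ref_start, L)


def _pair_group(s1, s2, rgap, qgap, chrom2="chr1", read_length=100_000):
    """Build a 2-segment group with the given strand-aware ref/query gaps."""
    qlen = 1000
    a = make_segment("r", "chr1", 10_000, 11_000, 0, qlen, s1,
                     cigar=[(0, qlen)])
    q2s = qlen + qgap
    if chrom2 != "chr1":
        rs2 = 50_000
    elif s1 != s2:
        rs2 = 13_000  # opposite strands: gaps are irrelevant to the label
    elif s1 == "+":
        rs2 = 11_000 + rgap  # rgap = b.ref_start - a.ref_end
    else:
        rs2 = 10_000 - rgap - qlen  # rgap = a.ref_start - b.ref_end
    b = make_segment("r", chrom2, rs2, rs2 + qlen, q2s, q2s + qlen, s2,
                     cigar=[(0, qlen)])
    return ReadGroup("r", [a, b], read_length)


def rule_table_oracle(chrom_same, s1, s2, rgap, qgap, min_len):
    """Declarative restatement of the split-signature rules."""
    if not chrom_same:
        return "TRA"
    if s1 != s2:
        return "INV"
    if rgap <= -min_len:
        return "DUP"
    if rgap - qgap >= min_len:
        return "DEL"
    if qgap - rgap >= min_len:
        return "INS"
    return "REF"


def test_classification_matches_rule_table_exhaustively():
    gaps = [-2 * L, -L, 0, L, 2 * L]
    n = 0
    for s1 in "+-":
        for s2 in "+-":
            for rgap in gaps:
                for qgap in gaps:
                    group = _pair_group(s1, s2, rgap, qgap)
                    st = classify_read_structure(group, L)
                    want = rule_table_oracle(True, s1, s2, rgap, qgap, L)
                    assert st.sv_type == want, (s1, s2, rgap, qgap, st.sv_type)
                    n += 1
    assert n == 100


def test_translocation_from_cross_chromosome_pair():
    group = _pair_group("+", "+", 0, 0, chrom2="chr5")
    st = classify_read_structure(group, L)
    assert st.sv_type == "TRA"
    assert st.sv_length == 0
    bp = st.breakpoints[0]
    assert {bp.chrom_a, bp.chrom_b} == {"chr1", "chr5"}


def test_deletion_length_from_split_pair():
    """Split deletion: ref gap 85 kb at query gap ~0 gives an 85 kb DEL."""
    group = _pair_group("+", "+", 85_000, 0)
    st = classify_read_structure(group, L)
    assert st.sv_type == "DEL"
    assert st.sv_length == 85_000


def test_single_matched_segment_is_ref():
    group = ReadGroup("r", [make_segment(cigar=[(0, 100)])], 100)
    st = classify_read_structure(group, L)
    assert st.sv_type == "REF" and st.breakpoints == [] and st.sv_length == 0


def test_reverse_complement_invariance():
    """A read and its reverse-complement alignment classify identically."""
    rng = np.random.default_rng(3)
    gaps = [-2 * L, -L, 0, L, 2 * L, 500, 5000]
    read_length = 100_000
    for s1 in "+-":
        for s2 in "+-":
            for _ in range(10):
                rgap = int(rng.choice(gaps))
                qgap = int(rng.choice([0, L, 2 * L]))
                fwd = _pair_group(s1, s2, rgap, qgap, read_length=read_length)
                flip = {"+": "-", "-": "+"}
                rc_segments = []
                for seg in fwd.segments:
                    rc_segments.append(make_segment(
                        "r", seg.chrom, seg.ref_start, seg.ref_end,
                        read_length - seg.query_end, read_length - seg.query_start,
                        flip[seg.strand], cigar=seg.cigar))
                rc = ReadGroup("r", rc_segments, read_length)
                st_f = classify_read_structure(fwd, L)
                st_r = classify_read_structure(rc, L)
                assert (st_f.sv_type, st_f.sv_length) == (st_r.sv_type, st_r.sv_length)


def test_sv_length_respects_minimum():
    rng = np.random.default_rng(9)
    for _ in range(100):
        rgap = int(rng.integers(-3000, 3000))
        qgap = int(rng.integers(-200, 3000))
        st = classify_read_structure(_pair_group("+", "+", rgap, qgap), L)
        if st.sv_type in ("DEL", "INS", "DUP", "INV"):
            assert st.sv_length >= L


def test_multi_event_read_keeps_all_breakpoints_labels_largest():
    cigar = [(0, 100), (2, 60), (0, 100), (2, 400), (0, 100)]
    seg = make_segment(ref_start=1000, ref_end=1000 + 760, query_end=300, cigar=cigar)
    st = classify_read_structure(ReadGroup("r", [seg], 300), L)
    assert st.sv_type == "DEL"
    assert st.sv_length == 400
    assert len(st.breakpoints) == 2


def test_split_breakpoints_emits_one_per_adjacency():
    group = _pair_group("+", "+", 5000, 0)
    bps = split_breakpoints(group, L)
    assert len(bps) == 1
    bp = bps[0]
    assert bp.orient == "++" and bp.source == "split"
    assert bp.pos_b - bp.pos_a == 5000


def test_cluster_breakpoints_single_linkage_and_types():
    def st(name, pos):
        return ReadStructure(name, "DEL", [
            Breakpoint("chr1", pos, "chr1", pos + 500, "++", "split", "DEL", 500)
        ], 500)

    chain = [st("a", 1000), st("b", 1010), st("c", 1990)]
    clusters = cluster_breakpoints(chain, tol=1000)
    assert len(clusters) == 1
    assert clusters[0].support == 3
    assert clusters[0].pos_a == 1010  # median

    mixed = [st("a", 1000),
             ReadStructure("b", "INS",
                           [Breakpoint("chr1", 1000, "chr1", 1000, "++", "cigar", "INS", 80)], 80)]
    assert len(cluster_breakpoints(mixed, tol=1000)) == 2
    assert cluster_breakpoints([], tol=1000) == []


def test_cluster_support_conserves_breakpoints():
    rng = np.random.default_rng(5)
    sts = []
    for i in range(40):
        pos = int(rng.integers(0, 50_000))
        sts.append(ReadStructure(f"r{i}", "DEL", [
            Breakpoint("chr1", pos, "chr1", pos + 100, "++", "split", "DEL", 100)
        ], 100))
    clusters = cluster_breakpoints(sts, tol=500)
    assert sum(c.support for c in clusters) == 40
    assert all(c.support <= 40 for c in clusters)
    assert all("\t" in c.to_bedpe() for c in clusters)
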