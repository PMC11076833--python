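"""Depth profiles, base-level pileup, and spliced-alignment exon chains.

These feed the auxiliary display panels: a binned coverage curve for
deletion/duplication (local CNV) inspection, a per-base pileup for SNV/indel
display over short windows, and per-read exon chains for isoform structure
from RNA-seq / iso-seq alignments (introns encoded as CIGAR N ops).

Coverage is an alignment fact, not an SV call: deletion (D) and intron (N)
CIGAR ops contribute no coverage regardless of the SV length threshold used
elsewhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .ingest import (
    BAM_CDEL,
    BAM_CINS,
    BAM_CMATCH,
    BAM_CREF_SKIP,
    BAM_CSOFT_CLIP,
    _REF_CONSUMING,
    BAM_CDIFF,
    BAM_CEQUAL,
    FilterConfig,
    ReadGroup,
    RegionSpec,
    load_region_reads,
)

logger = logging.getLogger("svlens")

DEFAULT_PILEUP_CAP = 1000
PILEUP_FRIENDLY_LIMIT = 200  # per-base display is legible up to ~this width


@dataclass
class DepthProfile:
    region: RegionSpec
    bin_size: int
    depths: np.ndarray  # per-bin mean coverage

    @property
    def n_bins(self) -> int:
        return len(self.depths)


@dataclass
class PileupColumn:
    pos: int
    ref_base: str | None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(v for k, v in self.counts.items() if k != "INS")


@dataclass
class IsoformChain:
    read_name: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _match_blocks(seg) -> list[tuple[int, int]]:
    """Reference intervals consumed by aligned (M/=/X) ops of a segment."""
    blocks = []
    ref = seg.ref_start
    for op, ln in seg.cigar:
        if op in (BAM_CMATCH, BAM_CEQUAL, BAM_CDIFF):
            blocks.append((ref, ref + ln))
        if op in _REF_CONSUMING:
            ref += ln
    return blocks


def per_base_coverage(groups: list[ReadGroup], region: RegionSpec) -> np.ndarray:
    """Per-base aligned coverage over ``region`` from already-filtered reads."""
    cov = np.zeros(len(region), dtype=np.int64)
    for g in groups:
        for seg in g.segments:
            if seg.chrom != region.chrom:
                continue
            for bs, be in _match_blocks(seg):
                lo, hi = max(bs, region.start), min(be, region.end)
                if hi > lo:
                    cov[lo - region.start : hi - region.start] += 1
    return cov


def region_depth(
    bam: str | Path | pysam.AlignmentFile,
    region: RegionSpec,
    bin_size: int = 100,
    cfg: FilterConfig | None = None,
) -> DepthProfile:
    """Binned mean coverage over ``region`` from filtered reads."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    groups = load_region_reads(bam, region, cfg)
    cov = per_base_coverage(groups, region)
    n_bins = math.ceil(len(region) / bin_size)
    depths = np.zeros(n_bins, dtype=float)
    for i in range(n_bins):
        chunk = cov[i * bin_size : (i + 1) * bin_size]
        depths[i] = chunk.mean() if len(chunk) else 0.0
    return DepthProfile(region=region, bin_size=bin_size, depths=depths)


def pileup_bases(
    bam: str | Path | pysam.AlignmentFile,
    region: RegionSpec,
    ref: str | Path | pysam.FastaFile | None = None,
    cfg: FilterConfig | None = None,
    max_width: int = DEFAULT_PILEUP_CAP,
) -> list[PileupColumn]:
    """Per-position base counts (plus DEL and left-anchored INS counts)."""
    width = len(region)
    if width > max_width:
        raise ValueError(f"pileup region width {width} exceeds cap {max_width}")
    if width > PILEUP_FRIENDLY_LIMIT:
        logger.warning("pileup over %d bp; display is most legible below %d bp",
                       width, PILEUP_FRIENDLY_LIMIT)

    ref_seq = None
    if ref is not None:
        fa = ref if isinstance(ref, pysam.FastaFile) else pysam.FastaFile(str(ref))
        try:
            if region.chrom in fa.references:
                end = min(region.end, fa.get_reference_length(region.chrom))
                ref_seq = fa.fetch(region.chrom, region.start, end).upper()
            else:
                logger.warning("contig %s absent from FASTA; no reference row", region.chrom)
        finally:
            if not isinstance(ref, pysam.FastaFile):
                fa.close()

    groups = load_region_reads(bam, region, cfg)
    counts = [dict[str, int]() for _ in range(width)]

    # ingest keeps coordinates, not sequences, so base identities come from a
    # second per-record pass restricted to the filtered read-name set
    kept = {g.read_name for g in groups}
    af = bam if isinstance(bam, pysam.AlignmentFile) else pysam.AlignmentFile(str(bam))
    try:
        for rec in af.fetch(region.chrom, region.start, min(region.end,
                            af.get_reference_length(region.chrom))):
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            if rec.query_name not in kept:
                continue
            seq = rec.query_sequence
            ref_pos = rec.reference_start
            qpos = 0
            for op, ln in rec.cigartuples or []:
                if op in (BAM_CMATCH, BAM_CEQUAL, BAM_CDIFF):
                    for k in range(ln):
                        p = ref_pos + k
                        if region.start <= p < region.end:
                            base = seq[qpos + k].upper() if seq else "N"
                            col = counts[p - region.start]
                            col[base] = col.get(base, 0) + 1
                    ref_pos += ln
                    qpos += ln
                elif op in (BAM_CDEL, BAM_CREF_SKIP):
                    if op == BAM_CDEL:
                        for k in range(ln):
                            p = ref_pos + k
                            if region.start <= p < region.end:
                                col = counts[p - region.start]
                                col["DEL"] = col.get("DEL", 0) + 1
                    ref_pos += ln
                elif op == BAM_CINS:
                    p = ref_pos - 1  # left anchor
                    if region.start <= p < region.end:
                        col = counts[p - region.start]
                        col["INS"] = col.get("INS", 0) + 1
                    qpos += ln
                elif op == BAM_CSOFT_CLIP:
                    qpos += ln
    finally:
        if not isinstance(bam, pysam.AlignmentFile):
            af.close()

    out = []
    for i in range(width):
        if not counts[i]:
            continue
        rb = ref_seq[i] if ref_seq is not None and i < len(ref_seq) else None
        out.append(PileupColumn(pos=region.start + i, ref_base=rb, counts=counts[i]))
    return out


def extract_isoforms(
    bam: str | Path | pysam.AlignmentFile,
    region: RegionSpec,
    cfg: FilterConfig | None = None,
) -> list[IsoformChain]:
    """Per-read exon chains: maximal runs of reference-consuming non-N ops."""
    groups = load_region_reads(bam, region, cfg)
    chains: list[IsoformChain] = []
    for g in groups:
        segs = [s for s in g.segments if s.chrom == region.chrom]
        if not segs:
            continue
        # spliced reads are expected to be single-segment; take the widest
        seg = max(segs, key=lambda s: s.ref_span)
        exons: list[tuple[int, int]] = []
        ref = seg.ref_start
        cur_start = None
        for op, ln in seg.cigar:
            if op in _REF_CONSUMING and op != BAM_CREF_SKIP:
                if cur_start is None:
                    cur_start = ref
                ref += ln
            elif op == BAM_CREF_SKIP:
                if cur_start is not None:
                    exons.append((cur_start, ref))
                    cur_start = None
                ref += ln
        if cur_start is not None:
            exons.append((cur_start, ref))
        if exons:
            chains.append(IsoformChain(read_name=g.read_name, strand=seg.strand, exons=exons))
    chains.sort(key=lambda c: (c.span[0], c.span[1], c.read_name))
    return chains
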