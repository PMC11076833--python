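"""Alignment ingest: load reads from BAM, group split alignments, apply quality filters.

Long-read SV evidence lives in two places: the CIGAR string of a single
alignment record (mid-read D/I ops, terminal soft clips) and the adjacencies
between a read's primary and supplementary alignments (split mapping).  This
module loads every record overlapping a region, chases supplementary
alignments genome-wide through the SA tag so that translocation partners
outside the window are represented, converts everything into read-space
(strand-corrected) coordinates, and applies the three evidence filters:
mean base quality, alignment identity, and minimum mapping length.

All internal coordinates are 0-based half-open; conversion from 1-based
inclusive region strings happens only in :func:`parse_region`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger("svlens")

# CIGAR operation codes (pysam convention)
BAM_CMATCH = 0
BAM_CINS = 1
BAM_CDEL = 2
BAM_CREF_SKIP = 3
BAM_CSOFT_CLIP = 4
BAM_CHARD_CLIP = 5
BAM_CPAD = 6
BAM_CEQUAL = 7
BAM_CDIFF = 8

_REF_CONSUMING = {BAM_CMATCH, BAM_CDEL, BAM_CREF_SKIP, BAM_CEQUAL, BAM_CDIFF}
_QUERY_CONSUMING = {BAM_CMATCH, BAM_CINS, BAM_CSOFT_CLIP, BAM_CEQUAL, BAM_CDIFF}
_ALIGN_CONSUMING = {BAM_CMATCH, BAM_CINS, BAM_CDEL, BAM_CEQUAL, BAM_CDIFF}

#: Sentinel end coordinate for a bare-chromosome region ("whole contig").
WHOLE_CHROM_END = 2**31 - 1


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class ReadSegment:
    """One aligned segment (primary or supplementary) of a read.

    ``query_start``/``query_end`` are offsets in the *original read
    orientation*: for a reverse-strand alignment they are mapped through the
    read length so that segments of one read can be ordered along the read.
    """

    read_name: str
    chrom: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    mapq: int
    mean_baseq: float
    identity: float
    is_supplementary: bool
    cigar: list[tuple[int, int]] = field(default_factory=list)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ReadGroup:
    """All surviving segments of one read, sorted by query_start."""

    read_name: str
    segments: list[ReadSegment]
    read_length: int

    def span_on(self, chrom: str) -> tuple[int, int] | None:
        """Union display interval (gap included) of this read on ``chrom``."""
        segs = [s for s in self.segments if s.chrom == chrom]
        if not segs:
            return None
        return min(s.ref_start for s in segs), max(s.ref_end for s in segs)


@dataclass
class FilterConfig:
    """Evidence filters applied per segment.

    min_mean_baseq
        Minimum mean Phred base quality (default Q20).  Records without
        stored qualities pass, with a warning.
    min_identity
        Minimum alignment identity 1 - NM/aligned_length (default 0.60).
    min_map_len
        Minimum reference span of a segment in bases (default 100).
    min_mapq
        Minimum mapping quality (default 0; exposed separately from the
        base-quality threshold).
    """

    min_mean_baseq: float = 20.0
    min_identity: float = 0.60
    min_map_len: int = 100
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if min(self.min_mean_baseq, self.min_identity, self.min_map_len, self.min_mapq) < 0:
            raise ValueError("all filter thresholds must be >= 0")


_REGION_RE = re.compile(r"^([^\s:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> RegionSpec:
    """Parse ``chrom:start-end`` (1-based inclusive, commas allowed) or a bare
    chromosome name into a 0-based half-open :class:`RegionSpec`."""
    text = text.strip()
    if not text:
        raise RegionParseError("empty region string")
    m = _REGION_RE.match(text)
    if m is None:
        if ":" in text or "-" in text and any(c.isdigit() for c in text.split("-")[-1]):
            # looks like it tried to be chrom:start-end
            if ":" in text:
                raise RegionParseError(f"malformed region string: {text!r}")
        return RegionSpec(chrom=text, start=0, end=WHOLE_CHROM_END, label=text)
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 > end1:
        raise RegionParseError(f"inverted interval in region string: {text!r}")
    if start1 < 1:
        raise RegionParseError(f"positions are 1-based; got {text!r}")
    return RegionSpec(chrom=chrom, start=start1 - 1, end=end1, label=text)


def mean_base_quality(qualities: Sequence[int] | None) -> float:
    """Arithmetic mean of Phred base-quality scores.

    Returns +inf for absent qualities (quality string "*"), so such reads
    pass any threshold; callers log the condition.
    """
    if qualities is None or len(qualities) == 0:
        return float("inf")
    return float(np.mean(qualities))


def aligned_length(cigar: Iterable[tuple[int, int]]) -> int:
    """Bases consumed by the alignment proper: matches + insertions + deletions."""
    return sum(ln for op, ln in cigar if op in _ALIGN_CONSUMING)


def alignment_identity(cigar: Sequence[tuple[int, int]], edit_distance: int | None) -> float:
    """Identity = 1 - NM / aligned_length, clamped to [0, 1].

    With no edit-distance tag available, falls back to the fraction of the
    alignment consumed by match ops (insertions/deletions counted as errors).
    """
    alen = aligned_length(cigar)
    if alen <= 0:
        return 0.0
    if edit_distance is None:
        matched = sum(ln for op, ln in cigar if op in (BAM_CMATCH, BAM_CEQUAL, BAM_CDIFF))
        ident = matched / alen
    else:
        ident = 1.0 - edit_distance / alen
    return min(1.0, max(0.0, ident))


def _infer_read_length(rec: pysam.AlignedSegment) -> int:
    """Full read length including hard-clipped bases."""
    length = 0
    for op, ln in rec.cigartuples or []:
        if op in _QUERY_CONSUMING or op == BAM_CHARD_CLIP:
            length += ln
    return length


def segment_from_record(rec: pysam.AlignedSegment) -> ReadSegment:
    """Convert one BAM record into a strand-corrected :class:`ReadSegment`."""
    cigar = list(rec.cigartuples or [])
    read_len = _infer_read_length(rec)
    # clip lengths in reference orientation
    left_clip = cigar[0][1] if cigar and cigar[0][0] in (BAM_CSOFT_CLIP, BAM_CHARD_CLIP) else 0
    right_clip = cigar[-1][1] if cigar and cigar[-1][0] in (BAM_CSOFT_CLIP, BAM_CHARD_CLIP) else 0
    q_aln = read_len - left_clip - right_clip
    if rec.is_reverse:
        qs, qe = right_clip, right_clip + q_aln
        strand = "-"
    else:
        qs, qe = left_clip, left_clip + q_aln
        strand = "+"
    try:
        nm = rec.get_tag("NM")
    except KeyError:
        nm = None
        logger.debug("read %s: no NM tag; identity from CIGAR match ops only", rec.query_name)
    if rec.query_qualities is None:
        logger.debug("read %s: no base qualities stored; passes quality filter", rec.query_name)
    return ReadSegment(
        read_name=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        query_start=qs,
        query_end=qe,
        strand=strand,
        mapq=rec.mapping_quality,
        mean_baseq=mean_base_quality(rec.query_qualities),
        identity=alignment_identity(cigar, nm),
        is_supplementary=rec.is_supplementary,
        cigar=cigar,
    )


def segment_passes(seg: ReadSegment, cfg: FilterConfig) -> bool:
    """Apply the per-segment evidence filters."""
    return (
        seg.mean_baseq >= cfg.min_mean_baseq
        and seg.identity >= cfg.min_identity
        and seg.ref_span >= cfg.min_map_len
        and seg.mapq >= cfg.min_mapq
    )


def _parse_sa_tag(sa: str) -> list[tuple[str, int, str]]:
    """Parse an SA tag into (chrom, 0-based pos, strand) triples."""
    out = []
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        out.append((fields[0], int(fields[1]) - 1, fields[2]))
    return out


def _trim_query_overlaps(segments: list[ReadSegment]) -> list[ReadSegment]:
    """Resolve query-space overlaps by trimming the lower-mapq segment
    (ties trim the query-later segment).  Segments trimmed to nothing drop."""
    segs = sorted(segments, key=lambda s: (s.query_start, s.query_end))
    out: list[ReadSegment] = []
    for seg in segs:
        if out and seg.query_start < out[-1].query_end:
            prev = out[-1]
            overlap = prev.query_end - seg.query_start
            if prev.mapq < seg.mapq:
                victim, edge = prev, "end"
            else:
                victim, edge = seg, "start"
            if edge == "end":
                victim.query_end -= overlap
                if victim.strand == "+":
                    victim.ref_end = max(victim.ref_start, victim.ref_end - overlap)
                else:
                    victim.ref_start = min(victim.ref_end, victim.ref_start + overlap)
            else:
                victim.query_start += overlap
                if victim.strand == "+":
                    victim.ref_start = min(victim.ref_end, victim.ref_start + overlap)
                else:
                    victim.ref_end = max(victim.ref_start, victim.ref_end - overlap)
            if victim.query_end - victim.query_start <= 0 or victim.ref_span <= 0:
                if victim is prev:
                    out.pop()
                else:
                    continue
        out.append(seg)
    return out


def _open_bam(bam: str | Path | pysam.AlignmentFile) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(bam, pysam.AlignmentFile):
        return bam, False
    path = Path(bam)
    af = pysam.AlignmentFile(str(path))
    if not af.has_index():
        raise FileNotFoundError(
            f"{path} has no index; run 'samtools index {path}' (coordinate-sorted BAM required)"
        )
    return af, True


def load_region_reads(
    bam: str | Path | pysam.AlignmentFile,
    region: RegionSpec,
    cfg: FilterConfig | None = None,
) -> list[ReadGroup]:
    """Load filtered, grouped reads overlapping ``region``.

    One :class:`ReadGroup` is returned per read name with at least one
    surviving segment overlapping the region.  Supplementary alignments of
    surviving reads are fetched genome-wide via the SA tag, so translocation
    partners on other chromosomes are represented in the group.
    """
    cfg = cfg or FilterConfig()
    af, own = _open_bam(bam)
    try:
        chrom_len = None
        if region.chrom in (af.references or ()):
            chrom_len = af.get_reference_length(region.chrom)
        start, end = region.start, min(region.end, chrom_len or region.end)
        if chrom_len is not None and region.end > chrom_len:
            logger.warning(
                "region %s:%d-%d extends past contig end (%d); clipped",
                region.chrom, region.start, region.end, chrom_len,
            )
        by_read: dict[str, dict[tuple, ReadSegment]] = {}
        read_lens: dict[str, int] = {}
        sa_targets: dict[str, list[tuple[str, int, str]]] = {}

        def _consider(rec: pysam.AlignedSegment) -> None:
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                return
            seg = segment_from_record(rec)
            if not segment_passes(seg, cfg):
                return
            key = (seg.chrom, seg.ref_start, seg.strand, seg.is_supplementary)
            by_read.setdefault(rec.query_name, {})[key] = seg
            read_lens[rec.query_name] = max(
                read_lens.get(rec.query_name, 0), _infer_read_length(rec)
            )
            if rec.has_tag("SA"):
                sa_targets.setdefault(rec.query_name, []).extend(_parse_sa_tag(rec.get_tag("SA")))

        for rec in af.fetch(region.chrom, start, end):
            _consider(rec)

        # chase SA partners lying outside the queried window
        for name, targets in list(sa_targets.items()):
            for chrom, pos, _strand in targets:
                have = any(
                    seg.chrom == chrom and seg.ref_start == pos
                    for seg in by_read.get(name, {}).values()
                )
                if have or chrom not in (af.references or ()):
                    continue
                for rec in af.fetch(chrom, pos, pos + 1):
                    if rec.query_name == name and rec.reference_start == pos:
                        _consider(rec)

        groups = []
        for name, segmap in sorted(by_read.items()):
            segs = _trim_query_overlaps(list(segmap.values()))
            if not segs:
                continue
            # the group must still touch the queried window
            if not any(
                s.chrom == region.chrom and s.ref_start < end and s.ref_end > start
                for s in segs
            ):
                continue
            groups.append(ReadGroup(read_name=name, segments=segs, read_length=read_lens[name]))
        return groups
    finally:
        if own:
            af.close()
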