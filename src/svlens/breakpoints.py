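"""Breakpoint detection and per-read SV classification.

Two evidence channels feed the classifier:

* **CIGAR events** — mid-read D/I operations and terminal soft/hard clips of
  a single alignment record, at or above the minimum SV length.
* **Split adjacencies** — for a read aligned in several segments, each
  consecutive pair of segments in query (read) order defines a putative
  breakpoint joining two reference loci.

Classification of an adjacency uses the signed reference gap (``rgap``) and
query gap (``qgap``) between the two segments.  Because a read aligned on the
minus strand traverses the reference right-to-left, the reference gap is
computed strand-aware; this makes classification invariant under
reverse-complementing the read.  Rules, in precedence order:

1. segments on different chromosomes → ``TRA``;
2. opposite strands on one chromosome → ``INV`` (length = distance between
   the two junction loci);
3. reference re-visit, ``rgap <= -min_sv_length`` → ``DUP`` (length =
   ``-rgap``; the tandem-duplication signature, which also presents as an
   insertion of upstream sequence and therefore takes precedence);
4. ``rgap - qgap >= min_sv_length`` → ``DEL``;
5. ``qgap - rgap >= min_sv_length`` → ``INS``.

A read with no qualifying event is a reference (``REF``) read.  Multi-event
reads keep every breakpoint; the read's single label is the type of its
largest event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .ingest import (
    BAM_CDEL,
    BAM_CHARD_CLIP,
    BAM_CINS,
    BAM_CSOFT_CLIP,
    _REF_CONSUMING,
    ReadGroup,
    ReadSegment,
)

SV_TYPES = ("REF", "DEL", "INS", "DUP", "INV", "TRA")

DEFAULT_MIN_SV_LENGTH = 50
DEFAULT_CLUSTER_TOL = 1000


@dataclass(frozen=True)
class CigarEvent:
    kind: str  # DEL | INS | CLIP
    ref_pos: int
    length: int
    side: str  # left | right | internal


@dataclass(frozen=True)
class Breakpoint:
    """Two joined reference loci with junction orientation.

    Intra-chromosomal breakpoints are normalized so that
    ``(chrom_a, pos_a) <= (chrom_b, pos_b)``.  ``sv_length`` is the event
    size implied by this single junction (0 where not applicable).
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    orient: str  # '++', '+-', '-+', '--'
    source: str  # 'cigar' | 'split'
    sv_type: str = "REF"
    sv_length: int = 0


@dataclass
class ReadStructure:
    """The per-read SV interpretation."""

    read_name: str
    sv_type: str
    breakpoints: list[Breakpoint] = field(default_factory=list)
    sv_length: int = 0
    has_clip: bool = False
    clips: list[CigarEvent] = field(default_factory=list)


def cigar_events(segment: ReadSegment, min_sv_length: int = DEFAULT_MIN_SV_LENGTH) -> list[CigarEvent]:
    """Extract DEL/INS/CLIP events >= ``min_sv_length`` from a segment's CIGAR."""
    events: list[CigarEvent] = []
    cigar = segment.cigar
    ref = segment.ref_start
    n = len(cigar)
    for i, (op, ln) in enumerate(cigar):
        if op == BAM_CDEL and ln >= min_sv_length:
            events.append(CigarEvent("DEL", ref, ln, "internal"))
        elif op == BAM_CINS and ln >= min_sv_length:
            events.append(CigarEvent("INS", ref, ln, "internal"))
        elif op in (BAM_CSOFT_CLIP, BAM_CHARD_CLIP) and ln >= min_sv_length:
            side = "left" if i == 0 else "right" if i == n - 1 else "internal"
            if side != "internal":
                pos = segment.ref_start if side == "left" else segment.ref_end
                events.append(CigarEvent("CLIP", pos, ln, side))
        if op in _REF_CONSUMING:
            ref += ln
    return events


def _junction_pos(seg: ReadSegment, which: str) -> int:
    """Reference coordinate of the read-end of ``seg`` adjacent to a junction.

    ``which`` = 'later' for the query-later end of the segment, 'earlier' for
    the query-earlier end.  On the minus strand the query-later end of the
    segment sits at the segment's reference *start*.
    """
    if which == "later":
        return seg.ref_end if seg.strand == "+" else seg.ref_start
    return seg.ref_start if seg.strand == "+" else seg.ref_end


def _adjacency(a: ReadSegment, b: ReadSegment, min_sv_length: int) -> Breakpoint:
    """Classify the junction between query-consecutive segments ``a`` then ``b``."""
    pos_a = _junction_pos(a, "later")
    pos_b = _junction_pos(b, "earlier")
    orient = a.strand + b.strand
    qgap = b.query_start - a.query_end

    if a.chrom != b.chrom:
        ca, pa, cb, pb, orient2 = a.chrom, pos_a, b.chrom, pos_b, orient
        if (cb, pb) < (ca, pa):
            ca, pa, cb, pb = cb, pb, ca, pa
            orient2 = orient[::-1]
        return Breakpoint(ca, pa, cb, pb, orient2, "split", "TRA", 0)

    if a.strand != b.strand:
        lo, hi = sorted((pos_a, pos_b))
        return Breakpoint(a.chrom, lo, a.chrom, hi, orient, "split", "INV", hi - lo)

    # same chromosome, same strand: strand-aware reference gap
    if a.strand == "+":
        rgap = b.ref_start - a.ref_end
    else:
        rgap = a.ref_start - b.ref_end
    lo, hi = sorted((pos_a, pos_b))
    if rgap <= -min_sv_length:
        return Breakpoint(a.chrom, lo, a.chrom, hi, orient, "split", "DUP", -rgap)
    if rgap - qgap >= min_sv_length:
        return Breakpoint(a.chrom, lo, a.chrom, hi, orient, "split", "DEL", rgap - qgap)
    if qgap - rgap >= min_sv_length:
        return Breakpoint(a.chrom, lo, a.chrom, hi, orient, "split", "INS", qgap - rgap)
    return Breakpoint(a.chrom, lo, a.chrom, hi, orient, "split", "REF", 0)


def split_breakpoints(group: ReadGroup, min_sv_length: int = DEFAULT_MIN_SV_LENGTH) -> list[Breakpoint]:
    """One classified breakpoint per consecutive segment pair in query order."""
    segs = sorted(group.segments, key=lambda s: s.query_start)
    return [_adjacency(a, b, min_sv_length) for a, b in zip(segs, segs[1:])]


def classify_read_structure(
    group: ReadGroup, min_sv_length: int = DEFAULT_MIN_SV_LENGTH
) -> ReadStructure:
    """Interpret a read's SV structure from split adjacencies and CIGAR events."""
    bps: list[Breakpoint] = []
    clips: list[CigarEvent] = []
    if len(group.segments) >= 2:
        bps.extend(bp for bp in split_breakpoints(group, min_sv_length) if bp.sv_type != "REF")
    for seg in group.segments:
        for ev in cigar_events(seg, min_sv_length):
            if ev.kind == "DEL":
                bps.append(
                    Breakpoint(seg.chrom, ev.ref_pos, seg.chrom, ev.ref_pos + ev.length,
                               seg.strand * 2, "cigar", "DEL", ev.length)
                )
            elif ev.kind == "INS":
                bps.append(
                    Breakpoint(seg.chrom, ev.ref_pos, seg.chrom, ev.ref_pos,
                               seg.strand * 2, "cigar", "INS", ev.length)
                )
            else:
                clips.append(ev)
    if not bps:
        return ReadStructure(group.read_name, "REF", [], 0, bool(clips), clips)
    # TRA has no length; give it top precedence among equals by treating its
    # size as the largest when selecting the read label.
    def _key(bp: Breakpoint) -> tuple:
        return (bp.sv_type == "TRA", bp.sv_length)

    top = max(bps, key=_key)
    sv_length = 0 if top.sv_type == "TRA" else top.sv_length
    return ReadStructure(group.read_name, top.sv_type, bps, sv_length, bool(clips), clips)


@dataclass
class BreakpointCluster:
    """Consensus over read breakpoints of one type on one chromosome pair."""

    sv_type: str
    chrom_a: str
    chrom_b: str
    pos_a: int
    pos_b: int
    sv_length: int
    support: int
    read_names: list[str]

    def to_bedpe(self) -> str:
        return "\t".join(
            str(x) for x in (
                self.chrom_a, self.pos_a, self.pos_a + 1,
                self.chrom_b, self.pos_b, self.pos_b + 1,
                self.sv_type, self.sv_length, self.support,
                ",".join(self.read_names),
            )
        )


def cluster_breakpoints(
    structures: list[ReadStructure], tol: int = DEFAULT_CLUSTER_TOL
) -> list[BreakpointCluster]:
    """Single-linkage clustering of same-type, same-chromosome-pair breakpoints.

    Breakpoints within ``tol`` of each other (on pos_a, chained) merge;
    consensus positions and length are medians; support counts contributing
    reads.
    """
    items: list[tuple[str, Breakpoint]] = []
    for st in structures:
        for bp in st.breakpoints:
            items.append((st.read_name, bp))
    by_key: dict[tuple, list[tuple[str, Breakpoint]]] = {}
    for name, bp in items:
        by_key.setdefault((bp.sv_type, bp.chrom_a, bp.chrom_b), []).append((name, bp))
    clusters: list[BreakpointCluster] = []
    for (sv_type, ca, cb), members in sorted(by_key.items()):
        members.sort(key=lambda m: (m[1].pos_a, m[1].pos_b))
        run: list[tuple[str, Breakpoint]] = []
        for m in members:
            if run and m[1].pos_a - run[-1][1].pos_a > tol:
                clusters.append(_consensus(sv_type, ca, cb, run))
                run = []
            run.append(m)
        if run:
            clusters.append(_consensus(sv_type, ca, cb, run))
    return clusters


def _consensus(sv_type: str, ca: str, cb: str, members: list[tuple[str, Breakpoint]]) -> BreakpointCluster:
    names = list(dict.fromkeys(name for name, _ in members))
    return BreakpointCluster(
        sv_type=sv_type,
        chrom_a=ca,
        chrom_b=cb,
        pos_a=int(median(bp.pos_a for _, bp in members)),
        pos_b=int(median(bp.pos_b for _, bp in members)),
        sv_length=int(median(bp.sv_length for _, bp in members)),
        support=len(names),
        read_names=names,
    )
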