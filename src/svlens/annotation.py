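"""Feature-track overlap for the annotation lane (genes, repeats, segdups).

Tracks are user-supplied BED 3/6 files or GenePred gene models (optionally
gzip-compressed).  Features intersecting the queried region are returned
clipped to the region bounds, tagged with their track name, for drawing
beneath the read panel.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

from .ingest import RegionSpec

logger = logging.getLogger("svlens")

TRACKS = ("gene", "repeat", "segdup")


@dataclass(frozen=True)
class AnnotationFeature:
    chrom: str
    start: int
    end: int
    name: str
    track: str


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_bed(path: Path):
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            yield f[0], int(f[1]), int(f[2]), name


def _iter_genepred(path: Path):
    """GenePred: name chrom strand txStart txEnd cdsStart cdsEnd exonCount
    exonStarts exonEnds [...].  Tolerates a leading bin column."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f and f[0].isdigit() and len(f) > 10:  # UCSC "bin" column
                f = f[1:]
            name, chrom = f[0], f[1]
            yield chrom, int(f[3]), int(f[4]), name


def is_genepred(path: str | Path) -> bool:
    """Heuristic: GenePred rows have strand in column 3 and >= 10 columns."""
    path = Path(path)
    try:
        with _open_text(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f and f[0].isdigit() and len(f) > 10:
                    f = f[1:]
                return len(f) >= 10 and f[2] in ("+", "-")
    except OSError:
        return False
    return False


def overlap_features(
    tracks: dict[str, str | Path] | list[tuple[str, str | Path]],
    region: RegionSpec,
) -> list[AnnotationFeature]:
    """All features from the given track files intersecting ``region``,
    clipped to the region bounds.  Missing files yield an empty lane with a
    warning — annotation is optional."""
    if isinstance(tracks, dict):
        items = list(tracks.items())
    else:
        items = list(tracks)
    out: list[AnnotationFeature] = []
    for track, path in items:
        path = Path(path)
        if not path.exists():
            logger.warning("annotation track %s: file %s missing; lane left empty", track, path)
            continue
        rows = _iter_genepred(path) if is_genepred(path) else _iter_bed(path)
        for chrom, start, end, name in rows:
            if chrom != region.chrom or start >= region.end or end <= region.start:
                continue
            out.append(
                AnnotationFeature(
                    chrom=chrom,
                    start=max(start, region.start),
                    end=min(end, region.end),
                    name=name,
                    track=track,
                )
            )
    out.sort(key=lambda f: (f.track, f.start, f.end, f.name))
    return out
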