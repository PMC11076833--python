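"""Force-call genotyping of candidate SVs from read-level structures.

Given a candidate SV (from VCF or BED), the genotyper re-examines the reads
around its breakpoints rather than discovering variants de novo.  Reads are
first screened for informativeness: a read must cover at least half of the
SV interval (for point-like SVs: of a +/-500 bp breakend neighborhood) and
align at least 100 bp inside the evaluation window.  A surviving read
supports the candidate when it carries a same-type structure whose
breakpoints all fall within the disparity tolerance (1000 bp) of the
candidate's; otherwise it counts as a reference read.  The allele frequency
AF = support / (support + reference) is thresholded strictly: AF > 0.3 gives
0/1 and AF > 0.8 gives 1/1; with evidence present but AF <= 0.3 the call is
0/0, and with no informative reads at all it is ./..

Deletion support additionally requires the read-level event length to agree
with the candidate's within max(0.5 x SVLEN, 1000 bp), so nested or adjacent
deletions are not conflated.  Insertion support also accepts reads with a
long terminal soft-clip anchored within the disparity tolerance of the
insertion breakend — such reads are too short to traverse the inserted
sequence, but their clip is direct evidence of it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pysam

from .breakpoints import (
    DEFAULT_MIN_SV_LENGTH,
    ReadStructure,
    classify_read_structure,
)
from .ingest import FilterConfig, ReadGroup, RegionSpec, load_region_reads

logger = logging.getLogger("svlens")

GENOTYPES = ("0/0", "0/1", "1/1", "./.")


@dataclass
class SvQuery:
    """One candidate SV interval (0-based half-open; end = start+1 for INS/BND)."""

    chrom: str
    start: int
    end: int
    sv_type: str
    sv_length: int = 0
    id: str = "."
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"SvQuery {self.id}: end < start")


@dataclass
class GenotypeResult:
    query_id: str
    n_support: int
    n_ref: int
    af: float
    genotype: str


@dataclass
class GenotypeConfig:
    """Force-calling parameters.

    min_overlap_frac
        Minimum fraction of the SV interval (or breakend neighborhood) a
        read's aligned span must cover to be informative (default 0.5).
    max_bp_disparity
        Maximum distance in bases between a read breakpoint and the
        candidate breakpoint for the read to count as support; also the
        window padding (default 1000).
    min_region_align_len
        Minimum aligned bases inside the evaluation window (default 100).
    het_af / hom_af
        Strict AF thresholds: AF > het_af gives 0/1, AF > hom_af gives 1/1.
    breakend_flank
        Half-width of the neighborhood used for the coverage test of
        point-like SVs (INS, TRA breakends; default 500).
    """

    min_overlap_frac: float = 0.5
    max_bp_disparity: int = 1000
    min_region_align_len: int = 100
    het_af: float = 0.3
    hom_af: float = 0.8
    breakend_flank: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.het_af < self.hom_af <= 1):
            raise ValueError("need 0 <= het_af < hom_af <= 1")


def evaluation_window(query: SvQuery, cfg: GenotypeConfig | None = None) -> list[RegionSpec]:
    """Window(s) to examine: the SV interval padded by the disparity
    tolerance; for INS a window around the breakend; for TRA one window per
    breakend (hence a list)."""
    cfg = cfg or GenotypeConfig()
    pad = cfg.max_bp_disparity
    if query.sv_type == "TRA":
        wins = [RegionSpec(query.chrom, max(0, query.start - pad), query.start + pad)]
        if query.mate_chrom is not None and query.mate_pos is not None:
            wins.append(
                RegionSpec(query.mate_chrom, max(0, query.mate_pos - pad), query.mate_pos + pad)
            )
        return wins
    if query.sv_type == "INS":
        return [RegionSpec(query.chrom, max(0, query.start - pad), query.start + pad)]
    return [RegionSpec(query.chrom, max(0, query.start - pad), query.end + pad)]


def _aligned_len_in(group: ReadGroup, windows: list[RegionSpec]) -> int:
    total = 0
    for w in windows:
        for seg in group.segments:
            if seg.chrom == w.chrom:
                total += w.overlap(seg.ref_start, seg.ref_end)
    return total


def _coverage_frac(group: ReadGroup, query: SvQuery, cfg: GenotypeConfig) -> float:
    """Fraction of the assessment interval covered by the read's display span."""
    if query.sv_type in ("INS", "TRA", "DUP"):
        fl = cfg.breakend_flank
        if query.sv_type == "DUP":
            # A tandem duplication is decided at the re-visit junction (the
            # interval end).  A read is only unambiguous when it is anchored
            # upstream of the duplicated unit AND reaches the junction: a read
            # starting inside the unit may originate from either copy on the
            # alt allele and carries no signal either way.
            span = group.span_on(query.chrom)
            if span is None or span[0] > query.start + fl:
                return 0.0
            ends = [(query.chrom, query.end)]
        else:
            ends = [(query.chrom, query.start)]
        if query.sv_type == "TRA" and query.mate_chrom is not None:
            ends.append((query.mate_chrom, query.mate_pos))
        best = 0.0
        for chrom, pos in ends:
            span = group.span_on(chrom)
            if span is None:
                continue
            lo, hi = max(0, pos - fl), pos + fl
            ov = max(0, min(span[1], hi) - max(span[0], lo))
            best = max(best, ov / (hi - lo))
        return best
    span = group.span_on(query.chrom)
    if span is None or query.end == query.start:
        return 0.0
    ov = max(0, min(span[1], query.end) - max(span[0], query.start))
    return ov / (query.end - query.start)


def _supports(structure: ReadStructure, query: SvQuery, cfg: GenotypeConfig) -> bool:
    tol = cfg.max_bp_disparity
    for bp in structure.breakpoints:
        if bp.sv_type != query.sv_type:
            continue
        if query.sv_type == "TRA":
            chroms = {query.chrom: query.start}
            if query.mate_chrom is not None:
                chroms[query.mate_chrom] = query.mate_pos
            if bp.chrom_a in chroms and bp.chrom_b in chroms and bp.chrom_a != bp.chrom_b:
                if (abs(bp.pos_a - chroms[bp.chrom_a]) <= tol
                        and abs(bp.pos_b - chroms[bp.chrom_b]) <= tol):
                    return True
            continue
        if bp.chrom_a != query.chrom:
            continue
        if query.sv_type == "INS":
            if abs(bp.pos_a - query.start) <= tol or abs(bp.pos_b - query.start) <= tol:
                return True
            continue
        if abs(bp.pos_a - query.start) <= tol and abs(bp.pos_b - query.end) <= tol:
            if query.sv_type == "DEL" and query.sv_length > 0:
                if abs(bp.sv_length - query.sv_length) > max(0.5 * query.sv_length, tol):
                    continue
            return True
    if query.sv_type == "INS":
        # incompletely-spanned insertion: a long terminal clip at the breakend
        for ev in structure.clips:
            if abs(ev.ref_pos - query.start) <= tol:
                return True
    return False


def collect_informative_reads(
    groups: list[ReadGroup],
    structures: list[ReadStructure],
    query: SvQuery,
    cfg: GenotypeConfig | None = None,
) -> tuple[set[str], set[str]]:
    """Partition window reads into (supporting, reference) name sets;
    uninformative reads (coverage or aligned-length failure) are excluded."""
    cfg = cfg or GenotypeConfig()
    windows = evaluation_window(query, cfg)
    by_name = {st.read_name: st for st in structures}
    supporting: set[str] = set()
    reference: set[str] = set()
    for g in groups:
        if _coverage_frac(g, query, cfg) < cfg.min_overlap_frac:
            continue
        if _aligned_len_in(g, windows) < cfg.min_region_align_len:
            continue
        st = by_name.get(g.read_name)
        if st is not None and _supports(st, query, cfg):
            supporting.add(g.read_name)
        else:
            reference.add(g.read_name)
    return supporting, reference


def assign_genotype(
    n_support: int, n_ref: int, cfg: GenotypeConfig | None = None, query_id: str = "."
) -> GenotypeResult:
    """AF thresholding with strict inequalities; ./. iff no informative reads."""
    cfg = cfg or GenotypeConfig()
    if n_support < 0 or n_ref < 0:
        raise ValueError("counts must be >= 0")
    total = n_support + n_ref
    if total == 0:
        return GenotypeResult(query_id, 0, 0, 0.0, "./.")
    af = n_support / total
    if af > cfg.hom_af:
        gt = "1/1"
    elif af > cfg.het_af:
        gt = "0/1"
    else:
        gt = "0/0"
    return GenotypeResult(query_id, n_support, n_ref, af, gt)


def genotype_query(
    bam: str | Path | pysam.AlignmentFile,
    query: SvQuery,
    gcfg: GenotypeConfig | None = None,
    fcfg: FilterConfig | None = None,
    min_sv_length: int = DEFAULT_MIN_SV_LENGTH,
) -> GenotypeResult:
    """Full force-call of one candidate against one BAM."""
    gcfg = gcfg or GenotypeConfig()
    groups_by_name: dict[str, ReadGroup] = {}
    for w in evaluation_window(query, gcfg):
        for g in load_region_reads(bam, w, fcfg):
            groups_by_name.setdefault(g.read_name, g)
    groups = list(groups_by_name.values())
    structures = [classify_read_structure(g, min_sv_length) for g in groups]
    sup, ref = collect_informative_reads(groups, structures, query, gcfg)
    return assign_genotype(len(sup), len(ref), gcfg, query.id)


# ---------------------------------------------------------------------------
# candidate parsing (VCF / BED) and annotated VCF output
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


class _SafeInfo:
    """INFO accessor tolerant of keys absent from the VCF header."""

    def __init__(self, rec: pysam.VariantRecord):
        self._info = rec.info

    def get(self, key, default=None):
        try:
            return self._info.get(key, default)
        except (KeyError, ValueError):
            return default


def query_from_vcf_record(rec: pysam.VariantRecord) -> SvQuery | None:
    """Build an SvQuery from a VCF record; None when SVTYPE is unusable."""
    info = _SafeInfo(rec)
    svtype = info.get("SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    if svtype is None and rec.alts:
        m = re.match(r"^<(\w+)(?::[\w:]+)?>$", rec.alts[0] or "")
        if m:
            svtype = m.group(1)
        elif _BND_RE.search(rec.alts[0] or ""):
            svtype = "BND"
    if svtype is None:
        return None
    svtype = str(svtype).upper()
    if svtype == "BND":
        svtype = "TRA"
    if svtype not in ("DEL", "INS", "DUP", "INV", "TRA"):
        return None

    start = rec.start  # 0-based
    svlen = info.get("SVLEN")
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    svlen = abs(int(svlen)) if svlen is not None else 0
    end = rec.stop
    mate_chrom = mate_pos = None
    if svtype == "TRA":
        end = start + 1
        c2 = info.get("CHR2")
        p2 = info.get("POS2") or info.get("END2")
        if isinstance(p2, tuple):
            p2 = p2[0]
        if c2 is not None and p2 is not None:
            mate_chrom, mate_pos = str(c2), int(p2) - 1
        elif rec.alts:
            m = _BND_RE.search(rec.alts[0] or "")
            if m:
                mate_chrom, mate_pos = m.group(1), int(m.group(2)) - 1
    elif svtype == "INS":
        end = start + 1
        if svlen == 0:
            ref_a = rec.ref or ""
            alt_a = (rec.alts or ("",))[0] or ""
            if len(alt_a) > len(ref_a) and not alt_a.startswith("<"):
                svlen = len(alt_a) - len(ref_a)
    else:
        if end <= start:
            end = start + max(svlen, 1)
        if svlen == 0:
            svlen = end - start
    return SvQuery(
        chrom=rec.chrom, start=start, end=end, sv_type=svtype, sv_length=svlen,
        id=rec.id or f"{rec.chrom}_{rec.pos}_{svtype}", mate_chrom=mate_chrom,
        mate_pos=mate_pos,
    )


def queries_from_bed(path: str | Path) -> list[SvQuery]:
    """BED columns: chrom, start, end, [type], [length]."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            svtype = f[3].upper() if len(f) > 3 and f[3] else "REGION"
            svlen = int(f[4]) if len(f) > 4 and f[4] else max(0, end - start)
            out.append(
                SvQuery(chrom=chrom, start=start, end=end, sv_type=svtype,
                        sv_length=svlen, id=f"{chrom}_{start}_{svtype}_{i}")
            )
    return out


def queries_from_vcf(path: str | Path) -> list[SvQuery | None]:
    """One entry per record; None marks records with unusable SVTYPE."""
    with pysam.VariantFile(str(path)) as vf:
        return [query_from_vcf_record(rec) for rec in vf]


_HEADER_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Reads supporting the variant">',
    '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Informative reference reads">',
    '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency among informative reads">',
]


def genotype_vcf(
    bams: list[str | Path] | str | Path,
    vcf_in: str | Path,
    vcf_out: str | Path,
    gcfg: GenotypeConfig | None = None,
    fcfg: FilterConfig | None = None,
    min_sv_length: int = DEFAULT_MIN_SV_LENGTH,
    sample_names: list[str] | None = None,
) -> list[list[GenotypeResult]]:
    """Re-genotype every record of ``vcf_in`` against one or more BAMs.

    Output preserves record order and non-genotype fields; sample columns
    (one per BAM) carry the recomputed GT plus DV/DR/AF.  Records whose
    SVTYPE cannot be interpreted pass through with GT ./..  Returns the
    per-record, per-sample results in input order.
    """
    bam_list = [bams] if isinstance(bams, (str, Path)) else list(bams)
    if sample_names is None:
        sample_names = []
        for b in bam_list:
            name = Path(str(b)).stem
            while name in sample_names:
                name += "_2"
            sample_names.append(name)

    gcfg = gcfg or GenotypeConfig()
    results: list[list[GenotypeResult]] = []
    with pysam.VariantFile(str(vcf_in)) as vin:
        header = pysam.VariantHeader()
        for rec in vin.header.records:
            if rec.type == "FORMAT":
                continue
            header.add_record(rec)
        for line in _HEADER_LINES:
            header.add_line(line)
        for s in sample_names:
            header.add_sample(s)
        with pysam.VariantFile(str(vcf_out), "w", header=header) as vout:
            for rec in vin:
                query = query_from_vcf_record(rec)
                if query is None:
                    logger.warning("record %s: unparseable SVTYPE; emitting GT ./.", rec.id)
                new = vout.new_record(
                    contig=rec.chrom, start=rec.start, stop=rec.stop,
                    alleles=rec.alleles, id=rec.id, qual=rec.qual,
                )
                for f in rec.filter.keys():
                    new.filter.add(f)
                for k, v in rec.info.items():
                    try:
                        new.info[k] = v
                    except (KeyError, ValueError):
                        pass
                rec_results = []
                for i, bam in enumerate(bam_list):
                    if query is None:
                        res = GenotypeResult(rec.id or ".", 0, 0, 0.0, "./.")
                    else:
                        res = genotype_query(bam, query, gcfg, fcfg, min_sv_length)
                    rec_results.append(res)
                    sm = new.samples[i]
                    sm["GT"] = _gt_tuple(res.genotype)
                    sm["DV"] = res.n_support
                    sm["DR"] = res.n_ref
                    sm["AF"] = round(res.af, 4)
                results.append(rec_results)
                vout.write(new)
    return results


def _gt_tuple(gt: str) -> tuple:
    if gt == "./.":
        return (None, None)
    a, b = gt.split("/")
    return (int(a), int(b))
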