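"""Hermetic synthetic fixtures: reference, reads with implanted SVs, BAM, truth VCF.

The generator builds a diploid donor for each locus by applying SVs to a
random reference (DEL removes sequence, INS inserts novel sequence, DUP
tandem-duplicates, INV reverse-complements, TRA exchanges arms between two
contigs), samples reads uniformly from the donor haplotypes at a target
depth with substitution errors, and then *synthesizes* the alignments
directly from the known donor-to-reference block map — no external aligner.
Deletions/insertions up to ``max_cigar_indel`` are encoded as CIGAR D/I ops;
larger events and all DUP/INV/TRA junctions become split alignments
(primary + supplementary records cross-referenced through SA tags).  Reads
ending inside an inserted sequence receive terminal soft clips.

Everything is deterministic given the seed; with a fixed seed the emitted
BAM is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

SV_CYCLE = ("DEL", "INS", "DUP", "INV", "TRA")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


@dataclass
class SimConfig:
    """Study conditions for one simulated locus.

    sv_specs entries are (type, pos, length, genotype) with genotype in
    {"0/1", "1/1"}; positions are 0-based on the locus reference contig.
    """

    seed: int = 0
    ref_length: int = 30_000
    depth: float = 30.0
    read_length: int = 10_000
    sv_specs: list[tuple[str, int, int, str]] = field(default_factory=list)
    error_rate: float = 0.002
    max_cigar_indel: int = 5_000
    base_quality: int = 30
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        ivals = []
        for t, p, ln, gt in self.sv_specs:
            if t not in SV_CYCLE:
                raise ValueError(f"unknown SV type {t}")
            if gt not in ("0/1", "1/1"):
                raise ValueError(f"genotype must be 0/1 or 1/1, got {gt}")
            hi = p + (1 if t == "INS" else ln)
            if p < 0 or hi > self.ref_length:
                raise ValueError(f"SV {t}@{p} len {ln} outside reference")
            ivals.append((p, hi))
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("overlapping SVs in sv_specs")


# a donor chromosome is a list of blocks:
#   ("R", chrom, start, end, strand)  reference-derived sequence
#   ("I", seq_array)                  novel inserted sequence
Block = tuple


def _ref_blocks_to_seq(blocks: list[Block], contigs: dict[str, np.ndarray]) -> np.ndarray:
    parts = []
    for blk in blocks:
        if blk[0] == "R":
            _, chrom, s, e, strand = blk
            piece = contigs[chrom][s:e]
            parts.append(revcomp(piece) if strand == "-" else piece)
        else:
            parts.append(blk[1])
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)


def _alt_blocks(contig: str, n: int, svs: list[tuple], rng: np.random.Generator) -> list[Block]:
    """Apply non-TRA SVs (sorted, non-overlapping) to one contig."""
    blocks: list[Block] = []
    cur = 0
    for t, p, ln, _gt in sorted(svs, key=lambda s: s[1]):
        if t == "DEL":
            if p > cur:
                blocks.append(("R", contig, cur, p, "+"))
            cur = p + ln
        elif t == "INS":
            if p > cur:
                blocks.append(("R", contig, cur, p, "+"))
            blocks.append(("I", rng.choice(BASES, size=ln)))
            cur = p
        elif t == "DUP":
            blocks.append(("R", contig, cur, p + ln, "+"))
            cur = p
        elif t == "INV":
            if p > cur:
                blocks.append(("R", contig, cur, p, "+"))
            blocks.append(("R", contig, p, p + ln, "-"))
            cur = p + ln
    if n > cur:
        blocks.append(("R", contig, cur, n, "+"))
    return blocks


@dataclass
class _Piece:
    """A read sub-interval mapped through one donor block."""

    q0: int
    q1: int
    kind: str  # 'R' | 'I'
    chrom: str = ""
    rs: int = 0
    re: int = 0
    strand: str = "+"


def _map_read(blocks: list[Block], s: int, e: int) -> list[_Piece]:
    """Map donor interval [s, e) through the block list into pieces."""
    pieces: list[_Piece] = []
    d0 = 0
    for blk in blocks:
        if blk[0] == "R":
            _, chrom, bs, be, strand = blk
            blen = be - bs
        else:
            blen = len(blk[1])
        d1 = d0 + blen
        lo, hi = max(s, d0), min(e, d1)
        if hi > lo:
            q0, q1 = lo - s, hi - s
            if blk[0] == "I":
                pieces.append(_Piece(q0, q1, "I"))
            else:
                off0, off1 = lo - d0, hi - d0
                if strand == "+":
                    pieces.append(_Piece(q0, q1, "R", chrom, bs + off0, bs + off1, "+"))
                else:
                    pieces.append(_Piece(q0, q1, "R", chrom, be - off1, be - off0, "-"))
        d0 = d1
        if d0 >= e:
            break
    return pieces


@dataclass
class _Seg:
    """One alignment segment under assembly (ops kept in read order)."""

    chrom: str
    strand: str
    rs: int
    re: int
    q0: int
    q1: int
    ops: list[tuple[str, int]] = field(default_factory=list)  # M/I/D


def _pieces_to_segments(pieces: list[_Piece], max_cigar_indel: int) -> list[_Seg]:
    segs: list[_Seg] = []
    cur: _Seg | None = None
    pending_ins = 0  # inserted bases awaiting a ref-contiguous continuation
    for pc in pieces:
        if pc.kind == "I":
            pending_ins += pc.q1 - pc.q0
            continue
        if cur is not None and pc.chrom == cur.chrom and pc.strand == cur.strand:
            gap = pc.rs - cur.re if cur.strand == "+" else cur.rs - pc.re
            mergeable = (
                (pending_ins == 0 and 0 <= gap <= max_cigar_indel)
                or (0 < pending_ins <= max_cigar_indel and gap == 0)
            )
            if mergeable:
                if pending_ins:
                    cur.ops.append(("I", pending_ins))
                elif gap > 0:
                    cur.ops.append(("D", gap))
                cur.ops.append(("M", pc.q1 - pc.q0))
                if cur.strand == "+":
                    cur.re = pc.re
                else:
                    cur.rs = pc.rs
                cur.q1 = pc.q1
                pending_ins = 0
                continue
        # start a new segment; pending inserted bases become clip space
        pending_ins = 0
        cur = _Seg(pc.chrom, pc.strand, pc.rs, pc.re, pc.q0, pc.q1, [("M", pc.q1 - pc.q0)])
        segs.append(cur)
    return segs


_OPNUM = {"M": 0, "I": 1, "D": 2, "S": 4}


def _seg_cigar(seg: _Seg, read_len: int) -> list[tuple[int, int]]:
    """CIGAR tuples in reference orientation, with terminal soft clips."""
    ops = seg.ops if seg.strand == "+" else seg.ops[::-1]
    lead = seg.q0 if seg.strand == "+" else read_len - seg.q1
    tail = read_len - seg.q1 if seg.strand == "+" else seg.q0
    out: list[tuple[int, int]] = []
    if lead:
        out.append((_OPNUM["S"], lead))
    out.extend((_OPNUM[o], ln) for o, ln in ops)
    if tail:
        out.append((_OPNUM["S"], tail))
    return out


def _cigar_str(cig: list[tuple[int, int]]) -> str:
    names = {0: "M", 1: "I", 2: "D", 4: "S"}
    return "".join(f"{ln}{names[op]}" for op, ln in cig)


@dataclass
class SimulatedLocus:
    """Truth and file paths for one simulated fixture."""

    fasta: Path
    bam: Path
    vcf: Path
    manifest: list[dict]


def _truth_records(contig: str, n: int, svs: list[tuple], locus_id: str,
                   tra_mate: tuple[str, int] | None = None) -> list[dict]:
    out = []
    for k, (t, p, ln, gt) in enumerate(svs):
        rec = {
            "contig": contig, "type": t, "pos": p, "length": ln, "genotype": gt,
            "id": f"{locus_id}_{t}_{k}",
        }
        if t == "TRA" and tra_mate is not None:
            rec["mate_contig"], rec["mate_pos"] = tra_mate
        out.append(rec)
    return out


class _LocusModel:
    """Reference contigs plus diploid donor chromosomes for one locus."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator, locus_id: str):
        self.cfg = cfg
        self.locus_id = locus_id
        n = cfg.ref_length
        tra = [sv for sv in cfg.sv_specs if sv[0] == "TRA"]
        if tra and len(cfg.sv_specs) > 1:
            raise ValueError("a TRA must be the only SV at its locus")
        self.contigs: dict[str, np.ndarray] = {}
        self.manifest: list[dict] = []
        hap_chroms: list[list[list[Block]]] = [[], []]  # per haplotype
        if tra:
            t, p, ln, gt = tra[0]
            ca, cb = locus_id, locus_id + "_B"
            q = p  # symmetric breakpoints on the mate contig
            self.contigs[ca] = rng.choice(BASES, size=n)
            self.contigs[cb] = rng.choice(BASES, size=n)
            der1 = [("R", ca, 0, p, "+"), ("R", cb, q, n, "+")]
            der2 = [("R", cb, 0, q, "+"), ("R", ca, p, n, "+")]
            normal = [[("R", ca, 0, n, "+")], [("R", cb, 0, n, "+")]]
            hap_chroms[0] = [der1, der2]
            hap_chroms[1] = [der1, der2] if gt == "1/1" else normal
            self.manifest = _truth_records(ca, n, tra, locus_id, tra_mate=(cb, q))
        else:
            self.contigs[locus_id] = rng.choice(BASES, size=n)
            alt = _alt_blocks(locus_id, n, cfg.sv_specs, rng)
            ref = [("R", locus_id, 0, n, "+")]
            hom = [sv for sv in cfg.sv_specs if sv[3] == "1/1"]
            hap2 = _alt_blocks(locus_id, n, hom, rng) if hom else ref
            hap_chroms[0] = [alt]
            hap_chroms[1] = [hap2]
            self.manifest = _truth_records(locus_id, n, cfg.sv_specs, locus_id)
        self.donors = []  # (blocks, seq)
        for hap in hap_chroms:
            for blocks in hap:
                self.donors.append((blocks, _ref_blocks_to_seq(blocks, self.contigs)))

    def sample_reads(self, rng: np.random.Generator):
        """Yield (name, seq_array, pieces) for reads at the configured depth."""
        cfg = self.cfg
        total_ref = sum(len(s) for s in self.contigs.values())
        n_reads = int(round(cfg.depth * total_ref / cfg.read_length))
        lens = np.array([len(seq) for _, seq in self.donors], dtype=float)
        weights = lens / lens.sum()
        for i in range(n_reads):
            d = int(rng.choice(len(self.donors), p=weights))
            blocks, seq = self.donors[d]
            rl = min(cfg.read_length, len(seq))
            start = int(rng.integers(0, max(1, len(seq) - rl + 1)))
            read = seq[start : start + rl].copy()
            n_err = rng.binomial(rl, cfg.error_rate)
            if n_err:
                pos = rng.choice(rl, size=n_err, replace=False)
                read[pos] = BASES[(np.searchsorted(BASES, read[pos]) + rng.integers(1, 4, n_err)) % 4]
            pieces = _map_read(blocks, start, start + rl)
            yield f"{self.locus_id}_read{i:05d}", read, pieces


def _write_alignments(out_bam, model: _LocusModel, rng: np.random.Generator,
                      tid_of: dict[str, int]) -> None:
    cfg = model.cfg
    for name, read, pieces in model.sample_reads(rng):
        segs = _pieces_to_segments(pieces, cfg.max_cigar_indel)
        segs = [s for s in segs if s.q1 - s.q0 > 0]
        if not segs:
            continue
        rl = len(read)
        primary = max(range(len(segs)), key=lambda i: segs[i].q1 - segs[i].q0)
        cigars = [_seg_cigar(s, rl) for s in segs]
        nms = []
        for s in segs:
            indel = sum(ln for o, ln in s.ops if o in ("I", "D"))
            nms.append(indel)  # substitution count omitted: NM stays conservative
        sa_strs = []
        for s, cig, nm in zip(segs, cigars, nms):
            sa_strs.append(f"{s.chrom},{s.rs + 1},{s.strand},{_cigar_str(cig)},{cfg.mapq},{nm}")
        for i, (s, cig, nm) in enumerate(zip(segs, cigars, nms)):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.reference_id = tid_of[s.chrom]
            a.reference_start = s.rs
            a.mapping_quality = cfg.mapq
            a.cigartuples = cig
            flag = 0
            if s.strand == "-":
                flag |= 16
            if i != primary:
                flag |= 2048
            a.flag = flag
            seq = read if s.strand == "+" else revcomp(read)
            a.query_sequence = seq.tobytes().decode()
            a.query_qualities = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * rl)
            a.set_tag("NM", nm, "i")
            if len(segs) > 1:
                others = ";".join(sa_strs[j] for j in range(len(segs)) if j != i)
                a.set_tag("SA", others + ";", "Z")
            out_bam.write(a)


def _write_truth_vcf(path: Path, contigs: dict[str, int], manifest: list[dict]) -> None:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">')
    header.add_line('##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate position (1-based)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("SIM")
    order = {c: i for i, c in enumerate(contigs)}
    recs = sorted(manifest, key=lambda m: (order[m["contig"]], m["pos"]))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for m in recs:
            t, p, ln = m["type"], m["pos"], m["length"]
            stop = p + 1 if t in ("INS", "TRA") else p + ln
            rec = vf.new_record(
                contig=m["contig"], start=p, stop=stop,
                alleles=("N", f"<{t}>"), id=m["id"],
            )
            rec.info["SVTYPE"] = t
            if t != "TRA":
                rec.info["SVLEN"] = -ln if t == "DEL" else ln
            else:
                rec.info["CHR2"] = m["mate_contig"]
                rec.info["POS2"] = m["mate_pos"] + 1
            a, b = m["genotype"].split("/")
            rec.samples["SIM"]["GT"] = (int(a), int(b))
            vf.write(rec)


def _emit(out_dir: Path, name: str, models: list[_LocusModel],
          seed: int) -> SimulatedLocus:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs: dict[str, int] = {}
    manifest: list[dict] = []
    for m in models:
        for c, seq in m.contigs.items():
            contigs[c] = len(seq)
        manifest.extend(m.manifest)

    fasta = out_dir / f"{name}.fa"
    with open(fasta, "w") as fh:
        for m in models:
            for c, seq in m.contigs.items():
                fh.write(f">{c}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")
    pysam.faidx(str(fasta))

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs.items()],
    }
    tid_of = {c: i for i, c in enumerate(contigs)}
    unsorted = out_dir / f"{name}.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as ob:
        for i, m in enumerate(models):
            rng = np.random.default_rng([seed, 7919, i])
            _write_alignments(ob, m, rng, tid_of)
    bam = out_dir / f"{name}.bam"
    pysam.sort("--no-PG", "-o", str(bam), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam))

    vcf = out_dir / f"{name}.truth.vcf"
    _write_truth_vcf(vcf, contigs, manifest)
    with open(out_dir / f"{name}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=int)
    return SimulatedLocus(fasta=fasta, bam=bam, vcf=vcf, manifest=manifest)


def simulate_locus(cfg: SimConfig, out_dir: str | Path, name: str = "locus") -> SimulatedLocus:
    """Simulate one locus: reference FASTA, truth VCF, sorted+indexed BAM."""
    rng = np.random.default_rng([cfg.seed, 104729])
    model = _LocusModel(cfg, rng, name)
    return _emit(Path(out_dir), name, [model], cfg.seed)


def simulate_cohort(
    n_loci: int,
    template: SimConfig,
    seed: int,
    out_dir: str | Path,
    name: str = "cohort",
    length_range: tuple[int, int] = (200, 2000),
) -> SimulatedLocus:
    """Simulate ``n_loci`` independent loci into one FASTA/BAM/truth VCF.

    SV types cycle through DEL/INS/DUP/INV/TRA and genotypes alternate
    0/1 and 1/1, so 100 loci give 20 per type with both genotypes; event
    lengths are drawn uniformly from ``length_range``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    models = []
    for i in range(n_loci):
        rng = np.random.default_rng([seed, 15485863, i])
        sv_type = SV_CYCLE[i % len(SV_CYCLE)]
        gt = "0/1" if (i // len(SV_CYCLE)) % 2 == 0 else "1/1"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        center = template.ref_length // 2
        pos = center + int(rng.integers(-template.ref_length // 10, template.ref_length // 10))
        cfg = SimConfig(
            seed=seed,
            ref_length=template.ref_length,
            depth=template.depth,
            read_length=template.read_length,
            sv_specs=[(sv_type, pos, length, gt)],
            error_rate=template.error_rate,
            max_cigar_indel=template.max_cigar_indel,
            base_quality=template.base_quality,
        )
        models.append(_LocusModel(cfg, rng, f"locus{i:04d}"))
    return _emit(Path(out_dir), name, models, seed)
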