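# svlens

IGV-style static visualization and force-call genotyping of structural
variants (SVs) from long-read BAM files.

Long-read SV callers (sniffles, cuteSV, pbsv, svim) report candidate
deletions, insertions, duplications, inversions and translocations, but the
calls still need curation: does the read evidence at this locus really show
the reported event, at the reported length, and at which genotype?  Doing
that in an interactive browser is slow and easy to get wrong for
split-mapped reads.  svlens answers both questions in batch: it draws one
annotated, IGV-like figure per candidate (reads colored by the SV type each
read supports, event lengths printed at the breakpoints, translocations as
paired chromosome panes) and re-genotypes each candidate directly from the
read evidence.  It is aimed at anyone triaging long-read SV calls —
clinical curation, trio/pedigree review, or population screens.

## Method

Each read overlapping a candidate window is decomposed into aligned
segments (primary + SA-tagged supplementaries), filtered on mean base
quality (≥ Q20), alignment identity (≥ 60%) and mapping length (≥ 100 bp),
and classified from its CIGAR operations and split adjacencies.  For
query-consecutive segments with signed reference gap `rgap` (strand-aware)
and query gap `qgap`, with minimum SV length `L` (default 50 bp):

| signature                      | call | length        |
|--------------------------------|------|---------------|
| segments on different chroms   | TRA  | —             |
| opposite strands               | INV  | junction span |
| `rgap ≤ −L` (re-visit)         | DUP  | `−rgap`       |
| `rgap − qgap ≥ L`              | DEL  | `rgap − qgap` |
| `qgap − rgap ≥ L`              | INS  | `qgap − rgap` |

CIGAR `D`/`I` operations ≥ `L` contribute the same way.  For genotyping, a
candidate's informative reads are those covering ≥ 50% of its assessment
interval with ≥ 100 bp aligned in the window; a read supports the candidate
when it carries a same-type structure with breakpoints within 1000 bp of
the candidate's.  The allele frequency over informative reads,
`AF = DV / (DV + DR)`, is thresholded strictly:

    AF > 0.8 → 1/1        AF > 0.3 → 0/1        otherwise → 0/0

with `./.` reserved for loci without informative reads.  Details, edge
cases and design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

The package ships a hermetic simulator (no aligner needed), so a complete
round trip runs anywhere:

```python
from svlens import SimConfig, simulate_locus, SvQuery, genotype_query

cfg = SimConfig(seed=7, ref_length=30_000, depth=30, read_length=10_000,
                sv_specs=[("DEL", 15_000, 1_200, "0/1")])
sim = simulate_locus(cfg, "demo_dir", name="demo")

truth = sim.manifest[0]
query = SvQuery(chrom="demo", start=truth["pos"], end=truth["pos"] + truth["length"],
                sv_type="DEL", sv_length=truth["length"], id="demo_del")
res = genotype_query(sim.bam, query)
print(f"{query.id}: {res.n_support} supporting / {res.n_ref} reference reads "
      f"-> AF={res.af:.3f}, genotype {res.genotype} (truth {truth['genotype']})")
```

prints

```
demo_del: 23 supporting / 29 reference reads -> AF=0.442, genotype 0/1 (truth 0/1)
```

23 reads carry a ~1.2 kb deletion signature within 1 kb of the candidate
breakpoints, 29 informative reads do not; AF 0.442 exceeds the 0.3
heterozygous threshold but not the 0.8 homozygous one, so the locus is
called 0/1 — the simulated truth.

## Command line

Five subcommands mirror the workflow (`svlens <cmd> --help` for options):

```bash
svlens sv_browse        -i sample.bam -b candidates.vcf -f vcf -o figs/ \
                        --genome hg38 --quality 20 --sv_min_length 50 -F png
svlens snpindel_browse  -i sample.bam -b windows.bed -f bed -r ref.fa -o figs/
svlens regiondepth_browse -i sample.bam -o figs/ -r chr7:151,000,000-151,200,000
svlens rna_browse       -i isoseq.bam -b gene.bed -f bed --genepred models.genePred -o figs/
svlens sv_genotyping    -i sample.bam -b candidates.vcf -f vcf -o out/
```

`sv_browse` emits one figure per VCF/BED record (multiple `-i` BAMs stack
as labeled sub-panels; `--thread N` parallelizes without changing results).
Every figure comes with a `.json` sidecar listing the reads, rows, SV types
and printed lengths, so figures are scriptably checkable.  `sv_genotyping`
writes the input VCF back with GT, DV (supporting reads), DR (reference
reads) and AF filled per sample.

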