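# methaplo

Haplotype-aware DNA methylation analysis for chemically induced plant
epimutant populations.

Epimutant populations — plants regenerated under 5-azacytidine (5-Aza), a
cytidine analog that traps DNA methyltransferase and causes genome-wide
demethylation — are a breeding resource whose molecular characterization
requires a specific chain of analyses: per-cytosine methylation calling
from whole-genome bisulfite sequencing (WGBS), differentially methylated
region (DMR) detection against untreated controls, annotation of DMRs to
genomic features, intersection with gene expression, and — on a
haplotype-resolved hybrid genome — allele-specific expression (ASE),
allele-specific methylation (ASM), and their relationship to structural
variants (SVs) between the two haplotypes. `methaplo` implements that
chain end to end, plus a synthetic-data generator that emulates the
statistical structure of such a study, so every stage is testable on a
laptop without any sequencing data.

## The statistics at the core

* **Weighted methylation level** of a region with cytosines i = 1..n:
  Σᵢ Cᵢ / Σᵢ (Cᵢ + Tᵢ), where Cᵢ/Tᵢ are methylated/unmethylated read
  counts.
* **Site calling**: exact binomial test of each site (depth ≥ 5) against
  the conversion error estimated from an unmethylated lambda spike-in;
  BH-corrected, methylated iff q < 0.05.
* **DMRs**: 200-bp windows tiled every 100 bp, > 5 covered cytosines per
  context; binomial-GLM likelihood-ratio test (closed-form G-test on
  pooled counts; Fisher's exact with single replicates); DMR iff |Δlevel|
  > 25/25/15 points (CG/CHG/CHH) and q < 0.05, labeled hyper/hypo.
* **Expression**: TPM with rank groups N (= 0), L (0,1], LM (1,7],
  MH (7,100], H (> 100]; DEG and ASE calls from exact conditional
  binomial rate-ratio tests with a |log2FC| gate of 1.
* **ASM**: the same windowed test between maternal and paternal allele
  counts in gene space, with per-bin divergence Δ (percentage points) and
  divergence grades [25,50), [50,75), [75,100) for CG/CHG and [15,35),
  [35,55) for CHH.
* **SV grouping**: SyRI-style raw codes mapped to TRANS, INV, AV (absent)
  and PV (present) variations; insertions/deletions ≤ 50 bp are short
  variations, excluded from SV sets.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Run the full chain on the default synthetic study (2 × 1 Mb haplotypes,
200 genes, two controls and four epimutants of varying demethylation
strength, depth 20, two replicates):

```python
from methaplo.simulate import SimulationSpec
from methaplo.report import run_pipeline

results = run_pipeline(SimulationSpec(seed=1), "toy_study")
```

This writes the simulated inputs under `toy_study/sim/` (FASTA, GFF3,
SyRI-style SV table, cytosine reports, count matrices) and one TSV per
summary panel under `toy_study/report/`. With seed 1 the genome-wide CG
levels come out as:

```
sample      CG     CHG    CHH
AZA0-7     0.506   0.338  0.070   # control
AZA25-7    0.473   0.317  0.062
AZA50-11   0.396   0.278  0.050   # strongest epimutant
AZA100-14  0.464   0.307  0.060
```

i.e. the strongest epimutant lost ≈ 10.9 CG percentage points relative to
the control (its configured strength is 10.78), and `panel6a_ase_counts.tsv`
classes ≈ 28% of the 200 allele pairs as expression-biased (M or P), with
the remainder unbiased — stable across samples. `panel7d_asmr_sv.tsv`
shows ASM bins overlapping SVs to be more divergent than those that do
not (CG median |Δ| ≈ 50.9 vs 44.1 points, Wilcoxon p ≈ 0.002).

The same stages are exposed as a CLI for file-based use:

```sh
methaplo --out-dir toy --seed 1 simulate
methaplo --out-dir toy callmeth toy/sim/reports/AZA0-7_rep1_hap1.tsv
methaplo --out-dir toy dmr toy/sim/reports/AZA50-11_rep*_hap1.tsv \
         toy/sim/reports/AZA0-7_rep*_hap1.tsv toy/sim/hap1.fa
methaplo --out-dir toy sv toy/sim/syri.tsv
methaplo --out-dir toy report
```

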