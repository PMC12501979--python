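# Methods

`methaplo` implements a haplotype-aware analysis of whole-genome bisulfite
sequencing (WGBS) and RNA-seq data for a chemically induced epimutant
population — plants treated with 5-azacytidine (5-Aza), a methyltransferase
inhibitor that produces stochastic genome-wide demethylation — together
with a synthetic-data generator that reproduces the statistical structure
of such a study at desk scale. This note describes the models, the
parameters that matter, the numerical conventions, and what the synthetic
data does and does not establish about real data.

## Methylation model and site calling

Cytosines are classified into the three plant sequence contexts CG, CHG
and CHH (H ∈ {A, C, T}) from the strand-aware trinucleotide. A cytosine
whose trinucleotide runs off the chromosome end or contains an N has
undefined context and is excluded from all statistics — exclusion is
conservative and avoids inventing a context. CG sites are kept per strand
(not collapsed into symmetric CpG pairs), matching the per-cytosine report
dialect consumed by the readers.

For each site, `c_meth` is the number of reads supporting methylation
(C_i) and `c_total` the covering reads (C_i + T_i). The weighted
methylation level of a region with n cytosines is

    level = Σᵢ C_i / Σᵢ (C_i + T_i),

so deeper sites carry proportionally more weight; with equal depths it
reduces to the unweighted mean of per-site levels (asserted in tests).

Site calling tests each site with depth ≥ 5 against the bisulfite
conversion error rate estimated from the unmethylated lambda spike-in
(apparent methylation on lambda = 1 − conversion rate). The p-value is the
exact upper binomial tail P(X ≥ c_meth | c_total, error); q-values are
Benjamini–Hochberg over all tested sites of a sample jointly (the FDR
criterion is stated unstratified, so no per-context split), and a site is
methylated iff q < 0.05. A single pooled lambda error rate is used by
default; per-context rates are reported alongside for diagnostics.

Genome-wide "percentage of methylated sites" is reported with both
denominators (all cytosines, and covered cytosines only), because the two
conventions differ and summaries of this kind are ambiguous between them.

## DMR detection

Windows of 200 bp tiled every 100 bp are tested per context. A final
partial window is emitted only when strictly longer than the step — a
chromosome of length 500 therefore yields exactly four windows, and a
chromosome shorter than one window yields a single whole-chromosome
window. Windows enter testing when they contain more than 5 covered
cytosines of the tested context (strict reading of "more than 5"), in
both groups.

The test is a likelihood-ratio test of a binomial GLM with a group factor
on replicate-level counts. Because the group-model MLEs are the pooled
within-group proportions, the LRT reduces exactly to a G-test on the
pooled 2×2 table (χ², df = 1) and is evaluated in closed form — this makes
the statistic reproducible without any external package and fast enough to
test hundreds of thousands of windows. When either group has a single
replicate the test falls back to Fisher's exact test on the pooled table.
Windows with zero coverage in a group are skipped and logged.

A window is a DMR iff |level difference| exceeds 25/25/15 percentage
points (CG/CHG/CHH) and its BH q-value (per context within the
comparison) is below 0.05; direction is hypo when the test sample is
lower. Overlapping tiled windows are reported as-is (DMR counts are window
counts); no merging is applied at the calling stage. Cross-sample
intersections cluster DMRs by ≥ 1 bp overlap within the same context and,
by default, the same direction; the position-only count is reported
alongside because "shared" is ambiguous between the two readings.

## Feature annotation, DMGs and metaplots

Each region receives exactly one feature label by the position of its
midpoint, with priority promoter > exon > intron > downstream >
intergenic. The promoter is the upstream 2 kb of the TSS (strand-aware;
2 kb matches the flank used throughout and is exposed as a config knob
since no numeric definition is printed); downstream is the 2 kb past the
TTS. Midpoint assignment is deterministic and, for 200-bp regions against
multi-kb genes, the ambiguity it ignores is negligible. A gene is a DMG
iff ≥ 1 DMR overlaps its body ± 2 kb flanks.

Metaplots map each feature body proportionally onto 40 bins (reversed for
minus-strand features) and the 2 kb flanks onto 20 fixed 100-bp bins each;
the per-bin level is the weighted level over all sites of all features
mapped to that bin. Sites in a flank that happen to lie inside a
neighboring gene still contribute — metaplots are feature-relative, not
exclusive. Features shorter than 40 bp are skipped (logged). Count mass
within the body bins is conserved (no site double-counted or lost), which
is asserted as an invariant.

Telomeres are detected by counting the plant telomere motif TTTAGGG in the
terminal 1 kb of each chromosome end (reverse complement CCCTAAA at the
start); an end is telomeric at ≥ 10 copies. On random sequence the
expected count is ≈ 1000/4⁷ ≈ 0.06, so false positives are negligible.

## Expression, DEGs, ASE

TPM is the standard within-sample normalization using union-exon lengths.
Expression rank groups follow fixed boundaries: N (TPM = 0), L (0,1],
LM (1,7], MH (7,100], H (>100]. Methylation-level categories are zero
(= 0), LML (0,10%], MML (10%,20%], HML (>20%].

Differential expression and allele-specific expression (ASE) use exact
conditional binomial rate-ratio tests on library-size-normalized pooled
counts: under equal rates, conditional on the total, the test-group count
is binomial with proportion given by the library sizes. BH correction is
applied, and calls are gated by |log2FC| > 1 (DEGs) or ≥ 1 (ASE), with a
pseudocount of 1 on normalized means. No dispersion is modeled: with
overdispersed counts the binomial test is anti-conservative, which is an
accepted fidelity limit at toy scale. Concretely, at negative-binomial
dispersion 0.1 with two replicates the log2FC estimate has a noise floor
of ~0.46 log2 units, so pairs near the |log2FC| = 1 gate are inherently
unclassifiable and clearly unbiased pairs are miscalled at roughly the
rate that floor implies (~10%), not at the nominal FDR; clearly biased
pairs (true |log2FC| >= 2) are recovered essentially completely. The
tests verify exactly this behavior against the generator truth.
ASE classes are M (maternal-biased), P (paternal-biased), U (unbiased);
relabeling the haplotypes swaps M↔P and negates log2FC exactly. Bias is
called jointly across replicates (the samples are pooled in the test);
per-sample counts remain available for diagnostics.

## Allele-specific methylation and SV integration

ASMRs use the same 200/100 tiling and the same window test, maternal vs
paternal, restricted to each pair's gene body ± 2 kb, after lifting
paternal (hap2) site coordinates onto hap1 through the inter-haplotype
alignment map, at the same 25/25/15 thresholds and q < 0.05. Δ is the
maternal minus paternal level in percentage points; "distance of
methylation rates" is |Δ|. A pair is an ASMG iff it owns ≥ 1 ASMR bin.
Swapping haplotypes negates every Δ and leaves the ASMR set unchanged
(asserted exactly).

Divergence grades are half-open: CG/CHG [25,50), [50,75), [75,100); CHH
[15,35), [35,55); values outside are ungraded. The fold-change-by-grade
analysis distributes each ASMR bin's pair |log2FC| into the bin's grade
(the unit is the bin, which is what gives the analysis its sample size);
only ASE-biased pairs contribute. A known limitation of the generator
here: windows at the edges of a divergence patch carry intermediate Δ, so
strongly divergent pairs also populate the low grades, which compresses
the contrast between adjacent low grades; the top grade separates
cleanly.

SyRI-style raw variant codes group as: TRANS/INVTR → TRANS; INV → INV;
CPL/DEL/DUP-loss/INVDP-loss → AV (absent variations); CPG/INS/DUP-gain/
INVDP-gain → PV (present variations); INS/DEL of ≤ 50 bp are "short" and
excluded from SV sets. DUP/INVDP gain-vs-loss is resolved by an explicit
copy-status field (which haplotype carries the extra copy): query gain →
PV, query loss → AV. The grouping is total and deterministic, and the
category counts partition the non-SYN/SNP records.

SV–allele overlap is multi-label (an SV spanning an exon–intron junction
counts for both features); both the multi-label tally and a once-per-SV
tally are emitted. ASMR-vs-SV divergence is compared by two-sided Wilcoxon
rank-sum on |Δ| between SV-overlapping and non-overlapping ASMR bins.
SV location proportions between expression-biased and unbiased pairs are
compared by a χ² test (df = 2 for the 2×3 table; all-zero rows/columns are
dropped first so degenerate tables stay defined). Breakpoint support
counts reads covering ±500 bp around each breakpoint; reads longer than
20 kb form the high-confidence subset.

## The synthetic-data generator

The generator's defaults are the study conditions every downstream test
runs under: 2 chromosomes × 1 Mb per haplotype, 200 genes (~3 kb average,
in the proximal 60% of each chromosome; the distal 40% is gene-free
repeat/SV territory), 12% TE content, SNP rate 0.01/bp, a catalog of
SVs of every raw type plus ≤ 50-bp short variants, two controls and four
epimutants with per-context demethylation strengths (the strongest at
10.78/5.88/2.0 points for CG/CHG/CHH, the others moderate), 2 biological
replicates, mean depth 20 (Poisson per site), bisulfite conversion error
0.01 on a 20 kb lambda spike-in, and telomeric TTTAGGG arrays at both
chromosome ends. These sizes run the full pipeline in minutes on one CPU
and are a deliberate desk-scale rendering of the study design, not a
reproduction of its sequencing depth or genome size.

Site-level truth: CG and CHG levels are drawn from a high/low/mid mixture
(high mode Beta(40, 2.1) ≈ 0.95; low mode near 0.03; weights 0.42/0.50/0.08
for CG and 0.21/0.65/0.14 for CHG, chosen to match the polarized level
distributions such data show); CHH is low-mode dominated (weights
0.02/0.95/0.03) so the large majority of CHH sites sit below 10%. TE
cytosines are shifted toward the high mode (moderately for CHH), gene
bodies are CG-enriched, and levels dip near the TSS/TTS to produce the
canonical metaplot shape.

Epimutant demethylation is applied as coherent 200–2000 bp patches per
context (multiplying site levels by 0.08 inside a patch), sampled until
the genome-wide mean has dropped by the sample's configured strength —
windowed DMR detection requires spatially correlated effects, which
i.i.d. per-site demethylation would not provide. Patch placement avoids
the implanted-DMR intervals so implants remain clean test objects. Known
DMRs are implanted per epimutant (CG: 40 per sample at Δ = 40 points,
CHG: 20 at Δ = 40, CHH: 15 at Δ = 25; one in five hyper, the rest hypo)
on a plateau baseline so the realized Δ clears the detection threshold
with a stated margin at infinite depth (asserted from the truth arrays).

Allele pairs carry constitutive per-context divergences: 35% of pairs are
divergent with |ΔCG| ~ U(20, 90) (ΔCHG = 0.7 ΔCG; ΔCHH small), realized
as 1–3 local patches in the pair's gene space where the maternal and
paternal site levels are set |Δ| apart. Pairs overlapping an allele-space
SV get boosted CG/CHG divergence and damped CHH divergence, and their
divergence patch is placed at the SV interval itself — the mechanism the
SV-integration stage is designed to detect is local to the variant.
Allele expression follows log2FC = 0.025 × ΔCG + ε with ε ~ N(0, 0.15);
counts are negative binomial (dispersion 0.1) around a log-normal
baseline that couples negatively to gene-body CG methylation (the most
methylated 12% of genes are silenced, so non-expressed genes carry the
highest methylation), and epimutant expression responds to that sample's
own demethylation (6 log2FC units per unit drop in gene CG level), which
produces the dominance of negative methylation–expression correlations.
HiFi-like read spans (mean 19.6 kb) tile the genome at depth ~12 for
breakpoint validation.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: alignment and mapping artifacts, M-bias,
PCR duplicates, context-dependent conversion failure, culture-induced
methylation differences between control regenerants (our two controls
share identical truth, so the control-vs-control comparison is a clean
null, unlike real regenerated plants), CHH-specific correlation reversal,
linkage between SNP density and methylation, and realistic gene/TE length
distributions. Gene space covers ~60% of the toy genome (vs a few percent
of a real tree genome), which saturates gene-level overlap statistics
such as DMG enrichment; those are therefore tested for correctness of the
statistic, not for significance under the generator.

## Numerical choices and determinism

All randomness flows from integer-seeded NumPy generators (the study seed
plus small fixed offsets per stage); no order-dependent accumulation is
used, so a seed fully determines every output byte. Report TSVs are
written with fixed float formatting (%.6g) and deterministic ordering, and
the full pipeline re-run with the same seed is byte-identical (asserted).
Degenerate inputs follow explicit rules: empty regions have undefined
(NaN) level rather than 0; identical groups give p = 1; constant series
are excluded from correlations; all-zero rows/columns are dropped from χ²
tables; zero-coverage windows are skipped and logged. Compact letter
displays are the maximal cliques of the pairwise non-significance graph
(exhaustively enumerated — group counts are ≤ 5), so sharing a letter is
exactly equivalent to pairwise non-significance.
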