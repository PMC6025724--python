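# Methods

`intronmeth` implements an integrative analysis of gene-feature DNA
methylation and gene expression in a two-tissue bisulfite + RNA-seq design,
with the first intron as the focal feature. This note documents the models,
the parameters that matter, the synthetic data the package tests itself
against, and the numerical choices made where the design was open.

## Gene-feature partition

Each gene is collapsed to a single transcript model (the transcript with
the longest genomic span; ties broken by smallest start — a deterministic
rule suited to gene-level expression data) and partitioned into:

- **promoter** — 1,000 bp immediately upstream of the annotated TSS,
  strand-aware, clipped at chromosome edges, and deliberately *not* trimmed
  when it overlaps a neighbouring gene (the definition is a fixed window by
  construction);
- **first exon / rest of exons**, **first intron / rest of introns** —
  "first" in transcription order, i.e. the genomically last element on the
  minus strand; introns are the gaps between consecutive exons;
- **gene body** — first to last exon.

The exon/intron features tile the gene body exactly; this partition
property and its strand-mirror symmetry are asserted over thousands of
random gene models in the test suite. Coordinates are 0-based half-open
internally; GFF3/BED conventions are converted only at I/O boundaries.

## Methylation aggregation

Per-CpG calls (BSMAP-methratio, Bismark coverage, or bedGraph dialects) are
strand-merged by summing read counts (CpG methylation is symmetric),
filtered per sample to `10 ≤ coverage ≤ Q0.999` (the upper cut removes
PCR/duplication artefacts; quantiles use linear interpolation, numpy's
default), and united across samples by site-set intersection so every
retained site is observed in all samples.

Feature-level methylation averages in a fixed order: per site, the percent
values of one tissue's samples are averaged; then sites within a feature
are averaged *unweighted by coverage* — the aggregation operates on percent
values, not reads. A separate whole-genome path averages replicate percents
(100·m/t per replicate, positions under 10 reads excluded) for designs with
replicated WGBS.

## Expression

Counts become cpm (counts per million); the working scale is
log2(cpm + 1) — the offset is a conventional choice documented here because
low-expression genes sit in the plots and correlations. Deciles are
assigned per tissue among expressed genes (cpm > 0) by rank, sizes equal
within one gene, ties broken lexicographically on gene id for determinism
(decile 1 = lowest). Tissue-specific genes are those with cpm > 0 in every
sample of one tissue and 0 in every sample of the other (the strictest
reading). Differential expression is an *input* (gene, log2FC, FDR):
significance requires |log2FC| strictly above 1.5 and FDR < 0.05. The
normalization/DE model that produced the table is out of scope.

## Correlation analyses

Methylation–expression association uses Spearman's rank correlation (the
relationship is not assumed linear), computed over genes per feature and
tissue, with per-decile median/quartile summaries. Variance heterogeneity
across tissue × decile groups is tested Brown–Forsythe style — one-way
ANOVA on absolute deviations from group medians — followed by all-pairs
Tukey HSD; "residuals" in this context is interpreted as those deviations,
since the target quantity is spread, not location.

A feature is **methylated** above 90% mean methylation, **unmethylated**
below 10%; intermediates are excluded. The association of two features'
states across genes is the odds ratio (N00·N11)/(N01·N10) with a Wald
confidence interval at alpha = 0.001, i.e. exp(ln OR ± z₀.₉₉₉₅·SE),
SE = √(ΣN⁻¹), z₀.₉₉₉₅ ≈ 3.29053. Zero cells receive the Haldane–Anscombe
+0.5 correction and are flagged. CI coverage of the interval is verified by
simulation (≥ 99.4% over 1,000 tables at a known OR).

The extremes analysis restricts to deciles 1–2 (low) and 9–10 (high) and
methylation below 10% or above 90%; within each expression class the two
extreme fractions sum to one. First-intron length stratification splits
genes into four equal-size length quartiles (ties broken by gene id) and
recomputes Spearman per quartile. Two-group comparisons use the Wilcoxon
rank-sum test with continuity correction after removing outliers outside
the Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR), per group.

## Differential methylation

Per-site testing pools read counts within each tissue and applies a
binomial logistic regression of methylation on tissue. With a single
two-level factor the likelihood-ratio statistic has a closed form (the
G-test of the pooled table), which the implementation computes vectorized;
a unit test confirms equality with an IRLS-fitted GLM. P-values are
adjusted by Benjamini–Hochberg. A DMC needs |difference| > 15 percentage
points and q < 0.01. The difference is tissue-B-minus-tissue-A (positive =
hyper-methylated in B), with B designated in the run configuration.

Candidate regions chain consecutive united CpGs with inter-CpG gaps of at
most 100 bp (configurable); a region qualifies as a tissue-DMR with ≥ 5
CpGs, ≥ 3 DMCs, |mean difference| > 15 points and region q < 0.001, where
the region p combines site p-values by Stouffer's method and q is BH over
candidate regions. The caller does not reproduce any particular published
region-finder's boundaries; it preserves the stated, testable criteria. No
emitted region may violate them — asserted exhaustively in tests.

tDMRs are assigned to genes by any-overlap (≥ 1 bp) against the gene body
± 4 kb window, the promoter, the first exon and the first intron; a tDMR
may hit several genes and classes. Pairs of significant DEGs and their
tDMRs are classified into quadrants by sign(log2FC) × direction;
up+hypo/down+hyper form the negative-correlation set, the other two the
positive set, and Spearman rho of (log2FC, mean difference) is reported per
set. Distances of first-intron tDMRs from the first exon–first intron
boundary are measured from the transcription-order intron start to the
nearest edge of the region clipped to the intron.

## Motif analysis

Windows of ± 50 bp are taken around each united first-intron CpG, clipped
at the intron boundaries so the analysis stays inside the declared feature
(50 bp covers the maximum admissible motif width of 31 nt with margin).
PFMs in JASPAR text format are smoothed with pseudocount 1 per cell and
scored log2(p/bg) against a strand-symmetric background estimated from the
input windows; motifs wider than 31 nt are rejected.

Scanning quantizes log-odds to an integer lattice (10⁻³ log2-odds units)
and computes the **exact** score distribution under the background by
dynamic programming, giving exact p-values on the lattice; a hit requires
p < 10⁻⁴ (the conventional scanning threshold). The reverse strand is
scored with the reverse-complement matrix on the forward sequence, so hit
coordinates are always forward-strand. Exactness is verified against
exhaustive 4^w enumeration for widths ≤ 8.

Enrichment uses dinucleotide-preserving shuffles of the input windows as
controls (Altschul–Erickson Eulerian-path sampling: the exact dinucleotide
count multiset and both endpoints are preserved — asserted for every
shuffle in tests). Each sequence is scored by its average odds score (mean
over offsets and strands of 2^log-odds). The positive/negative threshold is
optimized over score split points and each split tested by a one-sided
Fisher's exact test; the best p is Bonferroni-corrected by the number of
splits tested and then by the number of motifs, with enrichment at
adjusted p < 0.001. As a numerical choice the split search is capped at
200 quantile-spaced candidates among the distinct scores — the calibration
tests (no enrichment ever under the null; ≥ 95% detection at 80% planted
instances) run with this cap in place.

Motifs enriched in both tissues and containing a CpG in their consensus
(argmax base per position; a probability-based rule, P(C) > 0.5 followed by
P(G) > 0.5, is available behind a flag) are selected for the CpG-level
analysis. Each motif CpG is classified per tissue against the first/third
quartiles of the analyzed CpG set — the set actually entering the analysis,
not all first-intron CpGs — as unmethylated (< Q1) or methylated (> Q3);
intermediates are excluded downstream. Relative distance is the
transcription-order offset from the intron start divided by intron width;
on the minus strand the boundary base maps to exactly 0. Expression
effects are tested by ANCOVA: log2cpm ~ distance + status +
distance:status with sequential (Type-I) sums of squares in that order,
plus a Shapiro–Wilk residual-normality p-value as a diagnostic. The unit
of analysis is one record per CpG; genes contributing several qualifying
CpGs contribute several records.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale (default 3,000 genes on 5 chromosomes; 3 bisulfite and 4 RNA
replicates per tissue):

- gene models with Poisson exon counts and log-normal element lengths;
- a latent per-gene methylation state (35% low) correlating feature states
  within a gene, so per-gene gene-body methylation is bimodal under the
  pure mixture configuration; promoter and first exon additionally share a
  5' CGI state (followed with probability 0.95 each) so their methylation
  states are strongly coupled, as for a shared CpG island, while remaining
  biased low overall;
- a planted first-intron effect: decile medians ramp linearly from 60%
  (decile 1) to 10% (decile 10), per tissue, with 12-point gene-level
  noise — the correlation analysis must recover a strongly negative rho
  while promoters stay expression-independent;
- beta-binomial read counts at negative-binomial coverage (mean 30),
  written as Bismark coverage files;
- negative-binomial RNA counts with tissue effects; 15% of genes carry a
  true |log2FC| ≥ 1.6; the DEG table is fabricated from the true effects;
- planted tissue-DMRs: dense 12-CpG runs in first introns with tissue
  deltas coupled to the expression fold change (60% anti-correlated, the
  rest positively coupled); 70% of host genes are differentially expressed;
- motif instances (synthetic PFMs built from consensus sequences, four
  CpG-containing and two CpG-free) embedded in first introns, near the
  intron start in high-expression genes, with the motif-CpG methylation
  increasing with relative planting position.

Identical seeds give byte-identical corpora. What the generator does *not*
emulate: real genome composition (CpG islands, isochores, repeats), RRBS
fragment selection, alignment and conversion artefacts, isoform diversity,
or cell-type mixtures within a tissue. Passing tests therefore demonstrate
correctness and calibration of the *methods* under the assumed statistical
structure, not biological conclusions about any real genome.

## Problem sizes and degenerate inputs

The test suite exercises the planted-correlation recovery at 3,000 genes,
DMC calibration at 20,000 sites, enrichment calibration over 50 seeded
runs, ANCOVA power over 100 seeded runs (with a lightweight record
simulator), and full-pipeline determinism at 250 genes; the acceptance
script runs the full pipeline at 1,200 genes. These sizes were chosen as
the smallest at which the planted effects are comfortably identifiable.

Degenerate inputs are handled explicitly: empty annotation or call files
yield empty outputs; constant methylation yields an NA correlation with a
warning; zero-coverage tissues skip the site; all-intermediate state
tables, single groups, emptied outlier groups and single-class ANCOVA
raise errors naming the problem.

## Limitations

- The DMC test pools replicates within tissue and is binomial: replicate
  overdispersion beyond the pooled model inflates the statistic in
  principle; the calibration test bounds the practical consequence under
  the generator's dispersion.
- The region caller's boundaries depend on the max-gap parameter; regions
  are not optimized against an empirical inter-CpG distance model.
- Enrichment approximates the published average-odds ranking method; it is
  not a bit-exact reimplementation of any external tool.
- Quartile classification of motif CpGs is computed on the analyzed set,
  which makes the class boundaries dataset-dependent by construction.
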