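# intronmeth

Integrative analysis of gene-feature DNA methylation and gene expression
for two-tissue bisulfite + RNA-seq designs, built around the first intron
as the focal regulatory feature.

Vertebrate methylomes are bimodal — CpGs sit near 0% or near 100%
methylation — and the relationship between methylation and transcription
depends strongly on *where* in the gene the CpGs lie. This package
partitions each gene into promoter (1 kb upstream of the TSS), first exon,
rest of exons, first intron, rest of introns and gene body, and asks, per
feature:

- How does mean methylation vary with expression? Genes are ranked into
  expression deciles per tissue (log₂ cpm among expressed genes) and the
  association is measured with Spearman's ρ — the first intron is the
  feature expected to carry the strongest, tissue-independent negative
  correlation.
- Are the methylation states of two features associated? Features are
  called methylated (> 90%) or unmethylated (< 10%) and the association is
  the odds ratio OR = (N₀₀·N₁₁)/(N₀₁·N₁₀) with 99.9% Wald confidence
  intervals exp(ln OR ± z₀.₉₉₉₅·√ΣN⁻¹).
- Where does tissue-specific differential methylation fall? Per-site
  binomial logistic regression (> 15-point difference, BH q < 0.01 for a
  DMC) feeds a region caller (≥ 5 CpGs, ≥ 3 DMCs, |mean diff| > 15,
  q < 0.001); tissue-DMRs are overlapped with features and paired with
  differentially expressed genes (|log₂FC| > 1.5, FDR < 0.05) into
  hyper/hypo × up/down quadrants.
- Which TF-binding motifs surround first-intron CpGs? ±50 bp windows are
  scanned with PWMs (exact score p-values by dynamic programming, hits at
  p < 10⁻⁴), enrichment is tested against dinucleotide-preserving shuffles
  (average odds score, Fisher's exact test, Bonferroni p < 0.001), and the
  methylation class of motif CpGs (quartile-based) is related to their
  distance from the first exon–first intron boundary and to host-gene
  expression by ANCOVA.

A synthetic-data module generates annotation (GFF3), genome (FASTA),
Bismark-format methylation calls, RNA-seq counts and a DEG table with the
statistical structure above — bimodal methylation, hypomethylated
promoters/first exons, a planted first-intron methylation–expression ramp,
planted tissue-DMRs and embedded motif instances — so the entire pipeline
is testable offline with known ground truth.

## Worked example

```bash
intronmeth synth --outdir corpus --seed 1 --n-genes 1200
intronmeth run-all --config corpus/config.yaml --outdir out
```

`out/decile_correlation.tsv` then contains (seed 1):

```
tissue  feature       n_genes  rho         p_value
muscle  first_exon    1101     0.019095    0.526775
muscle  first_intron  1010     -0.750385   1.94293e-183
muscle  gene_body     1106     -0.129701   1.51285e-05
muscle  promoter      1106     0.00424174  0.887943
muscle  rest_exons    1008     -0.0267402  0.396397
muscle  rest_introns  952      0.0288536   0.373853
```

The planted first-intron ramp (decile medians 60% → 10%) is recovered as a
strong negative Spearman correlation in both tissues, while the promoter —
generated expression-independent — shows |ρ| < 0.05: the qualitative
pattern the analysis is designed to detect. `out/quadrant_summary.tsv`
shows the two tDMR–DEG correlation sets, e.g.

```
overlap_class  corr_set  n_pairs  n_genes  rho        p_value
first_intron   negative  56       45       -0.867419  5.2908e-18
first_intron   positive  16       15       0.825607   8.18368e-05
```

— up-regulated genes with hypo-methylated tDMRs (and down-regulated with
hyper-methylated) form the large negative-correlation set; the smaller
positive set captures the positively coupled minority. Other outputs:
`feature_methylation.tsv`, `expression.tsv`, `odds_ratio.tsv`,
`extremes.tsv`, `length_quartiles.tsv`, `dmcs.tsv`, `tdmrs.tsv`/`.bed`,
`tdmr_overlaps.tsv`, `motif_enrichment.tsv`, `motif_cpgs.tsv`,
`ancova.tsv`, each with a provenance header (version, config hash, seed).
Stages can also be run individually (`intronmeth features|aggregate|
expression|integrate|diffmeth|motifs`), and real data can be supplied via
the same YAML configuration (GFF3 annotation; methratio/Bismark/bedGraph
methylation calls; a counts TSV; optionally a DEG table, JASPAR PFMs and a
genome FASTA).

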