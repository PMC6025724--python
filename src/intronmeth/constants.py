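"""Default thresholds of the analysis.

These are the published operating points of the pipeline: coverage filters
for bisulfite calls, the promoter window, the methylation-state cutoffs used
for the odds-ratio association, DMC/tDMR calling criteria, the differential
expression thresholds and the motif-enrichment significance level.
"""

#: minimum read coverage for a CpG call to be retained
MIN_COVERAGE = 10
#: per-sample upper coverage quantile; calls above it are discarded (PCR bias)
MAX_COVERAGE_QUANTILE = 0.999

#: promoter = this many bp upstream of the annotated TSS
PROMOTER_LENGTH = 1000
#: flank added on both sides of the gene body for the gene+/-4kb overlap class
FLANK_BP = 4000

#: a gene feature counts as unmethylated below this mean percent ...
UNMETH_CUTOFF = 10.0
#: ... and as methylated above this one; in between it is "intermediate"
METH_CUTOFF = 90.0

#: two-sided alpha for the Wald confidence interval of the odds ratio
OR_CI_ALPHA = 0.001

#: DMC: absolute methylation difference (percentage points) must exceed this
DMC_DIFF = 15.0
#: DMC: BH q-value must fall below this
DMC_Q = 0.01

#: tDMR: mean absolute difference over the region must exceed this
DMR_DIFF = 15.0
#: tDMR: region-level BH q-value threshold
DMR_Q = 0.001
#: tDMR: minimum number of united CpGs in the region
DMR_MIN_CPG = 5
#: tDMR: minimum number of DMCs in the region
DMR_MIN_DMC = 3
#: maximum gap (bp) between consecutive united CpGs chained into one region
DMR_MAX_GAP = 100

#: differential expression thresholds (|log2 FC| strictly greater, FDR below)
DEG_LFC = 1.5
DEG_FDR = 0.05

#: half-width (bp) of the sequence window drawn around each first-intron CpG
CPG_WINDOW = 50
#: maximum admissible TF-binding motif width (nt)
MAX_MOTIF_WIDTH = 31
#: motif hit threshold on the score p-value
MOTIF_HIT_P = 1e-4
#: enrichment significance after Bonferroni correction
ENRICH_P = 0.001

#: log2(cpm + CPM_OFFSET) is the expression scale used throughout
CPM_OFFSET = 1.0
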