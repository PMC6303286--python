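# Methods

## Scope and model

`trnascape` infers *relative* tRNA expression from small-RNA-seq
alignments. Reads from miRNA-seq libraries that happen to cover tRNA loci
are counted per annotated gene and normalized between samples; absolute
tRNA abundance is not identifiable from such data (tRNA modifications and
structure bias reverse transcription), so every downstream statement is
about relative levels and between-group contrasts. The package assumes
the alignments were produced elsewhere; it starts from SAM/BAM.

## Read counting

Primary, mapped, non-QC-fail alignments are assigned to the tRNA locus
with the largest overlap; exact ties go to the lexicographically smallest
`gene_id`. This rule is deterministic and order-independent; it does not
attempt isodecoder deconvolution of multi-mapped reads (a deliberate
non-goal — ambiguity is resolved upstream by the aligner's primary
flag). The library size is the total number of mapped primary reads in
the file, QC-fail reads included: it estimates the sample's sequencing
depth, of which the tRNA-assigned reads are a small subset. Coordinates
are 0-based half-open internally; GTF-style 1-based annotations must be
converted at the boundary.

Sample-level QC keeps a sample iff at least 50% of its reads passed the
sequencer's QC and at least 80% mapped to the genome; both thresholds are
inclusive (the drop condition is *fewer than* the cutoff).

## TMM normalization

Between-sample normalization follows the trimmed mean of M-values. The
reference is the sample whose 75th percentile of count fractions
(Y_gk/N_k) is closest to the mean such percentile. For sample k, over
genes expressed in both k and the reference r:

- M_g = log2((Y_gk/N_k)/(Y_gr/N_r)), A_g = ½·log2((Y_gk/N_k)·(Y_gr/N_r))
- weights w_g are the inverse of the delta-method variance
  (N_k−Y_gk)/(N_k·Y_gk) + (N_r−Y_gr)/(N_r·Y_gr)
- the most extreme 30% of M and 5% of A are removed (rank-based,
  symmetric; a gene must survive both trims)
- the factor is 2^(Σ w M / Σ w), and all factors are rescaled to
  geometric mean 1.

Degenerate cases: a sample proportional to the reference (max |M| <
1e-6) gets factor 1; a sample sharing no expressed gene with the
reference gets factor 1 with a warning. Expression values are
log2(Y/(N·f)·10⁶ + 1): TMM-scaled counts per million with a pseudocount
of 1, so a zero count maps to exactly 0. The detectability filter (mean
linear normalized value ≥ 1 within a cancer type, inclusive) operates on
the pre-log scale.

## Hierarchy

The decoded codon is the strict Watson-Crick reverse complement of the
anticodon; no wobble expansion is applied. Codon keys are
`"<AA>:<codon>"` so that initiator Met (`iMet:ATG`) stays distinct from
elongator Met (`Met:ATG`). Aggregation sums raw integer counts (total
counts are conserved exactly across levels) and TMM is re-run per level,
rather than summing normalized values — this keeps the normalization
model well defined at every level; it is a design choice where either
convention is defensible. The amino-acid panel is data-driven from the
annotation, never hard-coded.

## Differential expression

Per cancer type with ≥ 5 complete tumor/normal pairs (default,
configurable): paired Student's t-test on log2 expression, BH FDR across
features within the cancer type, calls at |fold change| ≥ 1.5 and
FDR < 0.05. The fold change is the ratio of mean *linear* normalized
values over the paired samples, not 2^(mean log difference): the linear
form is robust to the pseudocount at low counts. Features whose paired
log differences have zero variance get p = 1 by convention and a
`degenerate` flag rather than being dropped. Swapping tumor/normal labels
inverts every fold change exactly.

"Pervasive" alteration means up- plus down-calls in at least 8 cancer
types at the gene level (5 at codon/amino-acid level, both
configurable). A cancer type is "predominantly" up- or down-regulated
when one direction outnumbers the other at least 2:1 (no canonical
cutoff exists; the ratio is a parameter).

The up/down balance test is a 1-df goodness-of-fit χ² of (n_up, n_down)
against equal proportions, no continuity correction. Note that published
enzyme-tally p-values of this style are sometimes computed from an
unstated contingency layout (e.g. 97 up vs 30 down is far more extreme
than p ≈ 0.02 under the 1-df GOF test); this package implements exactly
the definition above.

## Codon usage O/E

Expected codon frequency is the product of the three base frequencies
computed over all coding positions — *not* renormalized after excluding
stops, so the 64 expectations sum to 1. Observed codon frequencies are
over sense codons only (stops counted separately). The asymmetry is
deliberate and documented: it follows the classic base-product teaching
definition of expected usage, while observed usage is what translation
sees. TGA is treated as the selenocysteine sense codon only when
explicitly requested (`sec_tga=True`).

The up-vs-down O/E comparison runs three tests: Welch's t, the
two-sample rank-sum, and a pooled-null bootstrap of the difference in
group means with p = (1 + #{|T*| ≥ |T|})/(B + 1), B = 10,000 by default,
seed mandatory. The bootstrap's type-I error at the 0.05 level is
calibrated to [0.03, 0.07] in the test suite (500 replicates, B = 2000).

## Survival and tiers

The log-rank screen splits patients at the median expression, ties to
the low group (a convention; tertile splits can be had by pre-binning).
All-censored inputs return p = 1 with a warning; a split leaving fewer
than 2 patients in a group is an error. Cox fits are univariate partial
likelihood with Efron tie handling and Wald p; fits require ≥ 10
patients and ≥ 3 events and flag non-convergence instead of raising.
Per-feature p-values are BH-adjusted with the same routine as the DE
stage.

Expression tiers come from UPGMA (average linkage, Euclidean distance)
on per-cancer-type median log2 expression, cut into exactly k = 3
clusters (a dendrogram cut by cluster count, not height), labeled
high/medium/low by cluster median. The reported thresholds are empirical
boundaries: t_high is the smallest overall median in the high tier,
t_low the largest in the low tier; `consistent` records whether the
thresholds reproduce the assignment (they do whenever the clusters are
separable along the median axis, which is not guaranteed for UPGMA on
multi-dimensional profiles).

## CNV calls

Gain iff score > log2(3) ≈ 1.585, loss iff score < log2(1) = 0, strict
inequalities (boundary scores are neutral); NaN scores are flagged, not
called. The thresholds apply verbatim to whatever log2-scale score is
supplied; the package does not re-derive them from segmentation.

## Synthetic data: what it does and does not emulate

Counts are negative binomial with Var = μ + φμ² (φ = `dispersion`,
default 0.1, a typical bulk RNA-count overdispersion; φ → 0 gives
Poisson). Gene abundances are log-normal (default mean log2 abundance 7,
SD 2), library sizes uniform over (8×10⁵, 1.2×10⁶) reads — small-RNA-seq
scale. Planted effects multiply tumor means of all member genes of a
feature equally, so group-level truth is the abundance-weighted
consequence of gene-level effects. Annotations place ~72-nt loci with
40-nt gaps on one toy chromosome, with Zipf-like anticodon copy numbers
(some codons decoded by many genes, some by one); one iMet and one Sec
gene are guaranteed from 25 genes up. SAM output uses 30-nt reads, MAPQ
30, flag 4 for unmapped and 512 for QC-fail. Survival times are
exponential with hazard baseline_rate·exp(β·z) on standardized
expression and independent exponential censoring tuned to the requested
censored fraction (censor_rate = 1 censors every record at its drawn
time).

Not emulated: post-transcriptional modification effects on read-through,
reverse-transcription stops, multi-mapping beyond a simple overlap case,
batch effects, and non-exponential survival. Passing tests therefore
demonstrate the correctness and calibration of the statistical
machinery, not the fidelity of any particular biological claim on real
cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical checks are meaningful:
cohorts of 12–15 pairs over 60–200 features, 20 random matrices for the
TMM oracle (equality to 1e-10 against a straight-loop reimplementation),
50 matrices for count conservation (exact integer equality), 500
bootstrap replicates at B = 2000 for calibration, 100 simulations of
n = 200 patients for Cox recovery (within 2 SE in ≥ 90%), and 300
features for tier recovery (adjusted Rand index 1 on well-separated
tiers). All random draws go through one `numpy.random.default_rng(seed)`
per call; no global RNG state is touched, and identical seeds give
byte-identical artifacts.

## Known limitations

- Largest-overlap assignment undercounts isodecoders that multi-map
  heavily; counts at the codon level are more robust than at the gene
  level.
- The pseudocount of 1 CPM compresses fold changes of very low-abundance
  features toward 1; the linear fold-change definition mitigates but
  does not remove this.
- UPGMA tiers need not be separable by overall median; `consistent`
  should be checked before using the thresholds as cutoffs.
- The O/E expected model ignores dinucleotide and positional effects on
  codon composition.
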