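# Methods

## Scope and data model

meripkit analyses two-group MeRIP-seq experiments downstream of peak
calling. All genomic arithmetic uses BED conventions internally
(0-based, half-open); GTF input (1-based, closed) is converted at the
reader. Peaks are unstranded, as produced by broad-peak callers, and
strand is ignored during merging. The reference peak panel is the union
of all per-group peak calls merged at gap 0 (overlapping **and**
bookended intervals join, matching `bedtools merge -d 0`); each panel
peak records which groups contributed.

## Methylation quantification

For sample *s* and panel peak *p* of length *L_p*, with SRN the summed
per-base read depth of a library over *p* (`samtools bedcov` semantics)
and ITR the library's total read count:

    depth(p, s) = (SRN_IP/ITR_IP − SRN_input/ITR_input) / L_p

The statistic can be negative when the input fraction exceeds the IP
fraction; it is invariant to jointly rescaling a library's SRN and ITR.
"Reads of peak region" is ambiguous between read counts and summed base
depth; base depth is the default because that is what bedcov computes,
and `count_overlapping_reads` provides the read-count alternative.

Differential methylation compares the High and Low groups per peak with
a two-sample t-test on normalized depth. Welch's test is the default
(matching the default of `t.test` in R); the pooled-variance Student
variant is a flag. Significance requires raw *P* < 0.05 and
|log₂FC| > log₂ 1.5, with fold change oriented High/Low. No
multiple-testing correction is applied to peak-level tests by default —
the convention for this analysis — and a Benjamini–Hochberg option
exists. Because mean normalized depth can be non-positive, fold changes
floor each group mean at 0, add a pseudo-depth ε = 10⁻⁹, and define
log₂FC = 0 (never significant) when both means are non-positive. Peaks
whose values are identical in both groups get *P* = 1 by convention.
Genes are flagged differentially methylated when any of their peaks is
significant; the reported gene-level statistics are those of the
minimum-*P* peak.

## Expression analysis

Genes with fewer than 4 samples at ≥ 10 counts are filtered. TPM
divides counts by gene length in kb and rescales each sample to 10⁶.
Size factors are DESeq-style median-of-ratios over zero-free genes,
falling back to geometric-mean-normalized library sizes (with a
warning) when no zero-free gene exists. Differential expression is a
t-test on log₂(normalized + 1) with log₂FC defined on pseudocounted
group means and the same thresholds as the methylation test. This is a
deliberate lightweight stand-in for a negative-binomial GLM: the
analysis contract here is the thresholds, not the test engine, and the
planted-effect recovery tests characterize its operating behaviour.
The sample screen projects samples onto PCs 1–2 of gene-centred
log-expression and flags samples whose distance from the score centroid
exceeds median + 3 × 1.4826 × MAD — a reproducible analogue of the
visual PCA/heatmap outlier exclusion this protocol normally relies on.

## Transcript regions, metagene, motifs

Transcript models keep exon structure and genomic CDS bounds; the
mature transcript is partitioned into 5′UTR/CDS/3′UTR strand-aware (on
the minus strand the 5′UTR is the genomically rightmost UTR). One
transcript per gene — the longest — is used for peak assignment,
metagene profiling and sequence extraction. Peaks are labelled by the
region with maximal base overlap across overlapping transcripts, with
ties broken 3UTR > 5UTR > CDS, the priority that reflects stop-codon
biology. The metagene profile maps each peak midpoint (midpoints, not
full-width smearing, keep the estimator simple and testable) to
transcript coordinates, rescales within its region to [0, 1), and
histograms into 30 bins per region over three equal-width axes; the
density integrates to 1 over the 3-unit axis. Relative region widths on
the axis are fixed and equal — the field's figures vary here and no
single convention dominates.

RRACH scanning matches `[AG][AG]AC[ACT]` with overlapping hits on a DNA
alphabet (U→T on input, N never matches). Motif enrichment compares
observed RRACH hits per nucleotide against dinucleotide-preserving
shuffles (Altschul–Erickson Euler-trail construction, first and last
base fixed, exact dinucleotide counts preserved) with the empirical
one-sided p-value (1 + #null ≥ obs)/(1 + n_shuffles). De novo motif
discovery is out of scope; only the canonical consensus is assessed.

## Co-expression network

Expression input is log₂(TPM + 1). The unsigned adjacency is
a_ij = |cor(x_i, x_j)|^β. The soft power β is chosen from candidates
1–20 as the smallest with signed scale-free fit R² ≥ 0.85, where the
fit discretizes connectivities into 10 equal-width bins and regresses
log₁₀ p(k) on log₁₀ k̄, signed by −sign(slope). Two guards restrict
eligible powers: mean connectivity must stay ≥ 5 (over-powered networks
disconnect faster than their fit improves), and the fit slope must lie
in [−2, 0) (a scale-free degree law has slope near −1; steeper fits at
low powers reflect background correlation, not topology). If no
eligible power reaches the threshold, the conventional sample-size
default for unsigned networks applies (9 below 20 samples, 8 below 30,
7 below 40, else 6), clipped to the eligible range. At cohort sizes of
~20 samples the fit curve is noisy and these guards keep the choice in
the regime where module structure survives.

TOM similarity is (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu a_uj, unit diagonal, clipped to [0, 1]. Modules
come from average-linkage clustering of 1 − TOM with a static tree cut.
Rather than re-implement dynamic tree cutting, the cut height is chosen
adaptively: heights from 0.80 to 0.98 of the maximum merge height are
scanned and the lowest height yielding the most clusters of at least
`min_module_size` (default 30) genes is kept; smaller clusters become
unassigned ("grey", label 0). An optional refinement pass
(`refine_modules_by_kme`, applied by the pipeline) reassigns every gene
to the module whose eigengene it correlates with best when
|kME| ≥ 0.6, recovering peripheral genes the conservative cut leaves
grey. Module eigengenes are the first principal component of the
z-scored module submatrix, unit-norm, sign-oriented so the correlation
with mean module expression is non-negative. Module–trait statistics
are Pearson r with two-sided p from t = r√((n−2)/(1−r²)). Module
membership MM is the signed correlation of a gene with its module's
eigengene; gene significance GS is the absolute correlation with the
trait (the absolute convention follows the hub-table definition this
rule is used with); hubs satisfy |MM| > 0.8 and GS > 0.2 and are
reported sorted by GS. No module merging step is applied.

## Integration

Co-differential genes are the intersection of the significant DM and DE
sets, classified by fold-change signs into hyper-up / hyper-down /
hypo-up / hypo-down (zero fold changes are kept but unclassified).
Over-representation uses the upper-tail hypergeometric distribution
with the universe defaulting to the post-filter expressed gene set, and
Holm step-down correction across terms ("Bonferroni step-down" is read
as Holm 1979; single-step Bonferroni is a flag). Term networks and
redundancy reduction are out of scope.

## Synthetic data generator

The generator emulates the study design: two groups of 10 samples,
paired IP/input libraries, ~30 % of genes methylated, 20 % of
methylated sites carrying a planted |log₂FC| = 2 group effect, planted
module-trait correlations +0.62 (IMF %) and −0.51 (m⁶A/A ratio) with
opposite signs, mirroring the opposing phenotype trends of fat content
and global methylation.

Transcripts are single-exon with 5′UTR (80–300 nt), CDS (300–1500 nt)
and 3′UTR (150–800 nt) on random strands across 18 chromosomes. Each
methylated gene gets one 100-nt site whose midpoint is, with
probability 0.8, Gaussian-jittered (σ = 25 nt) around the stop codon,
else uniform; an RRACH pentamer is written at the midpoint. Counts are
negative binomial with variance μ + μ²·d (d = 0.05 by default; d = 0 is
the Poisson limit). Input means are proportional to a lognormal
gene-level rate times peak length, scaled so a library expects 10⁶
reads; IP means multiply that by 2² baseline enrichment at methylated
peaks and additionally by 2^(effect) in High-group samples at
differential peaks. Per-group peak calls jitter the planted boundaries
by ±10 nt and add 10 % spurious peaks in unmethylated genes, so merging
and Venn logic are exercised. Library totals are the column sums of the
tables they describe.

Expression modules share a standard-normal latent factor with gene
loadings U(0.6, 1); log₂ means add `scale × loading × factor` plus
N(0, 0.3) noise, and the trait-linked module's factor is shifted ±0.4
by group so the High group is "fatter". 10 % of background genes carry
a planted ±2 log₂FC group effect. Traits are built from the
analytically standardized trait-module factor so their population
correlation equals the configured value. Because the DE genes and the
group-shifted module both load on the group contrast, they genuinely
co-express — a deliberately realistic confound that the network stage
has to resolve.

What the generator does **not** emulate: read-level sequencing noise,
alignment artifacts, fragment-length effects, antibody efficiency,
multi-isoform genes, or genomically overlapping genes. Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the declared generative model, not performance on real
libraries.

## Problem sizes and numerics

Defaults run 1000 genes × 20 samples; recovery statistics average 10
replicate cohorts, and the null calibration uses 2000 peaks at 10
samples per group — sizes chosen so the full analysis and its
verification complete in well under a minute on one core. Determinism:
every generator consumes a `numpy` SeedSequence derived from the
configured seed, so identical configs produce byte-identical outputs.
Degenerate inputs are handled explicitly: zero-variance genes are
dropped before correlation networks, identical-value peaks get *P* = 1,
singular modules fall back to direct standardization in the eigengene
SVD, and an all-zero-free-gene-less count matrix falls back to
library-size factors with a warning.

## Known limitations

* The DE engine is a log-scale t-test, not a count GLM; at very low
  counts its power differs from shrinkage-based methods.
* The static-cut module detector, even with the adaptive height and
  kME refinement, can merge a trait-driven module with strongly
  group-differential background genes at low soft powers.
* Metagene profiles use equal-width region axes and midpoints only.
* ORA treats terms independently: no term-graph structure.
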