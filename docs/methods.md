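# Methods

`brainmod` reimplements, as a tested pipeline over synthetic data, the
integration of a brain gene co-expression network with rare-variant, CNV and
common-variant enrichment, polygenic scoring, and developmental expression
trajectories. This note records the models, the parameter choices, the
numerical decisions, and what the synthetic data do and do not show.

## Co-expression network

The network follows the standard WGCNA recipe. From a genes × samples
log-expression matrix, the unsigned soft adjacency is
`a_ij = |cor(x_i, x_j)|^β` with β = 6 (even, so correlation sign is
immaterial; signed networks are not implemented). The topological overlap is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{j≠i} a_ij,

computed by matrix product with a zero diagonal (equal to the cubic-loop
definition to 1e-10; the test suite checks this against an O(n³) oracle).
Genes are clustered by average-linkage hierarchical clustering of
`1 − TOM`.

**Tree cut.** The hybrid dynamic tree cut is reimplemented as a
dynamic-height variant: a static cut at `h_min + f·(h_max − h_min)` over the
dendrogram merge heights, where `f` is looked up from the deepSplit level
(0→0.95, 1→0.90, 2→0.85, 3→0.75, 4→0.65; higher deepSplit cuts deeper and
yields more, smaller branches). Branches with ≥ `min_module_size` (default
30) leaves become modules; all other genes are labelled `grey`/unassigned.
Exact label equivalence with the reference R implementation is *not* the
contract — planted-partition recovery is: the suite requires ARI = 1 on
zero-noise planted modules and ARI ≥ 0.9 at noise σ = 0.4, and the pipeline
recovers all seven planted modules (ARI = 1.0) at the default study scale.

Modules whose eigengenes have dissimilarity `1 − cor < 0.3` are merged
iteratively (largest-pair-first, eigengenes recomputed after each merge).
The module eigengene is the first right-singular vector of the per-gene
z-scored module submatrix (per-gene standardization before PCA; the source
procedure is silent on this, as it is on the sign, which we fix so the
eigengene correlates nonnegatively with the module's mean expression
profile). kME is the correlation of each gene with each eigengene.
Zero-variance genes get zero correlations with a log warning rather than
NaN propagation.

Probe-level matrices are collapsed to genes first: non-refSeq probes are
dropped; one probe passes through; of two, the higher mean wins; of three or
more, the probe with the highest whole-network connectivity wins.

Hub graphs take the `top_edges` (150) strongest within-module TOM edges,
rank nodes by degree within that edge list (ties broken by gene ID for
determinism), and flag the 50 highest-degree nodes as the hub set.
Representative regions are chosen greedily: highest-SD region first, then
repeatedly the region with the lowest maximal r² against those already
chosen.

## Gene-set enrichment

The relative risk of a set in a module is `RR = (m_k/n_k)/(M/N)`: the set's
frequency among the module's genes over its frequency in the whole network
(the set is intersected with the network universe before counting). The
statistic's p-value comes from permutation — random same-size modules — and
its standard error from bootstrap resampling of the module's genes with
replacement. Because the permutation overlap of a random same-size module is
exactly hypergeometric, the permutation null is sampled directly from that
distribution (and the multivariate analogue for the whole-partition test);
this is an exact shortcut, not an approximation. All permutation p-values
use the `(k+1)/(n+1)` estimator and can never be zero.

The whole-partition distribution test uses the chi-square statistic of the
modules × (in-set/out-of-set) table with set membership permuted over genes;
a named exact test with a permutation count is a contradiction, so the
permutation reading was implemented. Rank concentration histograms the
cell-type specificity ranks of the overlapping genes into bins and
correlates bin median rank with bin count; a perfectly flat histogram is
reported as r = 0 rather than an undefined correlation.

CNV burden replaces gene counts with base pairs to correct for gene length:
`rr_k = (C_k/L_k)/(C/L)` with `C_k` the module base pairs covered by ≥ 1
event (interval union, so duplicated or split events never double-count).

## Trio QC and TDT

QC defaults: founder MAF > 0.10, founder HWE exact p > 0.001, call rate
> 0.90, per-SNP Mendel rate < 0.10, families flagged above 0.05. The HWE
test is the standard exact conditional test (probabilities of heterozygote
configurations given the allele count, summing those no more probable than
observed; no mid-p). Mendel rates use informative trio-SNPs (all three
genotypes present) as the denominator; trios with a missing genotype are
uninformative at that SNP, with no imputation.

The TDT counts, per SNP, reference alleles transmitted (b) and untransmitted
(c) by heterozygous parents; `chi² = (b−c)²/(b+c)`, `z = sign(b−c)·√chi²`.
The reference allele is A1 — when loading PED/MAP, the lexicographically
smaller allele observed at the SNP, a deterministic rule shared with the
scoring stage so discovery and target coding cannot disagree. λ_GC is the
median chi² over 0.4549364. Note that when many SNPs share a similar
informative-transmission count, the TDT chi² lattice makes the sample median
(and hence λ) move in visible discrete steps around 1 under the null; the
calibration test uses the tolerant band [0.9, 1.1] for this reason.

## GWAS enrichment

SNPs map to strand-extended gene regions — 20 kb upstream and 10 kb
downstream of the body, mirrored for − strand genes (a strand-agnostic mode
extending both ends by the larger margin is available); coordinates are
half-open, and a SNP inside several regions counts for all of them. Each
gene keeps its minimum SNP p-value and SNP count.

The module score is a weighted KS/GSEA-style running sum over genes ranked
by `−log10(min p)`: hits step up by `w_g/Σw` (w = −log10 min p, exponent 1),
misses step down by `1/(N−N_H)`; the ES is the maximum (positive deviations
only, matching the one-sided permutation comparison), and module genes at or
before the argmax are the leading edge. An unweighted switch exists because
the source describes the score only as KS-like. Significance permutes module
membership uniformly over the genes carrying statistics — each gene keeps
its own min-p and SNP-count advantage in the null, which is what corrects
for gene size — stopping after 20 exceedances (ties count) or 100,000
permutations, with `p = (k+1)/(n+1)`.

Per-study p-values combine by Fisher's method (−2Σln p against chi² with 2k
df), which reproduces the printed combined values from the printed per-study
inputs to within their rounding; gene-wide p-values are Bonferroni over the
gene's SNP count; module-level corrections are Bonferroni over the module
count.

## Polygenic scores

Tag SNPs are chosen by greedy position-order pruning: keep a SNP iff its r²
with every previously kept SNP in a 50-SNP sliding window is ≤ 0.25 (window
size is a config; the cited procedure is pairwise over a sample, which the
greedy scan approximates). The score is `Σ_j z_j·g_ij` over tag SNPs with
discovery p < P_T — restricted, for module scopes, to SNPs in the module's
genes — with missing genotypes imputed as twice the founder reference-allele
frequency. Cases are the affected children; pseudocontrols carry the
untransmitted parental alleles (`f + m − c`), an explicit design choice
since the source does not state its case/control construction for
family-based cohorts; an external-control design can be fitted by calling
`fit_logistic` directly.

Evaluation is a logistic regression of status on the score: Wald p and
Nagelkerke R² (Cox–Snell `1 − exp((2/n)(ll₀ − ll₁))` rescaled by its
maximum `1 − exp((2/n)ll₀)`). Scores are standardized internally for
numerical stability and the slope rescaled back. A constant score returns
the degenerate null fit; separation — detected as essentially zero deviance
or an unbounded standardized slope — is flagged (`separated=True`, R²
reported at its upper bound) rather than returning a silently garbage Wald
test.

## Developmental trajectories

The compound z-score is a two-stage standardization — each array column
first (removing global array effects), then each gene row across arrays —
adopted as the natural reading of removing "global differences between
arrays and between genes"; the exact published formula is not available, so
this reconstruction is flagged, and a single-stage gene z-score can be used
instead by skipping stage one. Zero-SD rows/columns map to 0. Note one
consequence checked by the tests: because arrays are centred, modules with
no planted temporal shape acquire a small trajectory mirroring the shaped
modules, and the all-gene mean trajectory is flat by construction.

Ages are normalized to days post conception (pcw×7; months×30.44 and
years×365.25 plus a 280-day gestation). The hub trajectory is the per-age
mean (over arrays) of the mean normalized score of the module's 50 hub
genes, smoothed by a cubic smoothing spline with its penalty chosen by
generalized cross-validation (the default behaviour of the reference
`smooth.spline`). Fewer than 4 distinct ages falls back to linear
interpolation with a warning; exactly 4 uses the natural interpolating
cubic (the zero-penalty limit), since GCV needs 5 points.

## Synthetic data: what it emulates, what it does not

Each planted module k has a latent profile `f_k` drawn i.i.d. standard
normal per sample and gene g in module k has `loading_g·f_k + N(0, σ²)`,
loadings uniform on [0.6, 0.95], noise σ = 0.5 by default; background genes
are independent unit-variance noise. Samples stand for brain regions and
are exchangeable — no spatial smoothness or region-adjacency structure is
modelled, because no pipeline stage uses it. Marker sets draw each member
from the target module with probability `target_RR·n_k/N`, so the expected
RR equals the target exactly and the realised overlap is recorded. Gene
intervals are non-overlapping with log-normal lengths (median ≈ 22 kb,
near the human median) and gaps wide enough that extended regions stay
disjoint — real genomes overlap and nest, so the SNP-to-gene multiplicity
path is exercised by a dedicated fixture instead. Parents are drawn in HWE
with allele frequencies uniform on [0.15, 0.5] (so MAF QC passes unless a
test plants failures); transmission distortion applies only at SNPs inside
the enriched module's genes. GWAS p-values are U(0,1) except Beta(a,1) with
a < 1 in the enriched module; `|z| = Φ⁻¹(1−p/2)` with random sign. No LD
beyond what pruning tests construct, no ancestry structure (a single
ancestry flag per family; ancestry inference is out of scope), no
genotyping batch effects.

Consequently, passing tests show that each stage recovers the parameter it
targets under the stated statistical structure — they do not show
robustness to LD, stratification, array batch effects, or overlapping gene
models.

**Problem sizes.** The default study is 2,000 genes × 200 samples, seven
modules of 40–300 genes, 500 families × 6,000 SNPs, three simulated GWAS
cohorts, and a 17-age developmental series — large enough that every
statistic is in its asymptotic regime while the full pipeline runs in
seconds. The analysis drivers plant a per-SNP transmission distortion of
0.53: at 0.6 the ~900 distorted SNPs jointly separate cases from
pseudocontrols outright, whereas 0.53 reproduces the regime of interest
(few genome-wide-significant SNPs, modest λ_GC, module-restricted score
beating the genome-wide score, with R² growing toward liberal thresholds).
Even so, planted effects remain far stronger per SNP than real polygenic
signal; the absolute R² values are demonstration-scale, and only the
orderings are meaningful.

## Known limitations

- The tree cut is a dynamic-height approximation; pathological dendrograms
  (nested modules at very different scales) may need a different deepSplit
  than the reference implementation would.
- `λ_GC` on a panel of SNPs with nearly equal informative counts is
  lattice-valued (see above).
- The enrichment permutation treats genes as exchangeable; correlated
  gene-level statistics (LD across gene boundaries) would make it
  anti-conservative on real data.
- Block-wise computation is not implemented; matrices beyond ~30k genes
  will not fit the dense TOM path.
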