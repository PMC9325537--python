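# Methods

This note documents the statistical model, the defaults and the design
choices behind `gnorms`, in the spirit of a model-description vignette.

## Per-gene model and estimation

For each gene independently, log2-normalized expression `y` is fitted by
ordinary least squares with fixed effects

    y ~ genotype + environment + genotype:environment + batch

(the basic model; nested and architecture variants replace the genotype
factor as described in the README). The environment enters numerically
(`linear` default), optionally with a quadratic term, or as a factor. OLS on
log-scale values rather than a count GLM follows the limma-style workflow:
it keeps per-term F-tests exact, and with the handful of batch levels
typical of these designs a per-gene random-effect (REML) fit for batch is
unstable — batch is therefore a fixed effect. Precision weighting (voom) and
empirical-Bayes dispersion shrinkage are out of scope.

**Coefficients vs tests.** Coefficients are treatment-coded against a
reference genotype and a reference environment (default: the minimum
observed level maps to 0), because directions of DE and DP are defined
against that model intercept. Term significance, however, cannot depend on
which genotype happens to be the reference: tests are type-III partial
F-tests computed on a sum-to-zero (deviation) coded matrix spanning the same
column space, with the environment centered at the sample mean. The two
matrices give identical fitted values and residuals; only the meaning of
individual columns differs. Under this convention

* the **G** test targets genotype differences in expression at the average
  environment (the DE notion: "mean expression across all environments"),
* the **E** test targets the across-genotype *average* slope (a gene whose
  genotypes respond with exactly cancelling slopes is DP but not plastic
  on average),
* the **G:E** test targets slope heterogeneity among genotypes.

p-values are converted to Benjamini–Hochberg q-values across genes within
each term separately (gene lists are produced per model term, not pooled
across terms); the default FDR threshold is α = 0.05 — a convention, not a
derived quantity.

**Degenerate cases.** Constant genes are flagged and their tests reported as
NaN, never silently dropped. Noise-free (zero-residual) genes get exact term
calls: p = 0 when removing the term changes the fit, p = 1 otherwise.
Perfectly confounded architecture groupings (SNP grouping identical to SV
grouping) are detected by rank comparison and reported as aliased, with the
aliased term's tests undefined.

**Variance partition.** Per-gene fractions use sequential (type-I) sums of
squares in the fixed order G, E, G×E, B, plus residual; they sum to one by
construction for any gene with nonzero variance.

## Normalization

Size factors are DESeq-style median-of-ratios computed over zero-free
reference genes and rescaled to geometric mean 1; if no zero-free gene
exists the package falls back to total-count factors with a warning.
Normalized values are `log2(CPM + 0.5)` where CPM is the size-factor-
corrected count per mean adjusted library size, times 10⁶. The pseudocount
is applied on the CPM scale, which makes normalized values exactly invariant
to rescaling any one sample's counts; users preferring other schemes can
supply their own `NormalizedMatrix`.

## Classification

Reaction norms are read off the treatment-coded coefficients: the reference
genotype's (intercept, slope), plus offsets for the others. DE magnitude is
the difference in *mean expression over the observed environment range*
(invariant to the reference-environment choice); DP magnitude is the slope
difference (mean derivative when curvature is present). In a two-genotype
contrast, opposite equal slopes ±s give DP = 2s and same-sign slopes give
the difference of slope magnitudes.

The 12 categories are the cells of {DE yes/no} × {DP yes/no} × {mean
environmental direction up/down/none}. This grid is this package's
operationalization of the DE / plastic / DP vocabulary; no letter-for-letter
correspondence with any published panel ordering is claimed. The mean
environmental direction is the sign of the across-genotype mean slope,
reported only when (a) the E term is significant or the gene is DP, (b) a
t-test of the mean-slope contrast rejects zero at α, and (c) the mean slope
is at least 25% of the slope range across genotypes. Gate (c) is a
scale-free magnitude floor: a pure significance gate fires at rate α no
matter how small the noise, which would randomly assign directions to genes
whose genotype slopes cancel. With more than two genotypes, tabulated DE/DP
directions compare the reference genotype against the average of the
others; pairwise post-hoc contrasts are available via `compute_de_dp`.

**Evolutionary patterns.** For DP genes with a user-designated
ancestral-proxy genotype (the package never infers ancestry): *reversal* if
the two norms' total changes across the observed range exceed τ with
opposite signs; otherwise, if the derived genotype is flat (total change
< τ), *assimilation* when its mean expression matches the ancestral norm at
the derived end of the gradient (low end = ancestral, high end = derived)
and *compensation* when it matches the ancestral end. τ defaults to 25% of
the ancestral total change. Slopes are compared as total log2 change across
the range so slope and expression criteria share units. These quantitative
rules are heuristics of this package — the underlying concepts have no
published formulas — and τ should be reported alongside any result.

Reaction-norm construction and categorization operate on the basic model
only: with nested or architecture fits the genotype scale at which a norm
should be drawn is ambiguous, so users refit at the scale of interest.

## Synthetic data

The simulator emulates a factorial common-garden-gradient experiment:
G genotypes × E environment levels × R replicates, with batches cycled
across replicates within each cell (balanced when R is a multiple of the
batch count). Defaults: 3 genotypes, environments (0, 1, 2), 4 replicates,
2 batches — an 18-cell, 36-sample design.

Each gene draws a category from a configurable mixture (default: 55%
conserved, 16% plastic-only, 8% DE-only, 6% DE+plastic, 9% DP-only, 6%
DE+DP — a null-heavy mixture chosen as a plausible genome-wide composition;
nothing downstream depends on it being right). Category membership dictates
the nonzero effects, all on the log2 scale and expressed against the
reference (first) genotype:

* `effect_size_slope` (default 0.5 per environment unit) — the common slope
  of plastic genes, signed by the category direction;
* `effect_size_de` (default 1.0) — each non-reference genotype of a DE gene
  is offset by ±1.0 in mean expression, signs uniform;
* `effect_size_dp` (default 0.5) — each non-reference genotype of a
  directional DP gene has its slope offset by ±0.5, signs uniform but
  constrained so the mean slope keeps the category's direction;
  mean-direction-none DP genes instead get opposite slopes ±`effect_size_slope`
  (two genotypes; zeros pad larger designs), the classical
  crossing-reaction-norm picture with DP = 2 × slope.

Intercepts are back-computed so that genotype mean expression over the
environment grid equals baseline + DE offset, making DE and DP effects
orthogonal by construction and the truth labels reproducible exactly by the
classifier's noise-free rule.

Counts are negative binomial with `var = μ + φμ²`: baselines uniform on
log2 ∈ [2, 12], gene-wise dispersions φ log-normal (meanlog log 0.1, sdlog
0.5 — the de facto description of bulk RNA-seq overdispersion), library-size
factors log-normal (sdlog 0.2) as multiplicative offsets, and gene-shared
Gaussian batch shifts (sd 0.2 log2 units). One integer seed drives all
randomness through a single generator; identical configurations reproduce
bit-identical outputs.

**What the simulator does not emulate:** read-level artifacts (mapping,
GC/length bias), UMI or single-cell zero inflation, correlated
gene networks (genes are independent given the design), outlier samples,
and unbalanced or confounded designs. Passing tests therefore demonstrate
correctness of the estimators and classifier under the assumed generative
model, not robustness to violations of it.

## Statistical behaviour worth knowing

On the default 3×3×4 design with dispersion 0.1, the per-sample log2-scale
noise SD is ≈0.45, so a slope offset of 0.5 carries z ≈ 2.2 — moderate
power. Null calibration is excellent (per-term p-values uniform, FDR held),
slope estimates are unbiased, and category recovery is exact in the
noise-free limit; but stochastic category recovery for effect genes is
~75–80%, dominated by G:E sensitivity (~0.4 at these settings). Detecting
differential plasticity of 0.5 log2 units per environment unit at 90%+
sensitivity requires more replication, a wider gradient, or larger effects —
a power constraint of the design, not of the estimator.

## Downstream analyses

Co-expression modules use average-linkage hierarchical clustering on
1 − Pearson correlation, cut to k clusters; each module is summarized by
the first principal-component score of its genes' standardized expression
(the eigengene), sign-oriented so the mean gene loading is nonnegative.
This deliberately replaces full WGCNA (soft-thresholding, topological
overlap, dynamic tree cut): module summaries only re-enter the same
reaction-norm model, so network topology is not needed. Fitness association
is a Pearson correlation across genotype units (fitness is a property of
genotypes, not samples) with a label-permutation null,
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm); mean expression, slope, or
DP magnitude can serve as the feature.
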