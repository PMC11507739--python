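# Methods

`eqtlkit` implements a disease-tissue cis-eQTL discovery workflow — mapping
with permutation-calibrated gene-level significance, Bayesian colocalization
within and across studies and against GWAS loci, cross-study classification
of sharing and novelty, multivariate effect-size shrinkage, and downstream
comparative statistics — together with a synthetic multi-study generator
that provides ground truth for every stage. This note records the models,
the defaults and why they were chosen, the numerical choices, and what the
synthetic data does and does not emulate.

## Synthetic data (`simgen`)

**Genotypes.** Haplotypes are thresholded latent Gaussians: within an LD
block the latent correlation between variants at distance *d* is
`exp(-ld_decay * d)`; blocks are independent. Two haplotype draws per
individual are thresholded at each variant's target allele frequency and
summed, giving hard dosage calls in {0, 1, 2}. A ridge of 1e-3 is mixed
into every correlation matrix before Cholesky factorization. The *variant
panel* (positions, alleles, target frequencies) is defined once per
population seed; studies drawn from the same population share the panel and
differ only in their sampled individuals. This is deliberately not a
coalescent model: it produces the block-wise LD needed to exercise lead
selection, LD prioritization and colocalization at a small fraction of the
cost, but it has no recombination hotspots, allele-frequency/LD coupling,
or demography.

**Expression.** Per gene, a latent value is the sum of the planted genetic
term (effect per alt allele x dosage, optionally amplified per study), sex
and batch loadings, loadings on latent factors, and Gaussian noise. The
non-genetic component is standardized to unit variance per gene so that a
planted `variance_explained` is realized exactly at the latent level
regardless of how much covariate structure a gene happens to draw. Counts
are gamma-Poisson: mean `library_factor * exp(baseline + latent)` with
overdispersion 0.05 (variance `mu + 0.05 mu^2`), baseline log-means uniform
in [3.5, 6.0]. Library sizes are recorded at simulation time as the known
per-sample depth rather than recomputed from the handful of simulated
genes, whose own counts would otherwise dominate the denominator.

Latent structure defaults to **3 hidden factors with loading SD 1.0**, so
hidden variation carries roughly three quarters of the non-genetic variance
of a typical gene. This mirrors bulk-tissue practice, where latent-factor
corrections (PEER/RUV, typically 15-60 factors) absorb most expression
variance and roughly double eGene discovery; with much weaker hidden
structure the covariate-adjusted model would gain little and the factor
selection machinery would have nothing to find.

**GWAS.** Summary statistics are simulated directly in z-space: one draw
from `N(R e_c * lambda, R)` where `R` is the regularized dosage correlation
matrix of the reference panel, `e_c` the causal indicator and `lambda` the
causal non-centrality (default 12, a typical genome-wide-significant index
z-score). `beta = z / sqrt(n)` and `se = 1 / sqrt(n)`, so `z = beta / se`
exactly. No individual-level GWAS cohort exists; case-control bookkeeping
(n = 40,000, case fraction 0.5) only selects the binary-trait effect prior
in colocalization.

**Scenarios.** The catalogue (`null`, `shared-coloc`, `distinct-causal`,
`disease-unique`, `rescue`, `three-study`) plants known architectures
across three studies with default sizes 250/350/450 (a smaller disease
cohort against two larger reference cohorts). Genes sit on alternating
strands, one region per gene, regions spaced 3 Mb so cis windows never
overlap; 150 background genes on a variant-free chromosome give
normalization and control-gene selection a realistic expression matrix.
Planted variance fractions default to 10%, with two exceptions chosen for
identifiability rather than convenience: `distinct-causal` and
`disease-unique` plant 15% because calling H3/H2 (distinct signals) against
the 1e-4 per-variant prior requires the eQTL to be *independently*
detectable (lead |z| of roughly 5 or more), and `rescue` plants a 4%
disease-study signal sized to land in the suggestive range (covariate-
adjusted nominal p around 1e-4) without reaching study-wide significance
strength.

What passing tests on these fixtures do **not** show: robustness to
allele-frequency-dependent effect sizes, population structure, trans
effects, count artifacts (GC/length bias), or real LD complexity. They do
show that each statistical component is calibrated and recovers planted
truth under its stated model.

## Expression preparation (`xprep`)

Fixed order: low-expression filter (>= 5 raw reads in >= 25% of samples) →
TMM between-sample normalization → per-gene rank inverse normal transform
(RINT) for the mapping phenotype. TMM follows the trimmed-mean-of-M-values
construction: upper-quartile-nearest-to-mean reference, precision-weighted
mean of M-values after two-sided trims (30% on M, 5% on A), factors
rescaled to geometric mean 1. RINT uses `Phi^-1((rank - 0.5)/n)` with
average ranks for ties — the 0.5 offset keeps quantiles away from 0/1 and
is standard in eQTL practice; constant genes are a degenerate input and
raise.

The RUV input matrix is `log2(CPM + 1)` on TMM-normalized counts with known
covariates removed by least-squares projection. This stands in for a
variance-stabilizing transform from a differential-expression package; at
the moderate-to-high expression levels that survive the filter the two are
close, and the factor analysis only needs an approximately
variance-homogeneous log scale. Control genes are the `n_controls` smallest
coefficient-of-variation genes among the `n_top_expressed` most highly
expressed (defaults 1000 of 5000), with CV computed on the non-log scale —
log-scale means near zero make CV unstable. CV ties break toward higher
mean expression, then lexicographic id. Factors are the first k sample-side
singular vectors of the column-centered control submatrix, scaled by their
singular values; the candidate ceiling is k = 0.25 n.

**Choosing k.** Mapping is re-run over a k grid and the number of
FDR-significant genes recorded; the knee of that curve is found by the
kneedle rule: normalize both axes to [0, 1], form the difference
d = y - x, and accept a local maximum of d as the knee when the curve later
falls below `d_max - S * mean(dx)` (S = 1) before a higher maximum occurs.
The curves here are discrete with few points, so no smoothing or
interpolation is applied. Two implementation choices matter:

- The scan counts significant genes with **Benjamini-Hochberg**, not the
  Storey q-value. Under an unadjusted (confounded) model the gene-level
  p-values are positively dependent through the shared hidden factors and
  the pi0 estimate can collapse, which cascades into wildly inflated eGene
  counts and spiky curves that defeat knee detection. The final mapping
  pass, run with the chosen covariates, uses Storey as intended.
- The scan uses a reduced permutation count (default 100) per candidate k;
  the final model uses the full count.

## cis-eQTL mapping (`qtlmap`)

The cis window is TSS ± 1 Mb inclusive (TSS = start on '+', end on '-'),
with a MAF >= 0.02 filter. Phenotype and dosages are residualized against
the covariates plus intercept; slope, SE, t and p come from the simple
regression of residuals with n - c - 2 degrees of freedom, so an orthogonal
covariate leaves slopes unchanged (Frisch-Waugh). Zero-variance dosages
after residualization are skipped with a log entry; p-values are floored at
1e-300.

Gene-level significance: the covariate-residualized phenotype is permuted
(seeded) against the fixed residualized dosages; the minimum nominal p over
the window is recorded per permutation; a Beta(a, b) is fitted to the
minima by maximum likelihood (moment-estimate start, L-BFGS on log-shape
scale); the adjusted p is the fitted CDF at the observed lead p. The
mapping literature's effective-degrees-of-freedom correction to this fit is
omitted — plain MLE tracks the direct empirical permutation p with Spearman
rho > 0.99 here, which is the property that matters. Lead ties break by
smaller |TSS distance|, then smaller position.

Across genes, Storey-Tibshirani q-values: pi0(lambda) on the grid
0.05..0.95, smoothed with a cubic least-squares fit evaluated at
lambda = 0.95 (a stand-in for the reference implementation's df = 3
smoothing spline), q-values monotone via the min-over-tail recursion.
Fewer than 100 p-values falls back to BH with a warning. Storey's pi1
(1 - pi0 of replication nominal p-values) measures cross-study
replication.

Independent signals per gene: forward stage repeatedly conditions on the
accumulated leads and re-runs the permutation pass until the adjusted p
exceeds the gene-level threshold; the backward stage re-tests each retained
lead conditional on all others and drops non-significant ones; ranks follow
backward adjusted p. Leads collinear with an earlier one (r^2 > 0.95) are
dropped.

## Colocalization (`coloc`)

Per-variant evidence is Wakefield's log approximate Bayes factor,
`lABF = 0.5 [log(1 - r) + r z^2]` with `r = W / (se^2 + W)`. Prior effect
variance W: quantitative traits `(0.15 sd_Y)^2` (sd_Y = 1 after RINT);
case-control `0.2^2` on the log-odds scale — the defaults of the standard
framework. Posteriors over H0-H4 use the single-causal-variant enumeration
identities `S1 = sum exp(lABF1)`, `S2`, `S12 = sum exp(lABF1 + lABF2)`,
with unnormalized posteriors {1, p1 S1, p2 S2, p1 p2 (S1 S2 - S12),
p12 S12} under default priors p1 = p2 = 1e-4, p12 = 1e-5. All sums are
accumulated in log space (safe for lABF up to 700); the single-variant case
gives PP3 = 0 exactly by construction. Tracks are intersected on
(chromosome, position, unordered allele pair) with a beta sign flip on
ref/alt swaps; ambiguous-strand sites are kept by default since the
synthetic data is strand-consistent.

GWAS-eQTL test pairs are prioritized in two stages: a pair is tested iff
the GWAS index variant and the eQTL lead are identical or have LD r^2
strictly > 0.2 in at least one reference panel (LD computed directly from
panel dosages). The colocalization call threshold is PP4 strictly > 0.5
everywhere.

## Cross-study classification (`crosscoloc`)

Sharing of a home-study eGene from pairwise eQTL-eQTL colocalizations:
*shared* if PP4 > 0.5 against any other study; *unique* if PP3 > 0.5
against all others with data; *suggestive-unique* if PP3 > 0.5 against
exactly one; *untestable* if no other study has data. A fifth label,
*inconclusive*, covers the reachable case where other studies have data but
neither PP3 nor PP4 clears 0.5 (e.g. the other study simply has no eQTL,
H1 dominating).

Novelty of a home-study GWAS colocalization: the same gene-GWAS pair is
re-tested in every other study regardless of eQTL significance or LD
prioritization; *novel* if every other study's best hypothesis is H2 or H3,
*shared* if any is H4, *not-colocalized* if some best hypothesis is H0/H1,
*untestable* with no data. The rescue scan runs the reverse direction:
genes colocalized with GWAS only in another study are re-tested at home;
*rescued* iff PP4 > 0.5, with a secondary list of genes whose best
hypothesis is H4 at any PP4. All classifications are pure functions of the
stored posterior vectors.

## Multivariate shrinkage (`mash`)

Effects measured in three studies are modeled as
`beta_hat_j ~ N(b_j, S_j V S_j)` with `b_j` drawn from a mixture of
canonical covariance patterns (null, identity, per-study singletons,
equal-effects, heterogeneous with correlation 0.25/0.5/0.75) scaled along a
sqrt(2)-spaced grid spanning [0.5 min(se), 2 max|beta_hat|]. The noise
correlation V is estimated from random rows with max |z| < 2 and projected
to the nearest PSD correlation matrix (identity fallback below 100
qualifying rows). Mixture weights are fitted by EM on the random set; the
per-row per-component likelihood matrix is precomputed, so each iteration
only updates responsibilities and weights. Following the null-biased
convention of this estimator family, the null carries a Dirichlet
pseudo-count of 10 and the initial weights put 0.9 on the null: small-scale
signal components are nearly collinear with the null, and an unbiased EM
spreads weight across that flat direction. The recorded objective (the
penalized log-likelihood) is non-decreasing.

Posteriors for the strong set use the conjugate identities
`mean = U (U + Sigma)^-1 beta_hat`, `cov = U - U (U + Sigma)^-1 U`, which
remain valid for singular U (null, singletons, equal-effects), mixed over
component responsibilities. The local false sign rate is
`Pr(b = 0) + min{Pr(b < 0), Pr(b > 0)}` per condition, with point masses
from degenerate components handled explicitly; missing conditions are
marginalized out row-wise. Data-driven covariances (extreme deconvolution)
are intentionally out of scope: the synthetic fixtures have canonical
structure, and the canonical set is what the tests can verify.

## Downstream statistics (`enrich`)

The eVariant enrichment fold among GWAS-significant variants (p < 5e-8,
restricted to eQTL-tested variants) is
`(overlap / GWAS-tested) / (eVariants / tested)`; per-gene eVariants are
variants whose nominal p falls below the inverse of the gene's fitted beta
null at the gene-level significance boundary. Pearson chi-square tests use
the plain `sum (O - E)^2 / E` statistic with (r-1)(c-1) degrees of freedom.
Mann-Whitney comparisons use the exact distribution for tie-free groups of
<= 20 and the tie-corrected normal approximation otherwise, with BH
correction across genes. TSS-distance summaries report per-group medians of
|signed distance| with pairwise Mann-Whitney tests.

## Pipeline and problem sizes

The file-based stages (simulate → prep → map-eqtl → coloc → cross-coloc →
mash → report) communicate through a run directory of plain-text formats
(VCF 4.2 with GT+DS, BED-like phenotype tables, TSV summary statistics) and
are deterministic given the recorded seed. The packaged `three-study`
scenario used by the end-to-end run carries 8 cis genes (shared, novel,
distinct-causal, amplified, reference-only and null architectures) plus
background genes, with 60 variants per gene region. Test and acceptance
experiments use region panels of 60 variants, studies of 200-500 samples,
100-2000 genes, and 100-1000 permutations — sizes chosen so the complete
verification suite reproduces each operating characteristic (calibration,
FDR control, power, recovery and classification rates) on a single CPU
while leaving the statistical conclusions at the stated thresholds
unchanged.

## Known limitations

- Genotypes are exchangeable individuals from one population; no
  relatedness, structure or kinship models (and none are fitted).
- The beta-null fit omits the effective-degrees-of-freedom correction used
  by some mapping tools; agreement with the empirical permutation
  distribution is verified instead.
- pi0 smoothing is a cubic polynomial, not a smoothing spline; both are
  heuristic and the estimate is clipped to (1/m, 1].
- Canonical-only shrinkage cannot represent sharing patterns outside its
  dictionary (e.g. a condition-specific amplification appears as a mixture
  of equal-effects and singleton components rather than its own pattern).
- Single-causal-variant colocalization: allelic series within one gene
  violate the model for both traits; conditional mapping identifies them
  upstream but the colocalization itself is not multi-signal.
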