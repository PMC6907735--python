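# Methods

## Model and reconstruction identities

All models are ordinary least squares with an intercept:
`y = Xβ + ε`, where the design `X = [1, g, x₁, …, x_p]` holds one SNP
dosage column `g ∈ {0,1,2}` and any number of released covariates, and
the response `y = Σₕ cₕ yₕ` is a weighted combination of phenotypes.
Coefficients solve `(X′X)β̂ = X′y`; the residual variance is
`σ̂² = (y′y − β̂′X′y)/(n − p − 1)` and coefficient variances are the
diagonal of `σ̂²(X′X)⁻¹`; inference uses the two-sided t distribution
with `n − p − 1` degrees of freedom.

Every entry of the three sufficient statistics is assembled from
released summaries:

- `Σxₖ = n x̄ₖ`; `Σxₖxₗ = cov(xₖ,xₗ)(n−1) + n x̄ₖ x̄ₗ`;
- the genotype column enters through `cov(g, v) = b_{v,g} var(g)` — the
  slope of the released simple regression `v ~ g` times the genotype
  variance — which is an algebraic identity of least squares, not an
  approximation, provided `var(g)` is the *sample* variance;
- `X′y` and `y′y` expand bilinearly in the response weights over the
  released covariance matrix and variable means.

Sample covariances use the n−1 denominator throughout. This convention
is load-bearing: mixing n and n−1 denominators breaks the bit-level
agreement with subject-level OLS.

Only one genotype column per model is supported. A joint model of two
SNPs would need their genotype–genotype covariance (linkage
disequilibrium), which is not part of the assumed release.

### Exact mode vs. HWE mode

When the release carries the sample genotype mean and variance ("exact
mode"), the reconstruction reproduces raw-data OLS to machine rounding
(the test suite bounds the relative error of slopes and SEs at 1e−10
over a 500 × 1,000 cohort sweep; observed errors are ~1e−14). When only
an allele frequency p is available, genotype moments fall back to the
Hardy–Weinberg values 2p and 2p(1−p); on finite samples this is
approximate even when genotypes are drawn under HWE, and fits are
logged as such. Allele frequencies above 0.5 are accepted with a
warning, since releases differ on minor/effect-allele orientation and
the moments depend only on the stored allele's frequency.

## Centering, standardization, principal components

Shifting a response by μ changes only the intercept (down by μ);
rescaling by σ divides all coefficients and standard errors by σ and the
residual variance by σ². The standard-error scale was adjudicated
against a subject-level oracle: regressing `(y−μ)/σ` directly reproduces
SE/σ, not SE/σ² — the implementation follows the oracle (the σ² variant
circulating in print is dimensionally inconsistent, consistent with a
typesetting artifact of √σ²).

The j-th PC score of centered phenotypes is the combination with
weights given by the j-th eigenvector of their covariance matrix, so
PC-score GWAS is the combined-response reconstruction with weights φⱼ
and all response means set to zero (covariances and slopes are
shift-invariant, so centering costs nothing). Under `scaled=True` the
correlation matrix is decomposed instead and the raw-phenotype weights
are φⱼₕ/σₕ.

Numerical conventions, chosen for byte-stable output:

- eigenvector sign: each column is flipped so its largest-absolute
  entry is positive, ties broken at the lowest index;
- equal eigenvalues are ordered by the variable index of the dominant
  loading; components are 1-based (PC1 = largest eigenvalue);
- the normal equations are solved by Cholesky factorization with a
  condition-number guard at 1e12 rather than the explicit inverse;
- residual variances in `(−1e−10·y′y, 0)` are clipped to zero (rounded
  release values can make y′y marginally inconsistent); larger negatives
  raise an error, since they indicate a self-contradictory panel.

## Covariance estimation from slope correlations

When the covariance matrix is not released, the off-diagonal entries
are estimated as `cor(bₕ, bⱼ)·√(var(yₕ)var(yⱼ))` with Pearson
correlation of the slope vectors across SNPs, and the released variances
on the diagonal. The rationale: for a null SNP the two slopes are pure
sampling noise whose correlation equals the correlation of the
variables themselves. Truly associated SNPs bias the estimate; the
estimator exposes an optional simple-regression |t| cutoff to exclude
them and reports how many SNPs were used. The estimate need not be
positive semidefinite; an eigenvalue-clipping repair (floor at
1e−10 × largest eigenvalue, diagonal rescaled back to the input
variances) is applied automatically before PCA and opt-in elsewhere.

Covariates are treated as variables like any other: they have released
slopes against every SNP, so their covariances (with each other and
with the phenotypes) are estimated the same way. This matters because
single-phenotype *slopes* are only affected by covariance errors
through the covariate blocks.

## Synthetic cohort generator

The generator emulates a small biobank: M SNP dosages drawn
Binomial(2, p) at allele frequencies p ~ Beta(2, 8) truncated to
[0.01, 0.5] (HWE holds by construction), age ~ Poisson(50),
sex ~ Bernoulli(0.5), and three unit-variance phenotypes driven
linearly by the first 10 SNPs, age and sex with jointly Gaussian
residuals. Effect sizes (per-allele effects of 0.05–0.10 on the causal
SNPs, 0.015–0.03 per year of age, 0.2–0.4 for sex) and the residual
covariance were fixed once, by solving for the residual covariance that
makes the total phenotype correlations hit 0.30 (y1,y2), −0.08 (y1,y3)
and 0.07 (y2,y3) in expectation; the implied heritability of ~2–3%
spread over 10 variants is in the realistic range for a small causal
panel. All parameters are overridable.

Desk-scale defaults are 2,000 subjects × 2,000 SNPs × 20 replicates;
`SimConfig.cluster_scale()` switches to 100,000 SNPs × 1,000 replicates
for cluster use. Seeds flow through `numpy.random.SeedSequence`, with
one spawned child per replicate, so any replicate is reproducible
independently.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: deviations from HWE, genotyping
error and missingness (each subject is complete-case), relatedness and
population structure, and linkage disequilibrium (SNPs are independent,
which flatters the slope-correlation covariance estimate: correlated
null SNPs contribute less independent information than S independent
ones). The exactness results are unaffected by these features — the
reconstruction identities are algebraic — but the size of
estimated-covariance errors on real releases can differ.

## Validation design

`simulate.validate` sweeps replicate cohorts: each is summarized,
optionally re-covarianced with the slope-correlation estimate, and every
analysis (a fixed-weight combination or a PC component, whose weights
are derived per replicate from that replicate's covariance source) is
fitted per SNP both from summaries and by direct OLS on the raw data.
Per-SNP errors (summary minus oracle) of the SNP slope, its SE and
−log10 p are aggregated as the mean across SNPs and the variance of the
per-SNP error within one genome (the intra-genomic variance), then
summarized across replicates by mean and max. The per-SNP table is
retained so the aggregates are recomputable.

−log10 p differences are computed on the log-survival scale of the t
distribution, so they remain meaningful far beyond where the p-value
itself underflows.

The error of the estimated-covariance approximation is a population
quantity with heavy genome-to-genome spread (observed 0.3%–6% of the
mean SE across single genomes at 2,000 SNPs, population mean ≈ 3%); the
test suite and acceptance script therefore measure it pooled across six
replicate genomes rather than from a single draw. Accuracy improves
with the number of SNPs entering the slope correlation, roughly as
1/√S; the suite checks monotonicity over S ∈ {500, 2,000, 10,000} with
fits on a fixed 300-SNP subset.

## Known limitations

- One shared sample size per panel (complete-case); heterogeneous
  per-SNP n is accepted in the schema but a model uses the minimum n of
  its inputs and warns.
- No weighted or robust variants; no multiple-SNP joint models; no
  mixed-model/kinship adjustment.
- The slope-correlation covariance fallback degrades when a large fraction of
  SNPs are truly associated; the |t|-cutoff flag mitigates but the
  package does not bound this error a priori.
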