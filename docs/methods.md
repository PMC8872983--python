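# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Synthetic data (`psychgen.simulate`)

**Item responses.** Abilities are standard normal. Accuracy follows the
3PL form c + (1−c)·logistic(a(θ−b)) (c = 0 for 2PL items). Chosen options
assume four response options per item: a correct answer selects the item
key, an incorrect one a uniformly random distractor. Response times are
lognormal around an item-specific median (40% of the item's presentation
limit, capped at 12 s; log-SD 0.4) and truncated at the limit. Items are
presented for 20–40 s by default. The response-time model is the simplest
one that supports a mean-RT-based exclusion rule; it is not fit to any
empirical RT distribution.

Planted careless responders ("clickers") come in three types: *uniform*
(one fixed option throughout, normal speed), *rapid* (random options at
10% of the typical median RT), and *random* (random options, normal
speed). Attentive subjects pass each quality-control (QC) item with
probability 0.98 — a declared default, not an empirical estimate; random
and rapid clickers answer QC items at the 1-in-4 chance level.

**Twin pairs.** Pairs are drawn from the model-implied (multivariate)
normal: unit trait variances, cross-twin covariance a²+c² (MZ) or
½a²+c² (DZ). Bivariate specs use cross-trait blocks rX·√(x²₁x²₂) for
X ∈ {A,C,E}. Sex composition defaults to an even MZ split and ¼/¼/½
DZm/DZf/DZos. Qualitative sex effects enter as a multiplier rg_os on the
opposite-sex DZ cross-twin genetic covariance; quantitative effects as
per-sex (a²,c²,e²). Non-positive-definite implied covariances are an
error, not silently repaired.

**Genotypes.** Dosages are Binomial(2, p) with p uniform on a configurable
MAF window (default 0.05–0.5 for heritability studies). Optional LD uses a
within-block AR(1) Gaussian copula per haplotype, thresholded at Φ⁻¹(p);
blocks are independent, which matches the windowed LD solver downstream.
Per-SNP effects are N(0, h²/M) on the standardized-genotype scale; the
phenotype adds N(0, 1−h²) noise. There is no population structure,
assortative mating, realistic MAF spectrum, or X chromosome — so passing
recovery tests demonstrates correctness of the estimators under their own
assumptions, not robustness to the confounders real cohorts face.

**Summary statistics.** Marginal estimates are β̂ = Rβ + ε with
ε ~ N(0, R/N) (R = I without LD). This is the large-sample sampling model
for standardized marginal regression; it ignores case-control ascertainment
and uneven per-SNP N.

## IRT (`psychgen.irt`)

Marginal ML via EM. E-step: posterior weights over 61 Gauss-Hermite nodes
(probabilists' rule rescaled to N(0,1)). M-step: per-item safeguarded
Newton updates in the slope/intercept parameterization P = expit(aθ + d)
with step-halving on the expected complete-data objective, which keeps
the observed-data log likelihood monotone (asserted in tests). Slopes are
bounded at |a| ≤ 6 and intercepts at |d| ≤ 40: unbounded MML slopes
diverge on small samples (quasi-Heywood items), and a slope of 6 is
already a near-Guttman item. Difficulty is reported as b = −d/a (NaN when
â ≈ 0, where b is unidentified). Convergence: max parameter change
< 1e−5, up to 2,000 iterations. The 1PL shares one slope across items;
the 3PL adds a guessing asymptote with a Beta(2,10) stabilizing prior
(3PL MML is ill-posed without one). Standard errors come from the
expected-count information of the final M-step, a block-diagonal
approximation that ignores cross-item coupling.

**Reduction.** Stage 1 removes items whose peak grid information
(θ ∈ [−4,4], 81 points) is below `flat_epsilon` = 0.02 ("completely
flat"). Stage 2 removes survivors with peak information < 0.2 or
|b̂| > 3 (too hard/easy for a N(0,1) population). Stage 3, applied to the
verbal domain by default, removes flat-characteristic-curve items (ICC
rise < 0.1 over the grid), then redundant items (sup-norm ICC distance
< 0.02 to an earlier item; removal proceeds from the end of the list so
the first-listed item of a duplicate cluster is retained), then the least
informative items, stopping as soon as the 20-per-domain quota is met.
The numeric thresholds for "flat", "out of range" and "identical" are
declared defaults exposed in `ReductionConfig`, not reconstructions of
any particular analysis. The procedure is idempotent and the report
partitions the bank.

## Psychometrics (`psychgen.psych`)

Adjustment is OLS residualization on sex, age and screen size (two
dummies), z-scored — residuals are exactly orthogonal to the design.
Composites require all components (subjects missing any component get a
missing composite). Cronbach's alpha uses the covariance-matrix formula;
hierarchical omega is (Σλ)²/(（Σλ)² + Σψ) from the one-factor fit. The
one-factor CFA minimizes the normal-theory ML discrepancy; CFI/TLI are
computed against the independence baseline, SRMR over correlation
residuals; Heywood cases are reported, not truncated; factor scores use
the regression method (which correlates > 0.98 with the first PC on
unidimensional data). Parallel analysis permutes each column
independently (500 reps, 95th percentile); adjusted eigenvalues are
observed − null mean + 1.

**Careless-responder screening.** Flag when any of: ≥ 2 of 5 QC items
wrong; mean RT < 20% of the cohort median; a run of ≥ 15 identical chosen
options; or a raw score below half the cohort median *with* a
corroborating soft indicator (≥ 1 QC miss, rapid, or uniform). Two
deliberate choices here: (i) the low-score cut is anchored to the median
rather than a low quantile because a cluster of careless respondents can
drag a 2–5% quantile below itself, and (ii) corroboration uses soft
indicators because requiring a *hard* indicator would make the low-score
rule redundant (the hard indicator already flags). On planted clickers
this yields sensitivity ≥ 95% with a false-positive rate < 2%.

## Twin models (`psychgen.twin`)

Traits are standardized on the grand mean/SD of all twin values and means
are fixed at zero; paths (a, c, e) are estimated by ML (L-BFGS-B, bounds
[0, 2], five jittered starts) and standardized components are the squared
paths over their sum, so negative variance components cannot occur
(boundary solutions are flagged). The saturated reference frees each
group's 2×2 covariance with means fixed at zero (df vs ACE = 3); χ² is
the −2LL difference. Profile-likelihood 95% CIs invert the χ²(1) = 3.84
threshold on each standardized component (inner 2-parameter
re-optimization, bisection on the component); percentile bootstrap over
pairs is available as an alternative. The bivariate model is
Cholesky-parameterized (guaranteeing PSD component matrices); the
phenotypic cross-trait correlation decomposes exactly as
r_p = A₁₂/√(V₁V₂) + C₁₂/√(V₁V₂) + E₁₂/√(V₁V₂). Sex-limitation fits the
nested sequence full (sex-specific paths + free rg_os ∈ [0,1]) →
rg_os = 1 → equal paths, with χ² df 1 and 3. Unpaired twins are not
currently modelled (pairs only); the generators produce complete pairs.

## Genomics (`psychgen.pgs`)

The GRM uses sample allele frequencies and the standard
allele-frequency-standardized cross-product averaged over SNPs with
MAF > 0.01. Pruning is greedy: repeatedly drop the individual in the most
over-threshold (default 0.05) pairs, first id on ties — no retained pair
exceeds the threshold (asserted exhaustively in tests); optimal vertex
cover is not attempted. REML is average-information with EM fallback
steps and step-halving, computed in the GRM eigenbasis so each iteration
is O(n) after one eigendecomposition; on very small fixtures where AI
steps stall, a bounded direct search of the restricted likelihood
polishes the solution. SE(ĥ²) is delta-method from the inverse AI matrix.
The incomplete-tagging adjustment used by some GRM pipelines (grm-adj 0)
is documented but not implemented: in these simulations causal and
genotyped SNPs coincide, making it a no-op by construction.

LDpred-infinitesimal weights solve (M/(Nh²)I + D)β̃ = β̂ in 100-SNP
windows with 50-SNP overlap (overlapping solutions averaged); D is the
sample correlation matrix of the target-panel dosages (empirical SDs, so
D is exactly a correlation matrix and the D = I closed form
β̂/(1 + M/(Nh²)) is exact for orthogonal panels). The fraction of causal
markers is fixed at 1. Incremental R² standardizes phenotype, scores and
covariates, and is non-negative by nesting. Multi-score combination fits
joint OLS weights on a 50/50 training split and evaluates the combined
score in the holdout; near-collinear score sets fall back to a small
ridge penalty with a warning.

## Reference simulation studies (`psychgen.benchmarks`)

Problem sizes follow the original cohort design: 639 MZ + 777 DZ pairs
(20 replicates per composite), n = 1,365 with M = 5,000 independent SNPs
for GREML (20 replicates), a GWAS of N = 2,591 on M = 2,000 markers
scored in a disjoint holdout of 1,365 (20 replicates; expected
R² = h⁴N/(h²N+M) ≈ 0.12 at h² = 0.37), a 138-item bank with 37 planted
zero-discrimination items calibrated on 144 subjects (stage-1 removals
majority-voted over 10 seeds, because single calibrations at n = 144 are
noisy), the structured 138-item bank at n = 2,000, and five
equicorrelated (ρ = 0.40) test scores at n = 4,545. These sizes keep the
whole battery of studies to about a minute on one CPU.

## Known limitations

- The generators produce complete, balanced data; missing-data handling
  is limited to item-level missingness in IRT and mean imputation of
  missing genotypes on read.
- IRT standard errors are block-diagonal approximations.
- The sex-limitation model is univariate and assumes the five-group
  design; ADE models, extended pedigrees and longitudinal models are out
  of scope, as are non-infinitesimal polygenic priors, imputation, and
  population-structure estimation.
- Synthetic recovery shows estimator correctness under the generating
  model, not robustness to ascertainment, stratification, measurement
  non-invariance, or other features of real cohort data.
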