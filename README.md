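# psychgen

Simulation-backed pipeline for building a short cognitive test battery and
analysing its genetics: item-response-theory (IRT) calibration and
information-based test shortening, psychometric validation, classical twin
ACE variance decomposition, GREML SNP heritability, and
infinitesimal-prior polygenic scores.

## Who this is for

Behaviour-genetics and psychometrics researchers who want a transparent,
tested re-implementation of the analysis chain used to construct and
validate gamified measures of general cognitive ability (*g*) — from raw
item responses down to DNA-based prediction — together with synthetic-data
generators that make every estimator checkable against planted truth.

## The models

**2PL IRT.** The probability that subject *i* answers item *j* correctly is
P(θᵢ) = 1/(1+exp(−aⱼ(θᵢ−bⱼ))) with discrimination aⱼ and difficulty bⱼ,
θ ~ N(0,1). Calibration is marginal maximum likelihood via EM with
Gauss-Hermite quadrature. Item information is I(θ) = a²P(1−P); shortening
removes items with flat information curves, items never reaching an
information threshold of 0.2 or with |b̂| > 3, and (within the verbal
domain) redundant or minimally informative items down to a 20-per-domain
quota.

**Twin ACE model.** For a standardized trait, MZ pairs have expected
cross-twin covariance a²+c² and DZ pairs ½a²+c², where a², c², e² are the
additive-genetic, shared-environment and nonshared-environment variance
fractions. Falconer's approximation gives a² = 2(r_MZ − r_DZ); full ML
fitting adds likelihood-ratio comparisons against the saturated model,
profile-likelihood CIs, bivariate Cholesky decomposition of cross-trait
correlations (rA, rC, rE), and five-group sex-limitation tests.

**GREML.** y = g + e with Var(y) = σ²g·A + σ²e·I, where A is the GCTA-style
genetic relationship matrix A_jk = (1/M) Σᵢ (x_ij−2pᵢ)(x_ik−2pᵢ)/(2pᵢ(1−pᵢ)).
Variance components are estimated by AI-REML after greedy pruning of pairs
with relatedness > 0.05; SNP heritability is ĥ² = σ̂²g/(σ̂²g+σ̂²e).

**Polygenic scores.** Infinitesimal-prior posterior-mean weights
β̃ = (M/(Nh²)·I + D)⁻¹ β̂ per LD window (D = local LD from the target
panel), scored as GPSⱼ = Σᵢ dosage_ij·β̃ᵢ and evaluated as incremental
R² = R²(covariates+GPS) − R²(covariates).

## Worked example

```python
from psychgen.simulate import AceSpec, gen_twin_data
from psychgen.twin import twin_correlations, falconer, fit_ace

spec = AceSpec(a2=0.57, c2=0.08, e2=0.35)      # planted truth
data = gen_twin_data(spec, n_mz=639, n_dz=777, seed=1)

corr = twin_correlations(data, n_boot=200, seed=1)
print(corr[["n_pairs", "r"]])
fit = fit_ace(data, seed=1)
print(f"a2={fit.a2:.3f} c2={fit.c2:.3f} e2={fit.e2:.3f}")
print("95% CI for a2:", tuple(round(v, 3) for v in fit.ci["a2"]))
```

Output:

```
       n_pairs         r
group
MZ         639  0.617189
DZ         777  0.375320
a2=0.506 c2=0.119 e2=0.375
95% CI for a2: (0.369, 0.646)
```

The MZ correlation (0.62) is well above the DZ correlation (0.38), the
classic signature of substantial heritability; the ML fit recovers the
planted decomposition (0.57/0.08/0.35) within sampling error at this
sample size, and the profile-likelihood CI covers the truth.

The full pipeline — simulate, screen careless responders, calibrate,
shorten, validate, twin-model, GRM/GREML, polygenic scoring — runs from a
YAML config:

```bash
psychgen run config.yaml        # or: psychgen greml config.yaml, etc.
```

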