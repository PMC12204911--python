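# Methods

## The biometric twin model

A trait measured on twin pairs is modelled as the sum of four latent
sources: additive genetic effects (A), non-additive genetic effects (D:
dominance or epistasis), shared environment (C) and unique environment
(E, which absorbs measurement error).  The total variance is
V_A + V_D + V_C + V_E.  MZ co-twins correlate 1 on A and D and share C;
DZ co-twins correlate 0.5 on A and 0.25 on D, giving

    r_MZ = (V_A + V_D + V_C) / V_Total
    r_DZ = (0.5 V_A + 0.25 V_D + V_C) / V_Total

C and D cannot be estimated together from twin data (two observed
correlations, three structural parameters), so the fitted families are
ACE, ADE and the nested AE, CE and E reductions.  A saturated model with
free zygosity-specific intercepts, variances and correlations (covariate
slopes shared) is the fit-quality baseline.

### Continuous traits

Each complete pair contributes a bivariate normal log-density with means
from a linear sex/age/height model (sex coded female = 0, male = 1; age
in years; height in cm), a common variance, and the model-implied
correlation for its zygosity.  Unpaired subjects can contribute
univariate terms (off by default; the choice only sharpens the mean and
scale, not the fractions).  The variance structure is parameterized by
unconstrained path coefficients whose squares are the variance
contributions: fractions are automatically nonnegative, sum to one, and
boundary solutions (a component estimated at exactly zero) are reachable.
Covariates are standardized internally for optimizer conditioning and
coefficients reported on the original scale.

Optimization is quasi-Newton (L-BFGS-B, gradient tolerance 1e-8) from a
moment-based start (OLS residual variance and raw MZ/DZ residual
correlations) plus random restarts (default 5) with a seed derived from
the run seed; non-convergence after all restarts is flagged on the fit,
never silent.

### Binary traits

A binary outcome is the indicator that a standard normal latent liability
exceeds a threshold.  Covariates shift the threshold linearly on the
probit scale; the total liability variance is fixed at 1 for
identification, so components are fractions directly and heritability is
the fitted a².  Each pair contributes the probability of its observed
concordance cell, a rectangle probability of the standard bivariate
normal with the model-implied liability correlation.  Because the unit
variance removes the scale parameter, the liability fractions use a
minimal trigonometric parameterization (a² = sin²u, next component =
(1−a²)·sin²v) rather than redundant squared paths — boundaries remain
reachable and the information matrix stays non-singular for delta-method
intervals.  Opposite-sex DZ pairs are excluded by default (twin
correlations for binary traits are conventionally reported for same-sex
pairs); a flag includes them with shared thresholds.  Pairs with one
member missing the trait are dropped: thresholds with covariates are
weakly identified from singletons.

Bivariate normal rectangle probabilities are computed from Owen's T
function (scipy.special.owens_t) via the standard identity
Φ₂(h,k,ρ) = (Φ(h)+Φ(k))/2 − T(h,a_h) − T(k,a_k) − β.  The route is fully
vectorized; near-zero margins are nudged by 1e-10 to keep the Owen
arguments finite, and the absolute error stays far below the 1e-7
contract (the orthant identity Φ₂ = 1/4 + asin(ρ)/2π is verified to
~1e-12 in the tests).

### Tetrachoric correlations

The 2×2 concordance table model (two thresholds + correlation) is
just-identified, so the multinomial MLE reproduces the margins exactly:
thresholds are inverse-normal margin proportions and ρ solves
Φ₂(t₁,t₂,ρ) = n₀₀/n (Brent's method).  Confidence intervals are
profile-likelihood (thresholds re-optimized at each fixed ρ).  Tests
verify the estimate against a brute-force grid search over (ρ, t₁, t₂)
that uses scipy's multivariate normal CDF, an implementation-independent
route.

### Model selection

The full family (ACE vs ADE) is chosen by AIC (2k − 2 log L, k = free
parameters actually estimated).  AE and CE are tested against the chosen
full model by likelihood-ratio tests; nested candidates with p ≥ α are
admissible and the lowest-AIC admissible candidate is reported (ties:
fewer parameters, then AIC, then label order); if both are rejected the
full model is reported.  α = 0.05.  Dropping a variance component is a
boundary hypothesis; the default is the conventional plain χ²(1)
reference, with a 50:50 χ²(0):χ²(1) mixture available as an option
(`boundary_mixture`), which simply halves positive-statistic p-values and
is conservative-to-exact for this case.  Report tables round components
and correlations half-up to 2 decimals and AIC to 1, and print the LRT
p-value only for the selected model.

The absolute degrees of freedom of an external saturated-model
parameterization are not reproducible without knowing its exact group
structure; AIC comparisons here are internally consistent and that is all
selection requires.

### Confidence intervals

Three methods for the variance fractions and implied correlations:
delta (inverse observed information via central finite differences,
truncated to [0,1]; one-sided from 0 at a boundary estimate), profile
(inverting the LRT at the χ²(1) 95% point, with the constrained fraction
enforced by substituting the corresponding path), and bootstrap
(resampling pairs within zygosity, percentile intervals).  A coverage
simulation in the acceptance suite checks the delta intervals cover a
true a² of 0.6 between 90% and 99% of the time at nominal 95%.

## The synthetic cohort generator

The generator draws twin pairs whose latent components have the design
cross-twin correlations (A: 1/0.5, D: 1/0.25, C: shared, E: independent),
shared within-pair age (uniform 40–80 y), sex (48% male; opposite-sex DZ
pairs get one member of each sex) and sex-specific heights
(female N(165.9, 6.1²), male N(179.3, 6.6²) cm).  Continuous traits add a
linear mean model and scale; binary traits threshold a unit-variance
liability at the target prevalence, with probit covariate effects and the
base threshold inflated by √(1 + var(covariate shift)) so the marginal
prevalence stays on target.  All draws come from one seeded generator in
a fixed vectorized order, so a (config, seed) pair reproduces a cohort
byte-for-byte.

The survey-mimicking preset produces 12,449 subjects: 2,000 MZ + 2,600
same-sex DZ + 1,600 opposite-sex DZ pairs plus 49 singletons (the
source survey's zygosity split is unpublished; these counts are declared
assumptions and overridable).  Marginals follow the published table:
smoking 20/38/42 current/former/never, BMI N(26.6, 4.4²), pack-years
gamma-distributed with mean 19.2/SD 18 among ever-smokers, z-score traits
with the reported means/SDs and generating heritabilities set to the
reported AE estimates (FEV₁ 0.64, FVC 0.61, ratio 0.50, chronic
bronchitis 0.48 on the liability scale at 3.7% prevalence).  Asthma is
assigned as an exact 991-subject random subset so the exclusion funnel
(12,449 → 11,458) is reproducible to the subject.  Respiratory symptom
flags derive from a latent with a weak link (ρ = 0.10) to low FEV₁/FVC,
calibrated once so clinical COPD lands near 2.5% after the asthma
exclusion; the raw ratio is an affine map of its z-score
(0.76 + 0.0445·z), putting fixed-ratio obstruction near 18%.

What the generator does *not* emulate: non-normal trait distributions,
age-dependent variance components, sex-limitation effects,
gene–environment interaction (smoking-stratified fits are exercised by
stratified model fitting, not by an interaction mechanism), item-level
questionnaire error, and informative missingness.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation in real
registry data.

## Numerical choices and degenerate inputs

- Strict `<` cutoffs for all case definitions; boundary values are
  non-cases.  Missing questionnaire flags count as "no" and are tallied
  in a missingness report so the choice is auditable.
- Trait prevalence 0 or 1, an empty concordance margin, >2 subjects per
  pair id, and a collinear design matrix are hard errors with specific
  messages.
- ρ is clipped to 1 − 1e-9 inside likelihoods; cell probabilities are
  floored at 1e-300 before logging.
- CSV output uses `%.17g` and input cells are re-parsed with Python's
  correctly-rounded `float()`, so write → read round-trips are exact.
- Ties in model selection resolve deterministically (parameters, AIC,
  label order) and the full candidate audit is always retained.

## Problem sizes used in the test and acceptance runs

Parameter-recovery studies use 40 replicate cohorts of 1,500 + 1,500
pairs (continuous) and 2,000 + 2,000 same-sex pairs at 3.7% prevalence
(liability); the coverage simulation uses 200 cohorts of 150 + 150 pairs;
selection-consistency checks use 3,000-pair cohorts over 9 seeds and
1,500-pair cohorts over 50 seeds.  At the liability study size the ML
heritability estimate is noticeably dispersed (SD ≈ 7 points per
replicate) with a small negative small-sample bias (~2 points, vanishing
by 8,000 + 8,000 pairs); the mean across replicates is the reported
quantity, and 40 replicates keep its Monte-Carlo error near one point.

## Known limitations

- Univariate traits only: no cross-trait genetic covariance, no
  sex-limitation models, no extended pedigrees.
- No ascertainment or censoring correction (population-based sampling is
  assumed).
- Liability fits exclude singletons by design.
- The internal sex/age/height standardization is a stand-in for external
  spirometric reference equations and accepts externally supplied
  z-scores whenever they exist.
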