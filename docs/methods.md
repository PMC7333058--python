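# Methods

This note documents the statistical model the package implements, the
numerical choices behind it, what the synthetic-cohort generator does
and does not emulate, and the sizes at which the test suite exercises
everything.

## Model

### Longitudinal submodel

Log-transformed blood glucose for woman *i* at gestational day
*t<sub>ij</sub>* (window 50–260) is a linear mixed model

y<sub>ij</sub> = β₀ + Σ<sub>r</sub> β<sub>r</sub> λ<sub>r</sub>(t<sub>ij</sub>) +
β<sub>age</sub> z<sub>age,i</sub> + β<sub>onset</sub> z<sub>onset,i</sub> +
b<sub>i0</sub> + Σ<sub>r</sub> b<sub>ir</sub> λ<sub>r</sub>(t<sub>ij</sub>) + ε<sub>ij</sub>

* λ<sub>r</sub> — natural cubic spline basis of gestational day,
  *excluding* the intercept (carried separately). With *m* interior
  knots the basis has *m*+1 functions; knots default to empirical
  quantiles of the pooled reading days, boundary knots at days 50/260.
* The basis is assembled from cubic B-splines with the two
  natural (zero boundary curvature) constraints applied in coefficient
  space, orthogonally to the constant function. Compact support keeps
  the design well conditioned at large knot counts (condition number ~20
  at 22 interior knots vs ~10⁹ for the truncated-power form), which is
  what makes per-coefficient random-effect variances identifiable.
  Beyond the boundary knots every basis function continues linearly, so
  the mild extrapolation needed by dynamic prediction is stable.
  Derivatives and antiderivatives are exact (B-spline calculus), with
  the linear tails integrated in closed form.
* Random effects b<sub>i</sub> = (b<sub>i0</sub>, …, b<sub>im+1</sub>)
  are mutually independent, one variance per effect (diagonal
  covariance). An unstructured covariance is deliberately out of scope.
* Ages are standardized with fixed reference constants
  (mean 26.9/SD 6.7 years at last menstrual period; 12.4/6.6 at
  diabetes onset), so age coefficients are per reference-SD. Raw
  per-year coefficients on a log-glucose scale would be tiny and poorly
  scaled for sampling.

A maximum-likelihood variant (random effects integrated analytically;
Woodbury identity per woman; L-BFGS-B over log-SDs with the fixed
effects profiled by GLS) provides BIC for knot-count selection and
starting values for MCMC. It is never the headline inference. SDs are
bounded below at e⁻⁴ ≈ 0.018 during optimisation; components that small
are numerically zero on this scale.

### Event submodel

Delivery time on the analysis scale t = day − 50 follows a Weibull
proportional-hazards model

h<sub>i</sub>(t) = (l/s)(t/s)<sup>l−1</sup>
exp(φ₀ + φ<sub>neph</sub> neph<sub>i</sub> + A<sub>i</sub>(t)),  s = 210

with association term A<sub>i</sub>(t) linking the latent trajectory:
current value (α·m<sub>i</sub>), value plus slope
(α₁·m<sub>i</sub> + α₂·m<sub>i</sub>′), or cumulative AUC
(α·∫₅₀<sup>day</sup> m<sub>i</sub>). The AUC integrates from day 50 (the
window origin) rather than conception: no glucose process exists before
day 50, and the difference is a constant absorbed by φ₀.

The reference scale s = 210 days (the window span) is a pure
reparametrisation making φ₀ O(1); with s = 1 the bare
`l t^{l−1} e^{φ'Ω+αm}` form is recovered. This matters because term
delivery is sharply timed — Weibull shapes around 40–50 — so the
unscaled intercept would sit near −l·log 210 ≈ −230, incompatible with
any weakly informative prior.

Every woman delivers (no censoring), so the likelihood is the full event
density log h(T) − H(T). The cumulative hazard is computed by
fixed-order **Gauss–Jacobi** quadrature (15 nodes, weight x^{l−1} on the
rescaled interval): the Weibull kernel is absorbed into the quadrature
weight exactly for any shape, so the α = 0 and constant-trajectory cases
reduce to the closed-form Weibull to machine precision, and
exp-of-spline association terms converge spectrally (refinement from 15
to 30 nodes moves H by < 10⁻⁶ relative in the study regime). Nodes and
weights are cached per shape. All hazard arithmetic is in log space.

### Priors (explicit, configurable)

Normal(0, 10²) on fixed effects, φ, and α; half-Normal(0, 5²) on all
SDs; Gamma(1, 0.02) on the Weibull shape — i.e. exponential with
mean 50. The rate matters: (shape, φ₀, α) sit on a flat curved
likelihood ridge, and a Gamma rate of 0.1 (mean 10) is informative
enough at the realistic scale of the shape (tens) to slide the posterior
several units down that ridge, visibly biasing α toward zero. Proposals
above shape 400 are rejected outright (prior mass there is ~e⁻⁸ and the
quadrature tables stop being worth building).

### Sampler

Blocked Metropolis-within-Gibbs, all in NumPy:

1. **Random effects** — all women in parallel, independence-MH from the
   exact Gaussian conditional implied by the longitudinal likelihood and
   the RE prior; the acceptance ratio is the event-likelihood ratio
   alone. Acceptance ~0.95 at study scale.
2. **Fixed effects** — the same device from the Gaussian conditional
   (likelihood × prior), accepted on the summed event-likelihood ratio.
3. **Residual SD / RE SDs (centered)** — adaptive log-scale random-walk
   MH; the SD conditionals are independent across effects given b.
4. **Collapsed variance moves** — per-coordinate random walks on each
   log-SD (and log σ<sub>ε</sub>) with the random effects *integrated
   out* of the longitudinal likelihood (Woodbury marginal) and a fresh b
   drawn from the proposed conditional. This is what lets chains
   traverse the σ<sub>k</sub> ≈ 0 funnel that defeats centered updates.
5. **Event block** (log shape, φ, α) — joint adaptive random-walk MH
   with empirical covariance adaptation during warmup; eight sub-updates
   per sweep because the block is cheap but strongly correlated, with
   15% of proposals stretched 4x to traverse the long axis of the
   (shape, φ₀, α) ridge. The block is initialised at the event-likelihood
   ML fit with trajectories pinned at their empirical-Bayes estimates
   (starting α at zero costs the chains most of their warmup crossing
   the ridge).

Adaptation runs only during warmup. Basis matrices at the quadrature
nodes are cached per Weibull shape, so steps 1–4 reuse them. Split-R̂
and ESS (arviz) are reported for every population parameter; `fit`
raises `ConvergenceError` when any exceeds the threshold (default 1.05)
unless downgraded to a warning, which the desk-scale tests deliberately
do — at a few hundred draws the weakly identified RE SDs commonly sit at
R̂ 1.1–1.6 while the scientific parameters (α, shape, φ, σ<sub>ε</sub>,
fixed effects) mix with ESS 150+.

### DIC

Conditional flavour: deviance D(θ, b) = −2 log p(y, T | θ, b), DIC =
D̄ + p<sub>D</sub>, p<sub>D</sub> = D̄ − D(posterior means, including the
random effects). Random effects therefore count toward the effective
number of parameters, which is the convention consistent with
per-subject p<sub>D</sub> values in the thousands reported for models of
this family. Negative p<sub>D</sub> is reported with a warning, not
hidden. `compare_structures` fits the three associations with a common
seed policy and ranks by DIC; a non-converging structure is marked
failed and excluded without aborting the run.

**Caveat on structure discrimination.** With realistically sharp
delivery timing (shape ≈ 45), the AUC association is locally
α(AUC(T) + m(T)(t−T)) over the narrow window where hazard mass lives —
nearly reparametrisable as value+slope, and close to value when
trajectories are intercept-dominated. An oracle experiment (ML fits of
each structure given the *true* latent trajectories at study scale,
n = 114) bounds the expected log-likelihood separation between the true
AUC structure and its misspecified rivals at ~1–5 units. DIC Monte Carlo
noise at desk-scale chain lengths is of the same order, so structure
ranking on synthetic data at this scale is only weakly repeatable; the
structure-selection acceptance test reflects whatever that ordering
honestly produces. Published DIC gaps of ~100 between structures imply
trajectory-feature variation much richer than the printed model
parameters generate.

## Synthetic-cohort generator

The generator *is* the joint model run forwards; its defaults are
calibrated once to the study's printed cohort structure:

| quantity | default | basis |
|---|---|---|
| women | 114 | printed cohort size |
| window | days 50–260 | printed recording window |
| preterm threshold | day 259 | 37 completed weeks |
| preterm fraction | ≈ 28% | printed; calibrates φ₀ = 8.59 at shape 45 |
| reading counts | median ≈ 157, wide IQR | printed 157 (6–211) |
| age at LMP | median 27 (IQR ≈ 22–31) | printed |
| age at onset | median 12 (IQR ≈ 8–17) | printed |
| nephropathy | 19% | printed |
| association | AUC, α = −0.01 | printed selected structure and estimate |
| φ<sub>neph</sub> | log 2.29 ≈ 0.829 | printed hazard ratio |

Choices the study does not pin down, fixed once on plausibility grounds:
mean trajectory declining from ~140 mg/dL (log 4.94) to ~110 mg/dL
mid-gestation with partial late recovery, projected onto the default
4-interior-knot basis; residual SD 0.35 (log scale — self-monitored
glucose is highly variable within a day); random-effect SDs 0.15
(intercept) and 0.12 (shape coefficients), making between-woman level
and shape variation comparable; Weibull shape 45, which concentrates
term deliveries with an SD of ~7 days and leaves < 0.5% of deliveries
truncated at day 280 (truncated deliveries are recorded as term births,
per the no-censoring design). Delivery days are continuous; reading days
are integers (multiple readings per day are legitimate), with a forced
reading at the exact delivery time, matching the observed-data structure.

Reading times are a per-woman homogeneous Poisson process whose rate is
drawn from a two-component mixture — 30% sparse reporters (log-normal
rate, median ≈ 0.012/day) and 70% near-daily monitors (normal rate,
mean 0.94/day, SD 0.28) — reproducing the printed median and the
strikingly wide printed IQR (6–211), which the package takes at face
value. Delivery times are drawn by inverting H<sub>i</sub>(t) = E,
E ~ Exp(1): a vectorised grid pass brackets each root and `brentq`
polishes it against the quadrature-exact cumulative hazard, so at α = 0
the draws are exact closed-form Weibull samples (verified by
Kolmogorov–Smirnov).

What the generator does **not** emulate: within-day meal/insulin
structure (readings on one day are exchangeable), informative missingness
(the sampling rate is independent of glucose level), covariates beyond
age/onset/nephropathy, and competing risks or indicated-vs-spontaneous
delivery distinctions. Tests passing on these cohorts therefore certify
the estimation machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Dynamic prediction

π(u | t) = 1 − S(u | b, θ)/S(t | b, θ), the probability of delivery
before horizon u (typically the preterm threshold 259) given
event-freedom at anchor t. For each posterior draw of θ, the new woman's
b is refreshed by one independence-MH step; the proposal is a Laplace
approximation of p(b | history, T > t) built once at the posterior
means (its mode found by BFGS — the target is concave because H is
convex in b, the association being linear in b — and its curvature
assembled analytically from the quadrature nodes). Summaries (mean,
median, 2.5/97.5% pointwise bands) are over the Monte Carlo draws. The
conditional sampler's mean is validated against a multivariate-t
importance-sampling oracle, and the α = 0 case collapses to the exact
conditional Weibull probability (the survival ratio is then independent
of b).

## Time-dependent Cox comparator

The counting-process expansion holds the *observed* log-glucose constant
between readings (LOCF, error-ignored); a woman enters the risk set at
her first reading. Covariates: glucose, gestational day, glucose×day,
both ages (standardized), nephropathy. The default semiparametric
variant maximises the Efron partial likelihood with an analytic
gradient (cross-checked against lifelines' `CoxTimeVaryingFitter` to
1e-10 on the log-likelihood); a Weibull parametric variant supplies a
full-likelihood comparison, integrating the piecewise-constant
covariates in closed form. Day-scaled covariates (days/100) are used
internally for optimiser conditioning and mapped back. For cross-model
tables the frequentist fit reports −2ℓ + 2p, labelled a DIC *analog*
(an AIC-type quantity), never a true DIC.

Because the LOCF covariate is the latent trajectory plus measurement
error, its fitted effect is attenuated toward zero relative to an
error-free refit; the paired-simulation test measures the effect as the
effective coefficient γ₁ + γ₃·day evaluated at day 200 (the raw γ₁ is
confounded with the interaction term).

## Desk-scale test sizes

The suite is sized to run comfortably on one CPU: generator-calibration
checks use the full 200/50 replicates (generation is cheap); Bayesian
recovery uses 10 replicates of 200 women at reduced reading intensity
(~50 readings/woman) with 2 chains × (400 warmup + 400 draws), asserting
pooled 95%-CI coverage ≥ 90% over the five scientific parameters;
structure selection uses 5 study-scale replicates with single chains of
400 + 500; simulation-based calibration uses 36 tiny cohorts (10 women,
1 interior knot) with narrowed α prior; the dynamic-prediction coverage
check uses 20 held-out women against one desk-scale posterior. Full-scale
settings are plain arguments away (`MCMCSettings`, `GeneratorConfig`).

## Known limitations

* Random-effect SD posteriors mix slowly when a component is weakly
  identified (few readings per woman); the collapsed moves make this
  tolerable but R̂ < 1.05 on every SD needs chains several times longer
  than the desk-scale defaults.
* The ML variant's variance components carry 10–25% sampling error at
  200 women; BIC knot selection inherits that noise.
* DIC-based structure selection is intrinsically low-powered under
  sharply timed delivery (see the caveat above).
* The no-censoring design ties the package to complete-delivery cohorts;
  administrative censoring would need a different event likelihood.
* One pregnancy per woman: repeated pregnancies would need a third
  grouping level.
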