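# pretermjm

Joint modelling of longitudinal maternal blood-glucose trajectories and
the risk of preterm birth in pregnancies complicated by type 1 diabetes.

Women with type 1 diabetes record blood glucose many times a day across
gestation; preterm delivery (before 37 completed weeks, gestational day
259) is several-fold more frequent in this population, and poor glycemic
control is a suspected driver. Because glucose readings are a noisy,
irregularly sampled view of a latent glycemic process, and because the
delivery process itself can depend on that process, naive regression of
delivery risk on observed glucose (a time-dependent Cox model with
last-observation-carried-forward covariates) is biased by measurement
error. `pretermjm` implements the shared-parameter joint model that
addresses this, for biostatisticians who want a self-contained, testable
Python implementation with a calibrated synthetic-cohort generator.

## The model

**Longitudinal submodel** — log glucose for woman *i* at gestational day
*t<sub>ij</sub>*:

    y_ij = β₀ + f(t_ij) + β_age·age_i + β_onset·onset_i
         + b_i0 + Σ_r b_ir λ_r(t_ij) + ε_ij,   ε_ij ~ N(0, σ_ε²)

with `f(t) = Σ_r β_r λ_r(t)` a natural cubic spline, mutually
independent random coefficients `b_ik ~ N(0, σ_k²)`, and ages
standardized by fixed reference constants.

**Event submodel** — Weibull hazard of delivery on analysis time
`t = day − 50`:

    h_i(t) = (l/s)(t/s)^{l−1} exp( φ₀ + φ_neph·neph_i + A_i(t) )

with association term `A_i(t)` one of

| structure     | A_i(t)                              |
|---------------|-------------------------------------|
| `value`       | α·m_i(t)                            |
| `value_slope` | α₁·m_i(t) + α₂·m_i′(t)              |
| `auc`         | α·∫₅₀ᵗ m_i(u) du                    |

where `m_i(t)` is the latent (noise-free) trajectory. Delivery is
observed for every woman (no censoring), so each contributes a full
event density `h_i(T_i)·exp(−H_i(T_i))`. Inference is Bayesian MCMC
(blocked Metropolis-within-Gibbs with conjugate-conditional proposals);
structures are compared by conditional DIC, and a frequentist
time-dependent Cox model (semiparametric and Weibull variants) serves as
the comparator. Individual preterm risk `P(T < 259 | T > t, history)` is
updated dynamically by Monte Carlo as a woman's readings accrue.

## Worked example

```python
from pretermjm import (GeneratorConfig, generate_cohort, JointModel,
                       MCMCSettings, conditional_preterm_risk)

cohort = generate_cohort(GeneratorConfig(n_women=40, high_rate_mean=0.25,
                                         high_rate_sd=0.08, low_rate_prob=0.1),
                         seed=42)
print(f"{cohort.n_subjects} women, {cohort.n_readings} readings, "
      f"{100*cohort.preterm_fraction():.0f}% preterm")

model = JointModel(cohort, association="auc", n_interior_knots=4)
res = model.fit(MCMCSettings(chains=2, warmup=600, draws=500, seed=1),
                on_bad_rhat="warn")
print(res.summary().loc[["alpha_auc", "shape", "phi_nephropathy"]].round(4))
dic, pd_ = res.dic()
print(f"DIC {dic:.1f} (pD {pd_:.1f})")
```

prints (elided to the key rows):

```
40 women, 1675 readings, 28% preterm
                    mean      sd     2.5%      50%    97.5%    rhat       ess
alpha_auc        -0.0135  0.0051  -0.0235  -0.0134  -0.0038  1.0028  314.9220
shape            47.5313  8.1253  32.6871  46.8341  63.8542  1.0028  310.4118
phi_nephropathy   0.1511  0.3913  -0.6518   0.1615   0.8637  1.0019  272.5409
DIC 1583.7 (pD 89.3)
```

The cumulative-glycemia association is recovered as negative
(`alpha_auc ≈ −0.013`, 95% CI excluding zero, against a generative value
of −0.01). On this sign convention a larger glucose AUC *lowers* the
delivery hazard; the generator mirrors the sign of the study's selected
model rather than imposing a clinical expectation. The Weibull shape
≈ 47 reflects the sharp timing of term delivery. With only 40 women the
nephropathy hazard ratio is imprecise (CI spans 1).

A command-line interface mirrors the library
(`pretermjm simulate|fit|compare|predict|report`).

## Layout

- `basis` — natural cubic spline basis (B-spline construction, exact
  derivative/integral, BIC knot-count selection)
- `config` / `simulate` — calibrated synthetic-cohort generator
- `longitudinal` — spline mixed model + marginal-ML variant
- `event` — Weibull hazard with the three association structures
  (Gauss–Jacobi cumulative hazard)
- `joint` — Bayesian joint model: sampler, diagnostics, DIC, structure
  comparison
- `prediction` — dynamic individualized preterm-risk curves
- `tdcox` — time-dependent Cox comparator (own Efron partial likelihood,
  cross-checked against lifelines)
- `pipeline` / `cli` — end-to-end workflow and command-line tool

See `docs/methods.md` for the statistical methods, default parameter
choices and their rationale, and known limitations.
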