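"""Synthetic-cohort generator configuration.

The defaults emulate the structure of a prospectively followed cohort of
114 pregnant women with type 1 diabetes: glucose recorded on gestational
days 50-260 (log scale), a heavily right-spread per-woman reading count
(median ~157, IQR ~6-211 — a mixture of sparse self-reporters and
near-daily monitors), ~28% preterm delivery (< day 259), age at last
menstrual period median 27 (IQR 22-31), age at diabetes onset median 12
(IQR 8-17), nephropathy prevalence 19%.

The data-generating mechanism *is* the joint model: log-glucose is a
natural-cubic-spline mixed model with independent random coefficients
and Gaussian measurement error, and the delivery time is drawn by
inverting the cumulative hazard of the Weibull event submodel under the
configured association structure (default: AUC with a negative
association, i.e. higher cumulative glycemia raises preterm risk).

Ages are standardised with the fixed reference constants below before
entering either the generating or the fitting equations, so age
coefficients are per reference-SD, not per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["GeneratorConfig", "AGE_LMP_REF", "AGE_ONSET_REF", "standardize_ages"]

# fixed standardisation reference (mean, sd in years)
AGE_LMP_REF = (26.9, 6.7)
AGE_ONSET_REF = (12.4, 6.6)

# population mean log-glucose trajectory, projected onto the default
# 4-interior-knot natural spline basis on days 50-260: glycemic control
# tightens from early pregnancy (~140 mg/dL) toward mid-gestation
# (~110 mg/dL) and partially relaxes near term.
_DEFAULT_BETA0 = 4.814465417782867
_DEFAULT_SPLINE_COEFS = (
    -0.09855733,
    -0.11398691,
    -0.09101568,
    0.16659775,
    -0.00304013,
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator (defaults = study scale)."""

    n_women: int = 114
    window: tuple[float, float] = (50.0, 260.0)
    truncation_day: float = 280.0
    preterm_threshold_day: float = 259.0
    seed: int | None = None

    # -- baseline covariates -------------------------------------------
    age_lmp_mean: float = 26.9
    age_lmp_sd: float = 6.7
    age_lmp_range: tuple[float, float] = (16.0, 45.0)
    age_onset_mean: float = 12.2
    age_onset_sd: float = 6.6
    age_onset_range: tuple[float, float] = (1.0, 30.0)
    nephropathy_prevalence: float = 0.19

    # -- longitudinal truth (log-glucose scale) ------------------------
    n_interior_knots: int = 4
    beta0: float = _DEFAULT_BETA0
    spline_coefs: tuple[float, ...] = _DEFAULT_SPLINE_COEFS
    beta_age: float = 0.05        # per reference-SD of age at LMP
    beta_onset: float = -0.04     # per reference-SD of age at onset
    re_sds: tuple[float, ...] = (0.15, 0.12, 0.12, 0.12, 0.12, 0.12)
    sigma_eps: float = 0.35

    # -- event truth ----------------------------------------------------
    association: str = "auc"
    alpha: tuple[float, ...] = (-0.01,)
    shape: float = 45.0
    # Weibull baseline on scaled analysis time (t / 210); the intercept is
    # calibrated so ~28% of women deliver before day 259
    event_t_scale: float = 210.0
    phi_intercept: float = 8.59
    phi_nephropathy: float = 0.8286  # log 2.29

    # -- reading-time process ------------------------------------------
    # per-woman homogeneous Poisson sampling with a two-component rate
    # mixture: a sparse-reporting group and a near-daily monitoring group
    low_rate_prob: float = 0.30
    low_rate_log_mean: float = field(default_factory=lambda: float(np.log(0.012)))
    low_rate_log_sd: float = 0.9
    high_rate_mean: float = 0.94
    high_rate_sd: float = 0.28
    min_rate: float = 0.004

    def __post_init__(self) -> None:
        a, b = self.window
        if not a < b:
            raise ValueError("window lower bound must be below upper bound")
        if not a < self.preterm_threshold_day < b + 50:
            raise ValueError("preterm threshold must sit inside the study window")
        if self.truncation_day <= b - 10:
            raise ValueError("truncation day should not precede the window end")
        if any(s <= 0 for s in self.re_sds) or self.sigma_eps <= 0:
            raise ValueError("all SDs must be positive")
        if self.shape <= 0:
            raise ValueError("Weibull shape must be positive")
        if not 0.0 <= self.nephropathy_prevalence <= 1.0:
            raise ValueError("nephropathy prevalence must be a probability")
        if not 0.0 <= self.low_rate_prob <= 1.0:
            raise ValueError("low_rate_prob must be a probability")
        if len(self.re_sds) != len(self.spline_coefs) + 1:
            raise ValueError(
                "re_sds must have one entry per random effect "
                "(intercept + one per spline coefficient)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("window", "age_lmp_range", "age_onset_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("spline_coefs", "re_sds", "alpha"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def standardize_ages(age_lmp, age_onset) -> tuple[np.ndarray, np.ndarray]:
    """z-score ages with the fixed reference constants (not per-cohort)."""
    z_lmp = (np.asarray(age_lmp, dtype=float) - AGE_LMP_REF[0]) / AGE_LMP_REF[1]
    z_onset = (np.asarray(age_onset, dtype=float) - AGE_ONSET_REF[0]) / AGE_ONSET_REF[1]
    return z_lmp, z_onset
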