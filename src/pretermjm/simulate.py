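"""Synthetic cohort generation.

Cohorts are generated from the joint model itself: spline mixed-model
trajectories for log-glucose, and delivery times drawn by inverting the
cumulative hazard of the Weibull event submodel under the configured
association structure (H_i(T_i) = E_i with E_i ~ Exponential(1)).
Deliveries that the hazard fails to produce by the truncation day are
set to the truncation day and count as term births.

Reading days are a per-woman homogeneous Poisson process on
[window start, delivery] with a mixture-distributed rate (sparse
self-reporters vs near-daily monitors); a reading is always forced on
the delivery day, matching the observed-data structure in which
delivery-day glucose is available for every woman.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import event as ev
from .basis import NaturalCubicSplineBasis, build_basis
from .config import GeneratorConfig, standardize_ages
from .data import CohortData
from .trajectories import LatentTrajectories

__all__ = ["generate_cohort", "trajectory_truth", "CohortTruth"]


@dataclass
class CohortTruth:
    """Latent quantities behind a synthetic cohort (for recovery tests)."""

    basis: NaturalCubicSplineBasis
    trajectories: LatentTrajectories
    random_effects: np.ndarray  # (n, 1 + n_basis)
    eta: np.ndarray             # event linear predictor per woman
    event_params: ev.EventParams
    ids: np.ndarray
    n_truncated: int = 0


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator, n: int):
    age_lmp = np.clip(
        np.round(rng.normal(cfg.age_lmp_mean, cfg.age_lmp_sd, n)),
        *cfg.age_lmp_range,
    )
    age_onset = np.clip(
        np.round(rng.normal(cfg.age_onset_mean, cfg.age_onset_sd, n)),
        *cfg.age_onset_range,
    )
    # diabetes onset precedes the index pregnancy
    age_onset = np.minimum(age_onset, age_lmp - 1)
    neph = (rng.uniform(size=n) < cfg.nephropathy_prevalence).astype(int)
    return age_lmp, age_onset, neph


def _invert_cumulative_hazard(
    params: ev.EventParams,
    traj: LatentTrajectories,
    eta: np.ndarray,
    targets: np.ndarray,
    t_max: float,
    origin: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve H_i(t) = E_i per woman by bracketed root-finding.

    A coarse vectorised grid pass brackets each root; `brentq` then
    refines against the quadrature-exact cumulative hazard.  Women whose
    H never reaches the target by ``t_max`` are truncated.
    """
    n = eta.size
    grid = np.linspace(0.0, t_max, 120)
    logH = ev.log_cumulative_hazard(
        params, traj, eta, np.broadcast_to(grid, (n, grid.size)), origin
    )
    log_targets = np.log(targets)
    times = np.empty(n)
    truncated = np.zeros(n, dtype=bool)
    for i in range(n):
        if logH[i, -1] < log_targets[i]:
            times[i] = t_max
            truncated[i] = True
            continue
        j = int(np.searchsorted(logH[i], log_targets[i]))
        lo = grid[max(j - 1, 1)] * 0.5 if j <= 1 else grid[j - 1]
        hi = grid[min(j, grid.size - 1)]
        tr = traj.subset([i])

        def f(t, i=i, tr=tr):
            return (
                ev.log_cumulative_hazard(params, tr, eta[i : i + 1], np.array([t]), origin)[0]
                - log_targets[i]
            )
        lo = max(lo, 1e-9)
        flo, fhi = f(lo), f(hi)
        while flo > 0 and lo > 1e-12:  # grid bracket conservative near zero
            lo *= 0.25
            flo = f(lo)
        if fhi < 0:
            hi = min(hi + (grid[1] - grid[0]), t_max)
            fhi = f(hi)
        times[i] = brentq(f, lo, hi, xtol=1e-8)
    return times, truncated


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> CohortData:
    """Generate one synthetic cohort; ``seed`` overrides ``config.seed``."""
    cfg = config or GeneratorConfig()
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = cfg.n_women
    a, b_day = cfg.window
    origin = a

    basis = build_basis(
        boundary=cfg.window, n_interior_knots=cfg.n_interior_knots, knot_rule="uniform"
    )
    q = basis.n_basis
    if len(cfg.spline_coefs) != q:
        raise ValueError(
            f"spline_coefs has length {len(cfg.spline_coefs)}, basis needs {q}"
        )

    age_lmp, age_onset, neph = _draw_covariates(cfg, rng, n)
    z_lmp, z_onset = standardize_ages(age_lmp, age_onset)

    re_sds = np.asarray(cfg.re_sds)
    b = rng.normal(size=(n, q + 1)) * re_sds
    const = cfg.beta0 + b[:, 0] + cfg.beta_age * z_lmp + cfg.beta_onset * z_onset
    coefs = np.asarray(cfg.spline_coefs) + b[:, 1:]
    traj = LatentTrajectories(basis, const, coefs)

    params = ev.EventParams(
        shape=cfg.shape,
        phi=np.array([cfg.phi_intercept, cfg.phi_nephropathy]),
        alpha=np.asarray(cfg.alpha),
        association=cfg.association,
        t_scale=cfg.event_t_scale,
    )
    eta = params.linear_predictor(neph)

    targets = rng.exponential(size=n)  # H(T) = E, E ~ Exp(1)
    t_max = cfg.truncation_day - origin
    t_delivery, truncated = _invert_cumulative_hazard(
        params, traj, eta, targets, t_max, origin
    )
    delivery_day = np.clip(origin + t_delivery, a + 1.0, cfg.truncation_day)

    # -- reading-time process ------------------------------------------
    is_low = rng.uniform(size=n) < cfg.low_rate_prob
    rate = np.where(
        is_low,
        np.exp(rng.normal(cfg.low_rate_log_mean, cfg.low_rate_log_sd, n)),
        rng.normal(cfg.high_rate_mean, cfg.high_rate_sd, n),
    )
    rate = np.maximum(rate, cfg.min_rate)

    rows_id, rows_day = [], []
    for i in range(n):
        exposure = min(delivery_day[i], b_day) - a
        count = rng.poisson(rate[i] * max(exposure, 0.0))
        days = np.sort(
            np.round(rng.uniform(a, a + max(exposure, 0.0), count))
        ).astype(float)
        days = days[(days >= a) & (days <= delivery_day[i])]
        days = np.append(days, delivery_day[i])  # forced delivery-day reading
        rows_id.append(np.full(days.size, i + 1))
        rows_day.append(days)
    ids_long = np.concatenate(rows_id)
    days_long = np.concatenate(rows_day)

    # evaluate m_i at each reading: group by woman for correct coefficients
    m_vals = np.empty(days_long.size)
    start = 0
    for i in range(n):
        k = rows_day[i].size
        m_vals[start : start + k] = traj.subset([i]).value(
            rows_day[i].reshape(1, -1)
        )[0]
        start += k
    noise = rng.normal(0.0, cfg.sigma_eps, days_long.size)
    log_glucose = m_vals + noise

    longitudinal = pd.DataFrame(
        {"id": ids_long.astype(int), "day": days_long, "log_glucose": log_glucose}
    )
    subjects = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age_lmp": age_lmp,
            "age_onset": age_onset,
            "nephropathy": neph,
            "delivery_day": delivery_day,
            "preterm": (delivery_day < cfg.preterm_threshold_day).astype(int),
        }
    )
    cohort = CohortData(
        longitudinal=longitudinal,
        subjects=subjects,
        provenance={"generator": cfg.to_dict(), "seed": int(seed)},
    )
    cohort.truth = CohortTruth(
        basis=basis,
        trajectories=traj,
        random_effects=b,
        eta=eta,
        event_params=params,
        ids=subjects["id"].to_numpy(),
        n_truncated=int(truncated.sum()),
    )
    return cohort


def trajectory_truth(cohort: CohortData, woman, t) -> np.ndarray:
    """Noise-free latent m_i(t) for a synthetically generated woman."""
    truth = getattr(cohort, "truth", None)
    if truth is None:
        raise ValueError("cohort carries no generator truth (not synthetic?)")
    idx = np.nonzero(truth.ids == woman)[0]
    if idx.size == 0:
        raise KeyError(f"unknown woman id {woman!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return truth.trajectories.subset(idx).value(t.reshape(1, -1))[0]
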