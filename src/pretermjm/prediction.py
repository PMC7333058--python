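"""Dynamic individualized preterm-birth risk prediction.

Given a fitted joint model and a *new* woman's glucose history up to an
anchor time ``t`` (with the assumption that she has not yet delivered at
``t``), the conditional probability of delivering before a horizon ``u``
is

    pi(u | t) = 1 - S(u | b, params) / S(t | b, params),

averaged over the posterior of the parameters and of her subject-specific
random effects ``b`` given her history.  The Monte Carlo scheme follows
the standard dynamic-prediction recipe for shared-parameter joint
models: for each posterior draw of the parameters, the random effects
are refreshed by one independence Metropolis-Hastings step whose
proposal is a Laplace approximation of the conditional posterior

    p(b | history, T > t) ∝ N(y | m(b)) N(b | 0, D) S(t | b),

built once around the conditional mode at the posterior means.  The
chain of ``b`` values is carried across posterior draws, so the sampler
is a proper MCMC over (params, b) and the risk summaries (mean, median,
2.5/97.5% pointwise bands) are over its draws.

"Risk of preterm birth" is operationalized as the probability of
delivery before gestational day 259 (37 completed weeks) given
event-freedom at the anchor; intermediate horizons u in (t, 259] trace
the conditional risk curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import event as ev
from .config import standardize_ages
from .data import PRETERM_THRESHOLD_DAY
from .trajectories import LatentTrajectories

__all__ = ["RiskCurve", "conditional_preterm_risk", "risk_trajectory"]


@dataclass
class RiskCurve:
    """Conditional preterm-risk trajectory for one woman at one anchor."""

    anchor_day: float
    horizon_days: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    lower: np.ndarray   # 2.5% pointwise
    upper: np.ndarray   # 97.5% pointwise
    n_draws: int
    threshold_day: float = PRETERM_THRESHOLD_DAY

    def __post_init__(self) -> None:
        for arr in (self.mean, self.median, self.lower, self.upper):
            if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
                raise ValueError("risks must lie in [0, 1]")
        if np.any(self.lower > self.median + 1e-9) or np.any(
            self.median > self.upper + 1e-9
        ):
            raise ValueError("pointwise bands must contain the median")

    @property
    def risk_at_threshold(self) -> float:
        """Posterior-mean P(delivery < threshold | event-free at anchor)."""
        return float(self.mean[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor_day": self.anchor_day,
                "horizon_day": self.horizon_days,
                "mean": self.mean,
                "median": self.median,
                "lower_2.5": self.lower,
                "upper_97.5": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Risk vs horizon with the 95% pointwise band."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.horizon_days, self.mean, label="posterior mean")
        ax.plot(self.horizon_days, self.median, ls="--", label="median")
        ax.fill_between(
            self.horizon_days, self.lower, self.upper, alpha=0.25, label="95% band"
        )
        ax.set_xlabel("gestational day")
        ax.set_ylabel("P(delivery before day "
                      f"{self.threshold_day:.0f} | event-free at day {self.anchor_day:.0f})")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False)
        return ax


class _NewSubject:
    """Design pieces for one new woman's history."""

    def __init__(self, model, history: pd.DataFrame, covariates: dict):
        self.model = model
        basis = model.basis
        days = history["day"].to_numpy(dtype=float)
        self.y = history["log_glucose"].to_numpy(dtype=float)
        self.days = days
        z_age, z_onset = standardize_ages(
            [covariates["age_lmp"]], [covariates["age_onset"]]
        )
        self.z_age = float(z_age[0])
        self.z_onset = float(z_onset[0])
        self.neph = float(covariates.get("nephropathy", 0))
        self.B = basis.evaluate(days)                      # (m, q)
        self.Z = np.concatenate([np.ones((days.size, 1)), self.B], axis=1)
        self.ZtZ = self.Z.T @ self.Z

    def fixed_offset(self, theta) -> np.ndarray:
        q = self.model.design.n_basis
        return (
            theta[0]
            + self.B @ theta[1 : q + 1]
            + theta[q + 1] * self.z_age
            + theta[q + 2] * self.z_onset
        )

    def traj(self, theta, b) -> LatentTrajectories:
        q = self.model.design.n_basis
        const = theta[0] + b[0] + theta[q + 1] * self.z_age + theta[q + 2] * self.z_onset
        coefs = theta[1 : q + 1] + b[1:]
        return LatentTrajectories(self.model.basis, np.array([const]), coefs[None, :])


def _log_target(model, sub, theta, b, sds, sigma, eparams, t_anchor):
    """log p(history | b) + log p(b) + log S(t_anchor | b) (unnormalised)."""
    resid = sub.y - sub.fixed_offset(theta) - sub.Z @ b
    ll = -0.5 * np.sum(resid**2) / sigma**2 - resid.size * np.log(sigma)
    ll += float(np.sum(-0.5 * (b / sds) ** 2 - np.log(sds)))
    traj = sub.traj(theta, b)
    eta = eparams.linear_predictor(np.array([sub.neph]))
    logH = ev.log_cumulative_hazard(
        eparams, traj, eta, np.array([t_anchor]), model.origin
    )[0]
    return ll - np.exp(logH)


def _laplace_proposal(model, sub, theta, sds, sigma, eparams, t_anchor):
    """Mode and covariance of the conditional b posterior (Gaussian part
    exact; survival term folded in by numerical optimisation)."""
    prec_gauss = sub.ZtZ / sigma**2 + np.diag(1.0 / sds**2)
    resid0 = sub.y - sub.fixed_offset(theta)
    mu_gauss = np.linalg.solve(prec_gauss, sub.Z.T @ resid0 / sigma**2)

    def negt(b):
        return -_log_target(model, sub, theta, b, sds, sigma, eparams, t_anchor)

    res = minimize(negt, mu_gauss, method="BFGS",
                   options={"maxiter": 200, "gtol": 1e-6})
    mode = res.x
    # Gauss-Newton curvature: Gaussian precision + quadrature curvature of H
    # (H is convex in b because the association is linear in b)
    hess = prec_gauss + _cumhaz_curvature(model, sub, theta, mode, eparams, t_anchor)
    cov = np.linalg.inv(hess)
    cov = 0.5 * (cov + cov.T)
    return mode, cov


def _cumhaz_curvature(model, sub, theta, b, eparams, t_anchor):
    """∇²_b H(t_anchor) via the quadrature nodes (A is linear in b)."""
    x, logw = ev._gj_nodes(ev.DEFAULT_NODES, float(eparams.shape))
    s = t_anchor * x
    days = model.origin + s
    basis = model.basis
    q = basis.n_basis
    alpha = eparams.alpha
    if eparams.association == "value":
        G = alpha[0] * np.concatenate([np.ones((s.size, 1)), basis.evaluate(days)], axis=1)
    elif eparams.association == "value_slope":
        G = alpha[0] * np.concatenate(
            [np.ones((s.size, 1)), basis.evaluate(days)], axis=1
        ) + alpha[1] * np.concatenate(
            [np.zeros((s.size, 1)), basis.derivative(days)], axis=1
        )
    else:  # auc
        a0 = basis.antiderivative(np.array([model.origin]))[0]
        G = alpha[0] * np.concatenate(
            [s[:, None], basis.antiderivative(days) - a0], axis=1
        )
    traj = sub.traj(theta, b)
    eta = eparams.linear_predictor(np.array([sub.neph]))
    A = ev.association_term(traj, alpha, eparams.association, s[None, :], model.origin)[0]
    base = np.exp(
        eta + eparams.shape * np.log(t_anchor / eparams.t_scale) + logw + A
    )
    return np.einsum("k,ki,kj->ij", base, G, G)


def conditional_preterm_risk(
    results,
    history: pd.DataFrame,
    covariates: dict,
    anchor_day: float | None = None,
    threshold_day: float = PRETERM_THRESHOLD_DAY,
    draws: int = 500,
    seed: int = 0,
    n_horizons: int = 25,
) -> RiskCurve:
    """Monte-Carlo conditional preterm risk for a new woman.

    Parameters
    ----------
    results
        A fitted :class:`~pretermjm.joint.JointModelResults`.
    history
        Readings (columns ``day``, ``log_glucose``) up to the anchor.
    covariates
        ``{'age_lmp': ..., 'age_onset': ..., 'nephropathy': 0/1}``.
    anchor_day
        Anchor gestational day (default: day of the last reading).  The
        woman is assumed event-free at the anchor.
    draws
        Monte Carlo size; posterior draws are cycled if fewer are stored.
    """
    model = results.model
    if anchor_day is None:
        anchor_day = float(history["day"].max())
    if np.any(history["day"].to_numpy() > anchor_day + 1e-9):
        raise ValueError("history contains readings after the anchor day")
    if anchor_day >= threshold_day:
        raise ValueError(
            f"anchor day {anchor_day} must precede the preterm threshold "
            f"{threshold_day}"
        )
    if results.n_draws < 1:
        raise ValueError("posterior has no draws")

    sub = _NewSubject(model, history, covariates)
    t_anchor = anchor_day - model.origin
    t_thresh = threshold_day - model.origin
    horizons = np.linspace(t_anchor, t_thresh, n_horizons + 1)[1:]

    theta_d = results.stacked("theta").reshape(-1, model.design.n_fixed)
    sds_d = results.stacked("re_sds").reshape(-1, model.design.n_random)
    sig_d = results.stacked("sigma_eps").reshape(-1)
    evec_d = results.stacked("evec").reshape(-1, 3 + model.n_alpha)

    rng = np.random.default_rng(seed)
    total = theta_d.shape[0]
    idx = rng.integers(0, total, size=draws) if draws != total else np.arange(total)

    # Laplace proposal at posterior means
    theta_bar = theta_d.mean(axis=0)
    sds_bar = sds_d.mean(axis=0)
    sig_bar = float(sig_d.mean())
    evec_bar = evec_d.mean(axis=0)
    ep_bar = model._event_params(evec_bar)
    mode, cov = _laplace_proposal(model, sub, theta_bar, sds_bar, sig_bar, ep_bar, t_anchor)
    Lc = np.linalg.cholesky(cov)
    prec = np.linalg.inv(cov)

    def prop_logpdf(b):
        d = b - mode
        return -0.5 * d @ prec @ d

    b_cur = mode.copy()
    risks = np.empty((draws, horizons.size))
    for k, j in enumerate(idx):
        theta = theta_d[j]
        eparams = model._event_params(evec_d[j])
        # target changes with every posterior draw: re-evaluate at b_cur
        lp_cur = _log_target(
            model, sub, theta, b_cur, sds_d[j], sig_d[j], eparams, t_anchor
        )
        b_prop = mode + Lc @ rng.standard_normal(mode.size)
        lp_prop = _log_target(
            model, sub, theta, b_prop, sds_d[j], sig_d[j], eparams, t_anchor
        )
        log_acc = (lp_prop - prop_logpdf(b_prop)) - (lp_cur - prop_logpdf(b_cur))
        if np.log(rng.uniform()) < log_acc:
            b_cur = b_prop
        traj = sub.traj(theta, b_cur)
        eta = eparams.linear_predictor(np.array([sub.neph]))
        ts = np.concatenate([[t_anchor], horizons])
        logH = ev.log_cumulative_hazard(
            eparams, traj, eta, ts[None, :], model.origin
        )[0]
        S = np.exp(-np.exp(logH))
        risks[k] = 1.0 - S[1:] / S[0]

    return RiskCurve(
        anchor_day=float(anchor_day),
        horizon_days=model.origin + horizons,
        mean=risks.mean(axis=0),
        median=np.median(risks, axis=0),
        lower=np.quantile(risks, 0.025, axis=0),
        upper=np.quantile(risks, 0.975, axis=0),
        n_draws=draws,
        threshold_day=threshold_day,
    )


def risk_trajectory(
    results,
    history: pd.DataFrame,
    covariates: dict,
    anchor_days,
    threshold_day: float = PRETERM_THRESHOLD_DAY,
    draws: int = 500,
    seed: int = 0,
) -> list[RiskCurve]:
    """One conditional risk curve per anchor, each using only the readings
    observed by that anchor (event-freedom extended to anchors after the
    last reading)."""
    anchor_days = np.asarray(anchor_days, dtype=float)
    if np.any(np.diff(anchor_days) <= 0):
        raise ValueError("anchor days must be strictly increasing")
    curves = []
    for i, t in enumerate(anchor_days):
        hist_t = history[history["day"] <= t + 1e-9]
        if hist_t.empty:
            raise ValueError(f"no readings on or before anchor day {t}")
        curves.append(
            conditional_preterm_risk(
                results,
                hist_t,
                covariates,
                anchor_day=t,
                threshold_day=threshold_day,
                draws=draws,
                seed=seed + i,
            )
        )
    return curves
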