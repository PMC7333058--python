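"""Bayesian shared-parameter joint model and its MCMC sampler.

The joint density factorises as  p(y | b) p(T | b) p(b) p(params): every
woman's glucose readings (Gaussian around her latent spline trajectory)
and her delivery time (Weibull hazard modulated by a functional of that
same trajectory) are tied together by her random spline coefficients
``b_i``.

Sampling scheme (blocked Metropolis-within-Gibbs):

* ``b_i`` — independence Metropolis-Hastings, proposing from the exact
  Gaussian conditional implied by the longitudinal likelihood and the
  random-effects prior; the acceptance ratio then involves only the
  event likelihood.  With hundreds of readings per woman the proposal
  is nearly the full conditional, so acceptance is high and mixing does
  not degrade with the dimension of ``b_i``.  All women update in
  parallel (their conditionals are independent).
* fixed effects — same independence-MH device from the Gaussian
  conditional (longitudinal likelihood x Normal prior), accepted on the
  event-likelihood ratio.
* residual SD and random-effect SDs — adaptive random-walk MH on the
  log scale (the SD conditionals are independent across effects given
  ``b`` and update as a vector).
* event block (log shape, phi, alpha) — joint adaptive random-walk MH
  with empirical covariance adaptation during warmup.

Priors are weakly informative and explicit: Normal(0, 10^2) on fixed
effects, phi and alpha; half-Normal(0, 5^2) on all SDs; Gamma(1, 0.02)
on the Weibull shape (weakly informative at the tens scale on which
sharply timed term delivery puts the shape).

DIC is the *conditional* flavour: deviance D(params, b) =
-2 log p(y, T | params, b) averaged over draws, with
pD = mean(D) - D(posterior means), so random effects count toward the
effective number of parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import event as ev
from .basis import NaturalCubicSplineBasis, build_basis
from .data import CohortData
from .longitudinal import (
    LongitudinalDesign,
    LongitudinalMixedModel,
    LongitudinalParams,
)

__all__ = [
    "Priors",
    "MCMCSettings",
    "JointModel",
    "JointModelResults",
    "ConvergenceError",
    "compare_structures",
]

LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """MCMC did not mix; carries the diagnostics payload."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults; all scales configurable."""

    fixed_effect_sd: float = 10.0
    phi_sd: float = 10.0
    alpha_sd: float = 10.0
    re_sd_scale: float = 5.0
    sigma_eps_scale: float = 5.0
    # Gamma(1, 0.02): exponential with mean 50 — term delivery is sharply
    # timed, so realistic Weibull shapes sit in the tens; a rate of 0.1
    # (mean 10) is informative enough at that scale to drag the posterior
    # down the (shape, alpha) likelihood ridge
    shape_gamma: tuple[float, float] = (1.0, 0.02)  # (shape a, rate)


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    n_quad: int = ev.DEFAULT_NODES
    # extra event-block updates per sweep: the (shape, phi, alpha) block is
    # cheap to evaluate but strongly correlated a posteriori, so it gets
    # several moves for every random-effect/fixed-effect move
    event_subiters: int = 8

    def __post_init__(self) -> None:
        if self.draws < 1 or self.chains < 1:
            raise ValueError("draws and chains must be >= 1")


class _EventLikelihood:
    """Vectorised event log-density with shape-keyed caching.

    The Gauss-Jacobi nodes and weights depend on the Weibull shape only;
    random-effect and fixed-effect updates leave the shape untouched, so
    the basis matrices at the node days are cached and reused across the
    many likelihood evaluations of one sweep.
    """

    def __init__(self, model: "JointModel", n_quad: int):
        self.model = model
        self.assoc = model.association
        self.t = model.event_times
        self.origin = model.origin
        self.t_scale = model.t_scale
        self.n_quad = n_quad
        basis = model.basis
        days_T = self.origin + self.t
        self.log_ts = np.log(self.t / self.t_scale)
        self.PT_val = basis.evaluate(days_T)
        self.PT_slope = basis.derivative(days_T) if self.assoc == "value_slope" else None
        a0 = basis.antiderivative(np.array([self.origin]))[0]
        self.PT_anti = basis.antiderivative(days_T) - a0 if self.assoc == "auc" else None
        self._a0 = a0
        self._cached_shape = None
        d = model.design
        self.z_age, self.z_onset = d.z_age, d.z_onset
        self.neph = model.nephropathy
        self.q = d.n_basis

    def _node_mats(self, shape: float):
        if self._cached_shape != shape:
            x, logw = ev._gj_nodes(self.n_quad, shape)
            s = self.t[:, None] * x  # (n, k) analysis times
            days = self.origin + s
            basis = self.model.basis
            self._s = s
            self._logw = logw
            self._N_val = basis.evaluate(days)
            self._N_slope = (
                basis.derivative(days) if self.assoc == "value_slope" else None
            )
            self._N_anti = (
                basis.antiderivative(days) - self._a0 if self.assoc == "auc" else None
            )
            self._cached_shape = shape
        return self._s, self._logw, self._N_val, self._N_slope, self._N_anti

    def _traj_pieces(self, theta, b):
        q = self.q
        const = theta[0] + b[:, 0] + theta[q + 1] * self.z_age + theta[q + 2] * self.z_onset
        coefs = theta[1: q + 1] + b[:, 1:]
        return const, coefs

    def loglik(self, evec: np.ndarray, theta: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Per-woman log event density log h(T_i) - H(T_i)."""
        shape = float(np.exp(evec[0]))
        eta = evec[1] + evec[2] * self.neph
        alpha = evec[3:]
        const, coefs = self._traj_pieces(theta, b)
        s, logw, N_val, N_slope, N_anti = self._node_mats(shape)

        if self.assoc == "value":
            A_nodes = alpha[0] * (const[:, None] + np.einsum("nkq,nq->nk", N_val, coefs))
            A_T = alpha[0] * (const + np.einsum("nq,nq->n", self.PT_val, coefs))
        elif self.assoc == "value_slope":
            val_nodes = const[:, None] + np.einsum("nkq,nq->nk", N_val, coefs)
            slope_nodes = np.einsum("nkq,nq->nk", N_slope, coefs)
            A_nodes = alpha[0] * val_nodes + alpha[1] * slope_nodes
            A_T = alpha[0] * (
                const + np.einsum("nq,nq->n", self.PT_val, coefs)
            ) + alpha[1] * np.einsum("nq,nq->n", self.PT_slope, coefs)
        else:  # auc
            A_nodes = alpha[0] * (
                const[:, None] * s + np.einsum("nkq,nq->nk", N_anti, coefs)
            )
            A_T = alpha[0] * (
                const * self.t + np.einsum("nq,nq->n", self.PT_anti, coefs)
            )

        m = np.max(A_nodes, axis=-1, keepdims=True)
        body = m[:, 0] + np.log(
            np.sum(np.exp(logw + A_nodes - m), axis=-1)
        )
        logH = eta + shape * self.log_ts + body
        logh = (
            np.log(shape)
            - np.log(self.t_scale)
            + (shape - 1.0) * self.log_ts
            + eta
            + A_T
        )
        return logh - np.exp(logH)


def _half_normal_logpdf(x, scale):
    return np.where(
        x > 0, -0.5 * (x / scale) ** 2 - np.log(scale) - 0.5 * LOG2PI + np.log(2.0), -np.inf
    )


class JointModel:
    """Shared-parameter joint model for one cohort.

    Parameters
    ----------
    cohort
        Validated :class:`~pretermjm.data.CohortData`.
    association
        ``'value'``, ``'value_slope'`` or ``'auc'``.
    basis / n_interior_knots / knot_rule
        Either a prebuilt basis, or a knot count (default 4) placed at
        pooled-reading-time quantiles.
    """

    def __init__(
        self,
        cohort: CohortData,
        association: str = "auc",
        basis: NaturalCubicSplineBasis | None = None,
        n_interior_knots: int = 4,
        knot_rule: str = "quantile",
        priors: Priors | None = None,
    ):
        if basis is None:
            basis = build_basis(
                n_interior_knots=n_interior_knots,
                knot_rule=knot_rule,
                observation_times=cohort.pooled_days(),
            )
        self.cohort = cohort
        self.basis = basis
        self.association = association
        self.n_alpha = ev.n_alpha(association)
        self.priors = priors or Priors()
        self.design = LongitudinalDesign(cohort, basis)
        self.origin = basis.boundary[0]
        self.t_scale = basis.boundary[1] - basis.boundary[0]
        self.event_times = (
            cohort.subjects["delivery_day"].to_numpy(dtype=float) - self.origin
        )
        if np.any(self.event_times <= 0):
            raise ValueError("delivery on/before the window origin")
        self.nephropathy = self.design.nephropathy

    # -- densities ------------------------------------------------------
    def _event_params(self, evec: np.ndarray) -> ev.EventParams:
        return ev.EventParams(
            shape=float(np.exp(evec[0])),
            phi=evec[1:3].copy(),
            alpha=evec[3:].copy(),
            association=self.association,
            t_scale=self.t_scale,
        )

    def _event_loglik_per_woman(self, evec, theta, b, n_quad=ev.DEFAULT_NODES):
        params = self._event_params(evec)
        traj = self.design.trajectories(theta, b)
        eta = params.linear_predictor(self.nephropathy)
        return ev.event_log_density(
            params, traj, eta, self.event_times, self.origin, n_quad
        )

    def _long_loglik(self, theta, b, sigma):
        d = self.design
        r = d.y - d.X @ theta - d.Zb_rows(b)
        N = r.size
        return -0.5 * N * (LOG2PI + 2.0 * np.log(sigma)) - 0.5 * np.sum(r**2) / sigma**2

    def log_joint(
        self,
        lparams: LongitudinalParams,
        eparams: ev.EventParams,
        random_effects: np.ndarray,
    ) -> float:
        """Full log joint density (likelihoods + random-effect and
        parameter priors) at the given values.

        Invalid parameter values (non-positive SDs or shape) return
        ``-inf`` by convention.
        """
        pr = self.priors
        if (
            np.any(lparams.re_sds <= 0)
            or lparams.sigma_eps <= 0
            or eparams.shape <= 0
        ):
            return -np.inf
        b = np.asarray(random_effects, dtype=float)
        evec = np.concatenate(
            [[np.log(eparams.shape)], eparams.phi, eparams.alpha]
        )
        ll = self._long_loglik(lparams.theta, b, lparams.sigma_eps)
        ll += float(np.sum(self._event_loglik_per_woman(evec, lparams.theta, b)))
        # random-effects prior
        sds = lparams.re_sds
        ll += float(
            np.sum(-0.5 * (b / sds) ** 2 - np.log(sds) - 0.5 * LOG2PI)
        )
        # parameter priors
        theta = lparams.theta
        ll += float(np.sum(-0.5 * (theta / pr.fixed_effect_sd) ** 2
                           - np.log(pr.fixed_effect_sd) - 0.5 * LOG2PI))
        ll += float(np.sum(_half_normal_logpdf(sds, pr.re_sd_scale)))
        ll += float(_half_normal_logpdf(np.array(lparams.sigma_eps), pr.sigma_eps_scale))
        a, rate = pr.shape_gamma
        # Gamma(a, rate) prior on the Weibull shape, up to its constant
        ll += float((a - 1.0) * np.log(eparams.shape) - rate * eparams.shape)
        ll += float(np.sum(-0.5 * (eparams.phi / pr.phi_sd) ** 2
                           - np.log(pr.phi_sd) - 0.5 * LOG2PI))
        ll += float(np.sum(-0.5 * (eparams.alpha / pr.alpha_sd) ** 2
                           - np.log(pr.alpha_sd) - 0.5 * LOG2PI))
        return float(ll)

    def _deviance(self, theta, b, sigma, evec, n_quad=ev.DEFAULT_NODES) -> float:
        """-2 log p(y, T | params, b): the conditional deviance."""
        ll = self._long_loglik(theta, b, sigma)
        ll += float(np.sum(self._event_loglik_per_woman(evec, theta, b, n_quad)))
        return -2.0 * float(ll)

    # -- initialisation --------------------------------------------------
    def _initial_state(self):
        ml = LongitudinalMixedModel(self.cohort, self.basis).fit()
        null = ev.fit_weibull_null(self.event_times, self.nephropathy, self.t_scale)
        theta = ml.params.theta
        evec0 = np.concatenate(
            [[np.log(null.shape)], null.phi, np.zeros(self.n_alpha)]
        )
        # refine the whole event block (including alpha) by ML with the
        # trajectories pinned at their empirical-Bayes estimates: the
        # (shape, phi0, alpha) posterior lies on a narrow curved ridge, so
        # starting at alpha = 0 costs the chains most of their warmup
        from scipy.optimize import minimize as _minimize

        evaluator = _EventLikelihood(self, ev.DEFAULT_NODES)
        b0 = ml.random_effects

        def nll(x):
            if x[0] > np.log(400.0):
                return 1e12
            val = -float(np.sum(evaluator.loglik(x, theta, b0)))
            return val if np.isfinite(val) else 1e12

        opt = _minimize(nll, evec0, method="Nelder-Mead",
                        options={"maxiter": 4000, "fatol": 1e-8, "xatol": 1e-8})
        if np.isfinite(opt.fun) and opt.fun < nll(evec0):
            evec0 = opt.x
        state = {
            "theta": theta,
            "log_re_sds": np.log(np.maximum(ml.params.re_sds, 1e-3)),
            "log_sigma": np.log(ml.params.sigma_eps),
            "evec": evec0,
            "b": b0.copy(),
        }
        return state, ml

    # -- the sampler ------------------------------------------------------
    def fit(
        self,
        settings: MCMCSettings | None = None,
        *,
        chains: int | None = None,
        warmup: int | None = None,
        draws: int | None = None,
        seed: int | None = None,
        rhat_threshold: float = 1.05,
        on_bad_rhat: str = "raise",
    ) -> "JointModelResults":
        """Run the MCMC and return a posterior results object.

        ``on_bad_rhat``: 'raise' (default) fails loudly with diagnostics if
        any population-parameter split-R-hat exceeds ``rhat_threshold``;
        'warn' downgrades to a warning (used at deliberately short desk-scale
        settings); 'ignore' skips the check.
        """
        s = settings or MCMCSettings()
        if chains is not None or warmup is not None or draws is not None or seed is not None:
            s = replace(
                s,
                chains=chains if chains is not None else s.chains,
                warmup=warmup if warmup is not None else s.warmup,
                draws=draws if draws is not None else s.draws,
                seed=seed if seed is not None else s.seed,
            )
        init, ml = self._initial_state()
        seeds = np.random.SeedSequence(s.seed).spawn(s.chains)
        chains_out = []
        for c in range(s.chains):
            rng = np.random.default_rng(seeds[c])
            chains_out.append(self._run_chain(init, s, rng, jitter=(c > 0)))
        res = JointModelResults(self, s, chains_out, ml)
        bad = res.max_rhat()
        if bad is not None and bad[1] > rhat_threshold and on_bad_rhat != "ignore":
            msg = (
                f"MCMC convergence failure: split R-hat for {bad[0]} is "
                f"{bad[1]:.3f} > {rhat_threshold}"
            )
            if on_bad_rhat == "raise":
                raise ConvergenceError(msg, diagnostics=res.diagnostics())
            warnings.warn(msg, stacklevel=2)
        return res

    def _run_chain(self, init, s: MCMCSettings, rng, jitter: bool):
        d = self.design
        pr = self.priors
        n, q1 = d.n_subjects, d.n_random
        p = d.n_fixed

        theta = init["theta"].copy()
        log_sds = init["log_re_sds"].copy()
        log_sigma = float(init["log_sigma"])
        evec = init["evec"].copy()
        b = init["b"].copy()
        if jitter:
            theta = theta + rng.normal(0, 0.005, p)
            log_sds = log_sds + rng.normal(0, 0.05, q1)
            log_sigma += rng.normal(0, 0.02)
            evec = evec + rng.normal(0, 0.02, evec.size)

        XtX = d.X.T @ d.X
        n_iter = s.warmup + s.draws

        # adaptive proposal scales
        sd_step = np.full(q1, 0.1)
        sigma_step = 0.05
        coll_step = np.full(q1 + 1, 0.1)
        ev_dim = evec.size
        alpha_scale = {"value": 0.1, "value_slope": 0.1, "auc": 0.002}[self.association]
        ev_step = np.concatenate(
            [[0.05, 0.3, 0.2], np.full(self.n_alpha, alpha_scale)]
        )
        ev_chol = np.diag(ev_step)
        ev_scale = 1.0
        ev_hist = []

        evaluator = _EventLikelihood(self, s.n_quad)

        def event_ll_pw(evec_, theta_, b_):
            return evaluator.loglik(evec_, theta_, b_)

        def event_logprior(evec_):
            a, rate = pr.shape_gamma
            if evec_[0] > np.log(400.0):  # quadrature guard; prior mass ~e^-40
                return -np.inf
            shape_ = np.exp(evec_[0])
            lp = a * evec_[0] - rate * shape_  # Gamma on shape + log-Jacobian
            lp += -0.5 * np.sum((evec_[1:3] / pr.phi_sd) ** 2)
            lp += -0.5 * np.sum((evec_[3:] / pr.alpha_sd) ** 2)
            return lp

        ev_ll = event_ll_pw(evec, theta, b)
        ev_lp = event_logprior(evec)

        keep_theta = np.empty((s.draws, p))
        keep_sds = np.empty((s.draws, q1))
        keep_sigma = np.empty(s.draws)
        keep_evec = np.empty((s.draws, ev_dim))
        keep_b = np.empty((s.draws, n, q1))
        keep_dev = np.empty(s.draws)
        acc = {"b": 0.0, "theta": 0.0, "sds": 0.0, "sigma": 0.0, "collapsed": 0.0, "event": 0.0}

        for it in range(n_iter):
            warm = it < s.warmup
            gamma = min(0.25, 5.0 / np.sqrt(it + 10.0)) if warm else 0.0
            sig2 = np.exp(2.0 * log_sigma)
            Dinv = np.exp(-2.0 * log_sds) ** 1.0

            # --- (a) random effects: vectorised independence MH ---------
            r_fix = d.y - d.X @ theta
            M = d.ZtZ / sig2 + np.diag(Dinv)[None, :, :]
            C = np.linalg.inv(M)
            mu = np.einsum("nij,nj->ni", C, d.segment_sum_Zv(r_fix) / sig2)
            Lc = np.linalg.cholesky(C)
            z = rng.standard_normal((n, q1))
            b_prop = mu + np.einsum("nij,nj->ni", Lc, z)
            ev_ll_prop = event_ll_pw(evec, theta, b_prop)
            log_acc = ev_ll_prop - ev_ll
            accept = np.log(rng.uniform(size=n)) < log_acc
            b[accept] = b_prop[accept]
            ev_ll = np.where(accept, ev_ll_prop, ev_ll)
            acc["b"] += accept.mean() / n_iter

            # --- (b) fixed effects: independence MH ----------------------
            resid_b = d.y - d.Zb_rows(b)
            Prec = XtX / sig2 + np.eye(p) / pr.fixed_effect_sd**2
            Lp = np.linalg.cholesky(Prec)
            mean = np.linalg.solve(Prec, d.X.T @ resid_b / sig2)
            zt = rng.standard_normal(p)
            theta_prop = mean + np.linalg.solve(Lp.T, zt)
            ev_ll_prop = event_ll_pw(evec, theta_prop, b)
            if np.log(rng.uniform()) < (ev_ll_prop.sum() - ev_ll.sum()):
                theta = theta_prop
                ev_ll = ev_ll_prop
                acc["theta"] += 1.0 / n_iter

            # --- (c) residual SD: log-scale RWMH -------------------------
            r = d.y - d.X @ theta - d.Zb_rows(b)
            SS = float(r @ r)
            N = r.size

            def sigma_target(x):
                return (
                    -N * x
                    - 0.5 * SS * np.exp(-2.0 * x)
                    + _half_normal_logpdf(np.exp(x), pr.sigma_eps_scale)
                    + x
                )

            x_prop = log_sigma + sigma_step * rng.standard_normal()
            a_log = sigma_target(x_prop) - sigma_target(log_sigma)
            accepted = np.log(rng.uniform()) < a_log
            if accepted:
                log_sigma = float(x_prop)
            acc["sigma"] += accepted / n_iter
            if warm:
                sigma_step *= np.exp(gamma * ((1.0 if accepted else 0.0) - 0.44))

            # --- (d) RE SDs: independent per-coordinate RWMH -------------
            SSb = np.sum(b**2, axis=0)

            def sds_target(x):
                return (
                    -n * x
                    - 0.5 * SSb * np.exp(-2.0 * x)
                    + _half_normal_logpdf(np.exp(x), pr.re_sd_scale)
                    + x
                )

            x_prop = log_sds + sd_step * rng.standard_normal(q1)
            a_log = sds_target(x_prop) - sds_target(log_sds)
            accept_k = np.log(rng.uniform(size=q1)) < a_log
            log_sds = np.where(accept_k, x_prop, log_sds)
            acc["sds"] += accept_k.mean() / n_iter
            if warm:
                sd_step *= np.exp(gamma * (accept_k.astype(float) - 0.44))

            # --- (d2) collapsed variance move ----------------------------
            # Joint RW on all log-SDs with the random effects integrated
            # out of the longitudinal likelihood (Woodbury marginal) and a
            # fresh b drawn from the proposed conditional; the acceptance
            # ratio reduces to marginal-likelihood x prior x event terms.
            # This is what lets the chain traverse the sd ~ 0 funnel.
            r_fix = d.y - d.X @ theta
            Ztr_fix = d.segment_sum_Zv(r_fix)
            rr_fix = float(r_fix @ r_fix)

            def marginal_pieces(x_sds, x_sig):
                sig2_ = np.exp(2.0 * x_sig)
                M_ = d.ZtZ + sig2_ * np.diag(np.exp(-2.0 * x_sds))[None, :, :]
                L_ = np.linalg.cholesky(M_)
                e_ = np.linalg.solve(M_, Ztr_fix[..., None])[..., 0]
                quad = (rr_fix - float(np.einsum("nq,nq->", Ztr_fix, e_))) / sig2_
                logdetM = 2.0 * float(
                    np.log(np.diagonal(L_, axis1=1, axis2=2)).sum()
                )
                logdetV = (
                    (N - n * q1) * 2.0 * x_sig + logdetM + 2.0 * n * float(np.sum(x_sds))
                )
                ll = -0.5 * (N * LOG2PI + logdetV + quad)
                return ll, M_, e_, sig2_

            ml_cur, _, _, _ = marginal_pieces(log_sds, log_sigma)
            any_collapsed = False
            for k in range(q1 + 1):
                x_sds_prop = log_sds.copy()
                x_sig_prop = log_sigma
                if k < q1:
                    x_sds_prop[k] += coll_step[k] * rng.standard_normal()
                else:
                    x_sig_prop = log_sigma + coll_step[k] * rng.standard_normal()
                ml_prop, M_p, e_p, sig2_p = marginal_pieces(x_sds_prop, x_sig_prop)
                # fresh b* ~ p(b | y, theta, proposed variances)
                C_p = sig2_p * np.linalg.inv(M_p)
                Lc_p = np.linalg.cholesky(C_p)
                b_prop = e_p + np.einsum(
                    "nij,nj->ni", Lc_p, rng.standard_normal((n, q1))
                )
                ev_ll_prop = event_ll_pw(evec, theta, b_prop)
                dprior = float(
                    np.sum(
                        _half_normal_logpdf(np.exp(x_sds_prop), pr.re_sd_scale)
                        + x_sds_prop
                        - _half_normal_logpdf(np.exp(log_sds), pr.re_sd_scale)
                        - log_sds
                    )
                    + _half_normal_logpdf(np.exp(x_sig_prop), pr.sigma_eps_scale)
                    + x_sig_prop
                    - _half_normal_logpdf(np.exp(log_sigma), pr.sigma_eps_scale)
                    - log_sigma
                )
                a_log = (ml_prop - ml_cur) + dprior + (ev_ll_prop.sum() - ev_ll.sum())
                accepted = np.log(rng.uniform()) < a_log
                if accepted:
                    log_sds = x_sds_prop
                    log_sigma = float(x_sig_prop)
                    b = b_prop
                    ev_ll = ev_ll_prop
                    ml_cur = ml_prop
                    any_collapsed = True
                acc["collapsed"] += accepted / (n_iter * (q1 + 1))
                if warm:
                    coll_step[k] *= np.exp(gamma * ((1.0 if accepted else 0.0) - 0.44))
            if any_collapsed:
                r_new = d.y - d.X @ theta - d.Zb_rows(b)
                SS = float(r_new @ r_new)

            # --- (e) event block: adaptive joint RWMH (several moves) ----
            for _ in range(s.event_subiters):
                zv = rng.standard_normal(ev_dim)
                # occasional long jumps traverse the curved (shape, phi,
                # alpha) ridge that small adapted steps crawl along
                stretch = 4.0 if rng.uniform() < 0.15 else 1.0
                evec_prop = evec + stretch * ev_scale * (ev_chol @ zv)
                ev_ll_prop = event_ll_pw(evec_prop, theta, b)
                lp_prop = event_logprior(evec_prop)
                a_log = (ev_ll_prop.sum() + lp_prop) - (ev_ll.sum() + ev_lp)
                accepted = np.log(rng.uniform()) < a_log
                if accepted:
                    evec = evec_prop
                    ev_ll = ev_ll_prop
                    ev_lp = lp_prop
                acc["event"] += accepted / (n_iter * s.event_subiters)
                if warm:
                    ev_scale *= np.exp(gamma * ((1.0 if accepted else 0.0) - 0.28))
                    ev_hist.append(evec.copy())
            if warm and (it + 1) % 50 == 0 and len(ev_hist) >= 250:
                cov = np.cov(np.asarray(ev_hist[-2000:]).T)
                cov = cov + 1e-10 * np.eye(ev_dim)
                try:
                    ev_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass

            if not warm:
                k = it - s.warmup
                keep_theta[k] = theta
                keep_sds[k] = np.exp(log_sds)
                keep_sigma[k] = np.exp(log_sigma)
                keep_evec[k] = evec
                keep_b[k] = b
                # conditional deviance from quantities already in hand:
                # the longitudinal residual SS (theta, b unchanged since
                # step (c)) and the cached per-woman event log-likelihood
                long_ll = (
                    -0.5 * N * (LOG2PI + 2.0 * log_sigma)
                    - 0.5 * SS * np.exp(-2.0 * log_sigma)
                )
                keep_dev[k] = -2.0 * (long_ll + float(ev_ll.sum()))

        return {
            "theta": keep_theta,
            "re_sds": keep_sds,
            "sigma_eps": keep_sigma,
            "evec": keep_evec,
            "b": keep_b,
            "deviance": keep_dev,
            "acceptance": acc,
        }


class JointModelResults:
    """Posterior draws, diagnostics, DIC and summaries for a fitted model."""

    def __init__(self, model: JointModel, settings: MCMCSettings, chains, ml_fit):
        self.model = model
        self.settings = settings
        self._chains = chains
        self.ml_fit = ml_fit
        q = model.design.n_basis

        names = (
            ["beta0"]
            + [f"spline_{r}" for r in range(1, q + 1)]
            + ["beta_age", "beta_onset"]
        )
        names += [f"re_sd_{k}" for k in range(q + 1)]
        names += ["sigma_eps", "shape", "phi_intercept", "phi_nephropathy"]
        names += self.alpha_names
        self.param_names = names

    @property
    def alpha_names(self) -> list[str]:
        if self.model.association == "value_slope":
            return ["alpha_value", "alpha_slope"]
        return [f"alpha_{self.model.association}"]

    # -- draw access ------------------------------------------------------
    def stacked(self, key: str) -> np.ndarray:
        """Draws with chain axis first: (chains, draws, ...)."""
        return np.stack([c[key] for c in self._chains])

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Population-parameter draws as name -> (chains, draws)."""
        theta = self.stacked("theta")
        sds = self.stacked("re_sds")
        sig = self.stacked("sigma_eps")
        evec = self.stacked("evec")
        out = {}
        for j, name in enumerate(self.param_names):
            if j < theta.shape[-1]:
                out[name] = theta[..., j]
            elif j < theta.shape[-1] + sds.shape[-1]:
                out[name] = sds[..., j - theta.shape[-1]]
            elif name == "sigma_eps":
                out[name] = sig
            elif name == "shape":
                out[name] = np.exp(evec[..., 0])
            elif name == "phi_intercept":
                out[name] = evec[..., 1]
            elif name == "phi_nephropathy":
                out[name] = evec[..., 2]
            else:
                out[name] = evec[..., 3 + self.alpha_names.index(name)]
        return out

    @property
    def n_draws(self) -> int:
        return sum(c["theta"].shape[0] for c in self._chains)

    def random_effects_draws(self) -> np.ndarray:
        """(chains, draws, n_subjects, 1 + n_basis)."""
        return self.stacked("b")

    # -- diagnostics -------------------------------------------------------
    def _azdata(self):
        import arviz as az

        return az.from_dict(posterior=self.scalar_draws())

    def rhat(self) -> pd.Series:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(self._azdata())
        return pd.Series({k: float(r[k].values) for k in self.scalar_draws()})

    def ess(self) -> pd.Series:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = az.ess(self._azdata())
        return pd.Series({k: float(e[k].values) for k in self.scalar_draws()})

    def max_rhat(self):
        r = self.rhat().dropna()
        if r.empty:
            return None
        name = r.idxmax()
        return name, float(r[name])

    def diagnostics(self) -> dict:
        return {
            "rhat": self.rhat().to_dict(),
            "ess": self.ess().to_dict(),
            "acceptance": [c["acceptance"] for c in self._chains],
        }

    # -- DIC ---------------------------------------------------------------
    def dic(self, recompute: bool = False) -> tuple[float, float]:
        """(DIC, pD), conditional on the random effects.

        With ``recompute=True`` the per-draw deviances are re-evaluated
        from the stored draws rather than taken from the sampling run
        (bit-identical either way; used for persistence round-trips).
        """
        if recompute:
            dev = []
            for c in self._chains:
                for k in range(c["theta"].shape[0]):
                    dev.append(
                        self.model._deviance(
                            c["theta"][k],
                            c["b"][k],
                            c["sigma_eps"][k],
                            c["evec"][k],
                            self.settings.n_quad,
                        )
                    )
            dev = np.asarray(dev)
        else:
            dev = np.concatenate([c["deviance"] for c in self._chains])
        dbar = float(np.mean(dev))
        theta_bar = self.stacked("theta").mean(axis=(0, 1))
        b_bar = self.stacked("b").mean(axis=(0, 1))
        sigma_bar = float(self.stacked("sigma_eps").mean())
        evec_bar = self.stacked("evec").mean(axis=(0, 1))
        d_at_mean = self.model._deviance(
            theta_bar, b_bar, sigma_bar, evec_bar, self.settings.n_quad
        )
        pd_ = dbar - d_at_mean
        if pd_ < 0:
            warnings.warn(
                f"negative pD ({pd_:.1f}): posterior means fit worse than the "
                "average draw; DIC is unreliable here",
                stacklevel=2,
            )
        return dbar + pd_, pd_

    # -- summaries ----------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, 2.5/50/97.5%, R-hat, ESS)."""
        draws = self.scalar_draws()
        rhat = self.rhat()
        ess = self.ess()
        rows = []
        for name, x in draws.items():
            flat = x.reshape(-1)
            rows.append(
                {
                    "param": name,
                    "mean": float(np.mean(flat)),
                    "sd": float(np.std(flat)),
                    "2.5%": float(np.quantile(flat, 0.025)),
                    "50%": float(np.quantile(flat, 0.5)),
                    "97.5%": float(np.quantile(flat, 0.975)),
                    "rhat": float(rhat.get(name, np.nan)),
                    "ess": float(ess.get(name, np.nan)),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def credible_interval(self, name: str, level: float = 0.95):
        x = self.scalar_draws()[name].reshape(-1)
        a = 0.5 * (1.0 - level)
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Persist draws + spec to a self-describing .npz container."""
        meta = {
            "association": self.model.association,
            "basis": self.model.basis.to_dict(),
            "settings": {
                "chains": self.settings.chains,
                "warmup": self.settings.warmup,
                "draws": self.settings.draws,
                "seed": self.settings.seed,
            },
            "param_names": self.param_names,
        }
        import json

        arrays = {}
        for i, c in enumerate(self._chains):
            for key in ("theta", "re_sds", "sigma_eps", "evec", "b", "deviance"):
                arrays[f"chain{i}_{key}"] = c[key]
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, cohort: CohortData) -> "JointModelResults":
        """Rebuild results from a saved container plus the original cohort."""
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            settings = MCMCSettings(**meta["settings"])
            chains = []
            for i in range(settings.chains):
                chains.append(
                    {
                        key: z[f"chain{i}_{key}"]
                        for key in ("theta", "re_sds", "sigma_eps", "evec", "b", "deviance")
                    }
                )
                chains[-1]["acceptance"] = {}
        model = JointModel(
            cohort,
            association=meta["association"],
            basis=NaturalCubicSplineBasis.from_dict(meta["basis"]),
        )
        return cls(model, settings, chains, ml_fit=None)


def compare_structures(
    cohort: CohortData,
    basis: NaturalCubicSplineBasis | None = None,
    n_interior_knots: int = 4,
    settings: MCMCSettings | None = None,
    priors: Priors | None = None,
    on_bad_rhat: str = "warn",
    associations=ev.ASSOCIATIONS,
) -> pd.DataFrame:
    """Fit all three association structures and rank them by DIC.

    Each structure is fitted with the same seed policy; a structure whose
    fit raises is marked failed and excluded from the ranking (the run
    continues).  Returns a table with columns {association, DIC, pD,
    status, max_rhat} sorted ascending by DIC, failures last.
    """
    settings = settings or MCMCSettings()
    rows = []
    fits = {}
    for assoc in associations:
        try:
            model = JointModel(
                cohort,
                association=assoc,
                basis=basis,
                n_interior_knots=n_interior_knots,
                priors=priors,
            )
            res = model.fit(settings, on_bad_rhat=on_bad_rhat)
            dic, pd_ = res.dic()
            mr = res.max_rhat()
            rows.append(
                {
                    "association": assoc,
                    "DIC": dic,
                    "pD": pd_,
                    "status": "ok",
                    "max_rhat": mr[1] if mr else np.nan,
                }
            )
            fits[assoc] = res
        except Exception as exc:  # noqa: BLE001 - structure-level robustness
            warnings.warn(f"association {assoc!r} failed: {exc}", stacklevel=2)
            rows.append(
                {
                    "association": assoc,
                    "DIC": np.nan,
                    "pD": np.nan,
                    "status": f"failed: {exc}",
                    "max_rhat": np.nan,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        "DIC", na_position="last", kind="stable"
    ).reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
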