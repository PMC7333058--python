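"""Spline mixed-effects longitudinal submodel.

Log-glucose for woman ``i`` at gestational day ``t_ij`` is

    y_ij = beta0 + f(t_ij) + beta_age * z_age_i + beta_onset * z_onset_i
           + b_i0 + sum_r b_ir * lambda_r(t_ij) + eps_ij

with ``f`` a natural cubic spline (fixed part), subject-specific random
coefficients ``b_i ~ N(0, diag(sd_k^2))`` — mutually independent, one
variance per effect — and Gaussian measurement error
``eps_ij ~ N(0, sigma_eps^2)``.

:class:`LongitudinalMixedModel` provides the maximum-(marginal-)likelihood
fitting variant used for BIC knot selection and for initialising the
Bayesian joint sampler.  The marginal likelihood integrates the random
effects analytically (each woman contributes a multivariate-normal
density with covariance ``sigma^2 I + Z_i D Z_i'``), evaluated through
the Woodbury identity so the per-woman cost is cubic in the random-effect
dimension, not the reading count.  Headline inference never uses this
fit; it belongs to the joint model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .basis import NaturalCubicSplineBasis
from .config import standardize_ages
from .data import CohortData
from .trajectories import LatentTrajectories

__all__ = [
    "LongitudinalDesign",
    "LongitudinalParams",
    "LongitudinalMixedModel",
    "LongitudinalMLResults",
    "m_value",
    "m_slope",
    "m_auc",
]


class FitConvergenceError(RuntimeError):
    """Optimiser failed; carries the scipy diagnostics payload."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


@dataclass
class LongitudinalParams:
    """Fixed effects and variance components of the longitudinal submodel."""

    beta0: float
    spline_coefs: np.ndarray
    beta_age: float
    beta_onset: float
    re_sds: np.ndarray      # (1 + n_basis,) — intercept first
    sigma_eps: float

    def __post_init__(self) -> None:
        self.spline_coefs = np.asarray(self.spline_coefs, dtype=float)
        self.re_sds = np.asarray(self.re_sds, dtype=float)
        if np.any(self.re_sds <= 0) or self.sigma_eps <= 0:
            raise ValueError("all SDs must be positive")
        if self.re_sds.size != self.spline_coefs.size + 1:
            raise ValueError("re_sds must be 1 + len(spline_coefs)")

    @property
    def theta(self) -> np.ndarray:
        """Fixed-effect vector in design order [beta0, splines, age, onset]."""
        return np.concatenate(
            [[self.beta0], self.spline_coefs, [self.beta_age, self.beta_onset]]
        )

    @classmethod
    def from_theta(cls, theta, re_sds, sigma_eps) -> "LongitudinalParams":
        theta = np.asarray(theta, dtype=float)
        return cls(
            beta0=float(theta[0]),
            spline_coefs=theta[1:-2].copy(),
            beta_age=float(theta[-2]),
            beta_onset=float(theta[-1]),
            re_sds=np.asarray(re_sds, dtype=float),
            sigma_eps=float(sigma_eps),
        )

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "spline_coefs": self.spline_coefs.tolist(),
            "beta_age": self.beta_age,
            "beta_onset": self.beta_onset,
            "re_sds": self.re_sds.tolist(),
            "sigma_eps": self.sigma_eps,
        }


class LongitudinalDesign:
    """Per-reading design matrices plus per-woman index bookkeeping.

    Fixed design ``X`` = [1, basis(t), z_age, z_onset]; random design
    ``Z`` = [1, basis(t)].  Rows are grouped by woman (stable order of
    first appearance in the subjects table) so per-woman segments are
    contiguous; ``offsets`` delimits them for `reduceat`-style sums.
    """

    def __init__(self, cohort: CohortData, basis: NaturalCubicSplineBasis):
        subj = cohort.subjects
        for col in ("age_lmp", "age_onset"):
            missing = subj[col].isna()
            if missing.any():
                raise ValueError(
                    f"missing covariate {col} for woman id(s) "
                    f"{subj.loc[missing, 'id'].tolist()}"
                )
        order = {sid: k for k, sid in enumerate(subj["id"])}
        lon = cohort.longitudinal.copy()
        lon["_k"] = lon["id"].map(order)
        lon = lon.sort_values(["_k", "day"], kind="stable").reset_index(drop=True)

        self.basis = basis
        self.cohort = cohort
        self.ids = subj["id"].to_numpy()
        self.n_subjects = len(subj)
        self.y = lon["log_glucose"].to_numpy(dtype=float)
        self.days = lon["day"].to_numpy(dtype=float)
        self.woman_index = lon["_k"].to_numpy()
        counts = np.bincount(self.woman_index, minlength=self.n_subjects)
        if np.any(counts == 0):
            raise ValueError("every woman needs at least one reading")
        self.counts = counts
        self.offsets = np.concatenate([[0], np.cumsum(counts)])

        z_age, z_onset = standardize_ages(
            subj["age_lmp"].to_numpy(), subj["age_onset"].to_numpy()
        )
        self.z_age = z_age
        self.z_onset = z_onset
        self.nephropathy = subj["nephropathy"].to_numpy(dtype=float)

        B = basis.evaluate(self.days)  # (N, q)
        ones = np.ones((len(lon), 1))
        self.Z = np.concatenate([ones, B], axis=1)
        self.X = np.concatenate(
            [ones, B, z_age[self.woman_index, None], z_onset[self.woman_index, None]],
            axis=1,
        )
        # per-woman Z_i' Z_i, precomputed once for Woodbury / conditionals
        qz = self.Z.shape[1]
        self.ZtZ = np.zeros((self.n_subjects, qz, qz))
        for i in range(self.n_subjects):
            Zi = self.Z[self.offsets[i]: self.offsets[i + 1]]
            self.ZtZ[i] = Zi.T @ Zi

    # ------------------------------------------------------------------
    @property
    def n_basis(self) -> int:
        return self.basis.n_basis

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]

    def segment_sum_Zv(self, v: np.ndarray) -> np.ndarray:
        """Per-woman ``Z_i' v_i`` as an (n, q+1) array."""
        return np.add.reduceat(self.Z * v[:, None], self.offsets[:-1], axis=0)

    def Zb_rows(self, b: np.ndarray) -> np.ndarray:
        """Row-wise ``Z_ij' b_i`` for a full random-effects matrix b (n, q+1)."""
        return np.einsum("nj,nj->n", self.Z, b[self.woman_index])

    def trajectories(self, theta: np.ndarray, b: np.ndarray) -> LatentTrajectories:
        """Latent per-woman trajectories for fixed effects + random effects."""
        q = self.n_basis
        const = (
            theta[0]
            + b[:, 0]
            + theta[q + 1] * self.z_age
            + theta[q + 2] * self.z_onset
        )
        coefs = theta[1: q + 1] + b[:, 1:]
        return LatentTrajectories(self.basis, const, coefs)


def design_matrices(cohort: CohortData, basis: NaturalCubicSplineBasis):
    """(fixed, random) design matrices, row order matching the design sort."""
    d = LongitudinalDesign(cohort, basis)
    return d.X, d.Z


# ----------------------------------------------------------------------
# trajectory functionals (latent mean and its derivative / running AUC)
# ----------------------------------------------------------------------
def _single_traj(params: LongitudinalParams, b_i, covariates, basis) -> LatentTrajectories:
    b_i = np.asarray(b_i, dtype=float)
    z_age, z_onset = standardize_ages(
        [covariates["age_lmp"]], [covariates["age_onset"]]
    )
    const = params.beta0 + b_i[0] + params.beta_age * z_age[0] + params.beta_onset * z_onset[0]
    coefs = params.spline_coefs + b_i[1:]
    return LatentTrajectories(basis, np.array([const]), coefs[None, :])


def m_value(params, b_i, covariates, basis, t) -> np.ndarray:
    """Latent mean log-glucose m_i(t) at day(s) t."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return _single_traj(params, b_i, covariates, basis).value(t[None, :])[0]


def m_slope(params, b_i, covariates, basis, t) -> np.ndarray:
    """Exact derivative dm_i/dt; baseline covariates contribute zero."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return _single_traj(params, b_i, covariates, basis).slope(t[None, :])[0]


def m_auc(params, b_i, covariates, basis, t0, t1) -> float:
    """Analytic ``int_{t0}^{t1} m_i(s) ds`` (log-glucose x day)."""
    if t0 > t1:
        raise ValueError("m_auc requires t0 <= t1")
    tr = _single_traj(params, b_i, covariates, basis)
    return float(tr.auc(np.array([[t1]]), lower=t0)[0, 0])


# ----------------------------------------------------------------------
@dataclass
class LongitudinalMLResults:
    """Maximum-likelihood fit of the longitudinal submodel."""

    params: LongitudinalParams
    random_effects: np.ndarray   # empirical-Bayes modes, (n, 1 + n_basis)
    llf: float
    bic: float
    n_params: int
    n_obs: int
    design: LongitudinalDesign
    optimizer: object = None

    def summary(self) -> pd.DataFrame:
        p = self.params
        rows = {"beta0": p.beta0}
        rows.update({f"spline_{r}": c for r, c in enumerate(p.spline_coefs, 1)})
        rows.update(
            {
                "beta_age": p.beta_age,
                "beta_onset": p.beta_onset,
                **{f"re_sd_{k}": s for k, s in enumerate(p.re_sds)},
                "sigma_eps": p.sigma_eps,
            }
        )
        df = pd.DataFrame({"estimate": rows})
        df.attrs["llf"] = self.llf
        df.attrs["bic"] = self.bic
        return df


class LongitudinalMixedModel:
    """ML variant of the spline mixed model (for knot selection / inits)."""

    def __init__(self, cohort: CohortData, basis: NaturalCubicSplineBasis):
        if cohort.n_subjects < 2:
            raise ValueError("need at least two women to fit the mixed model")
        self.design = LongitudinalDesign(cohort, basis)

    # -- marginal log-likelihood machinery -------------------------------
    def _profile_pieces(self, log_sds: np.ndarray, log_sigma: np.ndarray):
        """Per-woman Woodbury pieces at given variance parameters.

        Returns (theta_hat by GLS, profile log-likelihood at theta_hat).
        """
        d = self.design
        sds = np.exp(log_sds)
        sig2 = np.exp(2.0 * log_sigma)
        Dinv = np.diag(1.0 / sds**2)
        n, q = d.n_subjects, d.n_random

        # M_i = sigma^2 D^{-1} + Z_i'Z_i ;  V_i^{-1} = (I - Z M^{-1} Z')/sigma^2
        M = d.ZtZ + sig2 * Dinv
        L = np.linalg.cholesky(M)
        XtVX = np.zeros((d.n_fixed, d.n_fixed))
        XtVy = np.zeros(d.n_fixed)
        # accumulate X'V^{-1}X etc. via per-woman low-rank corrections
        ZtX = np.add.reduceat(
            d.Z[:, :, None] * d.X[:, None, :], d.offsets[:-1], axis=0
        )  # (n, q, p)
        Zty = d.segment_sum_Zv(d.y)  # (n, q)
        XtX = d.X.T @ d.X
        Xty = d.X.T @ d.y
        # solve M_i a_i = ZtX_i, M_i c_i = Zty_i  (batched)
        a = np.linalg.solve(M, ZtX)      # (n, q, p)
        c = np.linalg.solve(M, Zty[..., None])[..., 0]  # (n, q)
        XtVX = (XtX - np.einsum("nqp,nqr->pr", ZtX, a)) / sig2
        XtVy = (Xty - np.einsum("nqp,nq->p", ZtX, c)) / sig2
        theta = np.linalg.solve(XtVX, XtVy)

        r = d.y - d.X @ theta
        Ztr = d.segment_sum_Zv(r)
        e = np.linalg.solve(M, Ztr[..., None])[..., 0]
        quad = (r @ r - np.einsum("nq,nq->", Ztr, e)) / sig2

        # log|V_i| = n_i log sigma^2 + log|M_i| - q log sigma^2 + log|sigma^2 D| ... use
        # |V| = sigma^{2(n_i - q)} |M_i| |D|  (matrix determinant lemma)
        logdetM = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        logdetD = 2.0 * np.sum(np.log(sds)) * n
        N = d.y.size
        logdetV = (N - n * q) * np.log(sig2) + logdetM + logdetD
        llf = -0.5 * (N * np.log(2 * np.pi) + logdetV + quad)
        return theta, llf

    def loglike(self, params: LongitudinalParams) -> float:
        """Marginal log-likelihood at arbitrary parameter values."""
        d = self.design
        sds, sig2 = params.re_sds, params.sigma_eps**2
        Dinv = np.diag(1.0 / sds**2)
        M = d.ZtZ + sig2 * Dinv
        r = d.y - d.X @ params.theta
        Ztr = d.segment_sum_Zv(r)
        e = np.linalg.solve(M, Ztr[..., None])[..., 0]
        quad = (r @ r - np.einsum("nq,nq->", Ztr, e)) / sig2
        L = np.linalg.cholesky(M)
        logdetM = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        n, q, N = d.n_subjects, d.n_random, d.y.size
        logdetV = (N - n * q) * np.log(sig2) + logdetM + 2 * n * np.sum(np.log(sds))
        return float(-0.5 * (N * np.log(2 * np.pi) + logdetV + quad))

    def empirical_bayes(self, params: LongitudinalParams) -> np.ndarray:
        """Conditional modes of the random effects given the data."""
        d = self.design
        sig2 = params.sigma_eps**2
        Dinv = np.diag(1.0 / params.re_sds**2)
        M = d.ZtZ / sig2 + Dinv
        r = d.y - d.X @ params.theta
        Ztr = d.segment_sum_Zv(r) / sig2
        return np.linalg.solve(M, Ztr[..., None])[..., 0]

    def fit(self, start_log_sds=None, start_log_sigma=None) -> LongitudinalMLResults:
        d = self.design
        q = d.n_random
        resid_sd = np.std(d.y - d.X @ np.linalg.lstsq(d.X, d.y, rcond=None)[0])
        # random-effect SDs typically sit well below the total residual SD
        x0 = np.concatenate(
            [
                start_log_sds if start_log_sds is not None
                else np.full(q, np.log(max(resid_sd / 3.0, 2e-2))),
                [start_log_sigma if start_log_sigma is not None
                 else np.log(max(resid_sd, 1e-3))],
            ]
        )

        def nll(x):
            try:
                _, llf = self._profile_pieces(x[:-1], x[-1])
            except np.linalg.LinAlgError:
                return 1e12
            if not np.isfinite(llf):
                return 1e12
            return -llf

        # SDs bounded below at e^-4 (~0.018 on the log-glucose scale): a
        # variance component this small is numerically zero for these data
        # and an unbounded search crawls along the boundary
        res = minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(-4.0, 2.0)] * (q + 1),
            options={"maxiter": 500, "ftol": 2e-12, "gtol": 1e-8},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise FitConvergenceError("marginal likelihood optimisation failed", res)
        theta, llf = self._profile_pieces(res.x[:-1], res.x[-1])
        params = LongitudinalParams.from_theta(
            theta, np.exp(res.x[:-1]), float(np.exp(res.x[-1]))
        )
        n_params = d.n_fixed + q + 1
        bic = -2.0 * llf + n_params * np.log(d.y.size)
        return LongitudinalMLResults(
            params=params,
            random_effects=self.empirical_bayes(params),
            llf=float(llf),
            bic=float(bic),
            n_params=n_params,
            n_obs=d.y.size,
            design=d,
            optimizer=res,
        )
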