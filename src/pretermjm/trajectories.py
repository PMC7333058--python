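"""Latent (noise-free) glucose trajectories.

Each woman's true log-glucose process is

    m_i(day) = const_i + sum_r coef_{ir} * lambda_r(day)

where ``const_i`` collects the population intercept, her random
intercept and her baseline-covariate contribution, and ``coef_i`` are
the population-plus-random spline coefficients.  This container holds
the per-woman ``(const, coef)`` pairs for a whole cohort and evaluates
the three functionals the event submodel links to the hazard: the
current value, the slope, and the running area under the curve (AUC,
integrated from the window origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import NaturalCubicSplineBasis

__all__ = ["LatentTrajectories"]


@dataclass
class LatentTrajectories:
    basis: NaturalCubicSplineBasis
    const: np.ndarray  # (n,)
    coefs: np.ndarray  # (n, n_basis)

    def __post_init__(self) -> None:
        self.const = np.atleast_1d(np.asarray(self.const, dtype=float))
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        if self.coefs.shape != (self.const.size, self.basis.n_basis):
            raise ValueError(
                f"coefs shape {self.coefs.shape} incompatible with "
                f"{self.const.size} subjects x {self.basis.n_basis} basis functions"
            )

    @property
    def n_subjects(self) -> int:
        return self.const.size

    def _pad(self, days: np.ndarray) -> tuple[np.ndarray, tuple]:
        """Broadcast helper: days has shape (n, ...) or (n,)."""
        days = np.asarray(days, dtype=float)
        extra = days.ndim - 1
        idx = (slice(None),) + (None,) * extra
        return days, idx

    def value(self, days) -> np.ndarray:
        """m_i evaluated at per-woman day arrays of shape ``(n, ...)``."""
        days, idx = self._pad(days)
        P = self.basis.evaluate(days)  # (n, ..., q)
        return self.const[idx] + np.sum(P * self.coefs[idx + (slice(None),)], axis=-1)

    def slope(self, days) -> np.ndarray:
        """dm_i/dday; the constant and covariate terms contribute zero."""
        days, idx = self._pad(days)
        P = self.basis.derivative(days)
        return np.sum(P * self.coefs[idx + (slice(None),)], axis=-1)

    def auc(self, days, lower: float | None = None) -> np.ndarray:
        """Running integral of m_i from the window origin (or ``lower``)."""
        days, idx = self._pad(days)
        if lower is None:
            lower = self.basis.boundary[0]
        P = self.basis.integral(lower, days)
        return self.const[idx] * (days - lower) + np.sum(
            P * self.coefs[idx + (slice(None),)], axis=-1
        )

    def subset(self, rows) -> "LatentTrajectories":
        rows = np.atleast_1d(rows)
        return LatentTrajectories(self.basis, self.const[rows], self.coefs[rows])
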