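"""Natural cubic spline bases over gestational time.

The longitudinal submodel represents the population and subject-level
glucose trajectory as a linear combination of natural cubic spline basis
functions of gestational day.  A natural cubic spline is a cubic spline
constrained to be *linear* beyond its boundary knots, which makes modest
extrapolation (needed by dynamic risk prediction, which looks past a
woman's last reading) well behaved.

The basis is assembled from cubic B-splines on the knot vector
(boundary knots repeated to full multiplicity).  With ``m`` interior
knots there are ``m + 4`` cubic B-splines; imposing the two natural
constraints (second derivative zero at each boundary) and removing the
constant function leaves ``m + 1`` basis functions.  The constraint /
intercept reduction is done in coefficient space: the transform matrix
spans the null space of the boundary-curvature constraints orthogonal to
the all-ones coefficient vector (the constant function, by partition of
unity).  The intercept is deliberately *excluded* because the mixed
model carries its own intercept; an intercept column here would make the
fixed-effect design rank deficient.

Compact support keeps the evaluation matrix well conditioned even at
large knot counts, which matters for identifying per-coefficient
random-effect variances.  Derivatives and antiderivatives are exact
(B-spline calculus via :class:`scipy.interpolate.BSpline`); beyond the
boundary knots every basis function continues *linearly* (its curvature
there is zero by construction), so extrapolation — needed by dynamic
risk prediction past a woman's last reading — is well behaved, and the
linear tails are integrated in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["NaturalCubicSplineBasis", "build_basis", "select_knots_bic"]

DEFAULT_BOUNDARY = (50.0, 260.0)


class DegenerateKnotsError(ValueError):
    """Quantile knot placement produced coincident knots."""


@dataclass(frozen=True)
class NaturalCubicSplineBasis:
    """Natural cubic spline basis on a gestational-day window.

    Parameters
    ----------
    boundary
        (lower, upper) gestational days; the spline is linear outside.
    interior_knots
        Strictly increasing knot locations strictly inside the boundary.
    """

    boundary: tuple[float, float] = DEFAULT_BOUNDARY
    interior_knots: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        a, b = self.boundary
        if not a < b:
            raise ValueError(f"boundary must be increasing, got {self.boundary}")
        knots = np.asarray(self.interior_knots, dtype=float)
        object.__setattr__(self, "interior_knots", knots)
        if knots.size < 1:
            raise ValueError("need at least one interior knot")
        if np.any(np.diff(knots) <= 0):
            raise DegenerateKnotsError(
                f"interior knots must be strictly increasing, got {knots}"
            )
        if knots[0] <= a or knots[-1] >= b:
            raise ValueError(
                f"interior knots {knots} must lie strictly inside {self.boundary}"
            )
        t_knots = np.concatenate([[a] * 4, knots, [b] * 4])
        n_b = knots.size + 4  # cubic B-splines on the augmented knot vector
        # boundary-curvature constraints C (2, n_b): f''(a) = f''(b) = 0
        eye = np.eye(n_b)
        base = BSpline(t_knots, eye, 3, extrapolate=True)
        d2 = base.derivative(2)
        C = d2(np.array([a, b]))  # (2, n_b)
        ones = np.ones((n_b, 1))
        # null space of C orthogonal (coefficient space) to the constant
        Q, _ = np.linalg.qr(np.hstack([C.T, ones]), mode="complete")
        T = Q[:, 3:]  # (n_b, m + 1)
        spl = BSpline(t_knots, T, 3, extrapolate=True)
        object.__setattr__(self, "_spl", spl)
        object.__setattr__(self, "_dspl", spl.derivative())
        object.__setattr__(self, "_aspl", spl.antiderivative())
        # boundary values/slopes for the linear tails
        object.__setattr__(self, "_edge_val", spl(np.array([a, b])))
        object.__setattr__(self, "_edge_slope", spl.derivative()(np.array([a, b])))
        object.__setattr__(self, "_edge_anti", spl.antiderivative()(np.array([a, b])))

    # ------------------------------------------------------------------
    @property
    def n_basis(self) -> int:
        """Number of basis functions (= interior knot count + 1)."""
        return self.interior_knots.size + 1

    # -- public API -----------------------------------------------------
    def evaluate(self, t) -> np.ndarray:
        """Basis matrix at gestational days ``t`` (shape ``t.shape + (n_basis,)``).

        Extrapolation beyond the boundary is allowed and linear by the
        natural-spline construction.
        """
        t = np.asarray(t, dtype=float)
        a, b = self.boundary
        tc = np.clip(t, a, b)
        out = self._spl(tc)
        lo = t < a
        hi = t > b
        if np.any(lo):
            out[lo] = self._edge_val[0] + (t[lo] - a)[..., None] * self._edge_slope[0]
        if np.any(hi):
            out[hi] = self._edge_val[1] + (t[hi] - b)[..., None] * self._edge_slope[1]
        return out

    def derivative(self, t) -> np.ndarray:
        """Exact first derivative of each basis function w.r.t. day."""
        t = np.asarray(t, dtype=float)
        a, b = self.boundary
        tc = np.clip(t, a, b)
        out = self._dspl(tc)
        lo = t < a
        hi = t > b
        if np.any(lo):
            out[lo] = self._edge_slope[0]
        if np.any(hi):
            out[hi] = self._edge_slope[1]
        return out

    def antiderivative(self, t) -> np.ndarray:
        """Exact antiderivative (zero at the lower boundary) of each basis
        function, with the linear tails integrated in closed form."""
        t = np.asarray(t, dtype=float)
        a, b = self.boundary
        tc = np.clip(t, a, b)
        out = self._aspl(tc)
        lo = t < a
        hi = t > b
        if np.any(lo):
            dt = (t[lo] - a)[..., None]
            out[lo] = self._edge_anti[0] + self._edge_val[0] * dt \
                + 0.5 * self._edge_slope[0] * dt**2
        if np.any(hi):
            dt = (t[hi] - b)[..., None]
            out[hi] = self._edge_anti[1] + self._edge_val[1] * dt \
                + 0.5 * self._edge_slope[1] * dt**2
        return out

    def integral(self, t0, t1) -> np.ndarray:
        """Exact ``\\int_{t0}^{t1} lambda_r(s) ds`` for every basis function.

        ``t0`` may be scalar with array ``t1`` (broadcast); requires
        ``t0 <= t1`` elementwise.
        """
        t0 = np.asarray(t0, dtype=float)
        t1 = np.asarray(t1, dtype=float)
        if np.any(t0 > t1 + 1e-12):
            raise ValueError("integral requires t0 <= t1")
        return self.antiderivative(t1) - self.antiderivative(t0)

    def to_dict(self) -> dict:
        return {
            "boundary": [float(self.boundary[0]), float(self.boundary[1])],
            "interior_knots": [float(k) for k in self.interior_knots],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalCubicSplineBasis":
        return cls(tuple(d["boundary"]), np.asarray(d["interior_knots"]))


def build_basis(
    boundary: tuple[float, float] = DEFAULT_BOUNDARY,
    n_interior_knots: int = 4,
    knot_rule: str = "uniform",
    observation_times=None,
) -> NaturalCubicSplineBasis:
    """Construct a natural cubic spline basis with automatic knot placement.

    ``knot_rule='uniform'`` places interior knots equally spaced inside the
    boundary; ``'quantile'`` places them at empirical quantiles of
    ``observation_times`` (the usual choice for irregularly sampled
    longitudinal data).
    """
    if n_interior_knots < 1:
        raise ValueError("n_interior_knots must be >= 1")
    a, b = boundary
    probs = np.arange(1, n_interior_knots + 1) / (n_interior_knots + 1)
    if knot_rule == "uniform":
        knots = a + probs * (b - a)
    elif knot_rule == "quantile":
        if observation_times is None:
            raise ValueError("knot_rule='quantile' requires observation_times")
        times = np.asarray(observation_times, dtype=float)
        if times.size == 0:
            raise ValueError("observation_times is empty")
        if np.any(times < a - 30) or np.any(times > b + 30):
            raise ValueError(
                "observation_times outside a plausible gestational-day range "
                f"[{a - 30}, {b + 30}]"
            )
        knots = np.quantile(times, probs)
        if np.any(np.diff(knots) <= 0):
            bad = probs[np.concatenate([[False], np.diff(knots) <= 0])]
            raise DegenerateKnotsError(
                "quantile knot placement produced coincident knots at "
                f"quantiles {bad}; reduce the knot count"
            )
        # keep knots strictly interior even with ties at the extremes
        eps = 1e-6 * (b - a)
        knots = np.clip(knots, a + eps, b - eps)
    else:
        raise ValueError(f"unknown knot_rule {knot_rule!r}")
    return NaturalCubicSplineBasis(boundary=(float(a), float(b)), interior_knots=knots)


def select_knots_bic(cohort, candidate_counts, knot_rule: str = "quantile"):
    """Choose an interior-knot count by BIC of the maximum-likelihood
    longitudinal mixed-model fit.

    Fits the spline mixed model once per candidate count and returns the
    count with the smallest BIC; ties (within 1e-6) break toward fewer
    knots.  Candidates whose fit fails are excluded with a warning.
    """
    from .longitudinal import LongitudinalMixedModel  # circular-at-module-level

    candidate_counts = list(candidate_counts)
    if not candidate_counts:
        raise ValueError("candidate_counts is empty")
    results = {}
    for m in sorted(candidate_counts):
        try:
            basis = build_basis(
                n_interior_knots=m,
                knot_rule=knot_rule,
                observation_times=cohort.longitudinal["day"].to_numpy(),
            )
            fit = LongitudinalMixedModel(cohort, basis).fit()
            results[m] = fit.bic
        except Exception as exc:  # noqa: BLE001 - candidate-level robustness
            warnings.warn(f"knot candidate {m} failed to fit: {exc}", stacklevel=2)
    if not results:
        raise RuntimeError("all knot candidates failed to fit")
    best = min(results, key=lambda m: (round(results[m] / 1e-6) * 1e-6, m))
    return best
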