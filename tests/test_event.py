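"""Weibull event submodel: closed forms, quadrature, nesting, generator link."""

import numpy as np
import pytest
from scipy.integrate import quad

from pretermjm import event as ev
from pretermjm.basis import build_basis
from pretermjm.config import GeneratorConfig
from pretermjm.simulate import generate_cohort
from pretermjm.trajectories import LatentTrajectories

from conftest import ALPHA0_PHI, REDUCED_INTENSITY


@pytest.fixture(scope="module")
def flat_traj():
    """Constant latent trajectory m(t) = 4.7 (spline part zeroed)."""
    basis = build_basis(n_interior_knots=2)
    return LatentTrajectories(basis, np.array([4.7]), np.zeros((1, 3)))


@pytest.fixture(scope="module")
def wiggly_traj():
    basis = build_basis(n_interior_knots=4)
    return LatentTrajectories(
        basis, np.array([4.8]), np.array([[-0.3, 0.5, -0.4, 0.3, -0.2]])
    )


def _params(shape=1.0, phi=(0.0, 0.0), alpha=(0.0,), assoc="value", t_scale=1.0):
    return ev.EventParams(
        shape=shape, phi=np.array(phi), alpha=np.array(alpha),
        association=assoc, t_scale=t_scale,
    )


def test_shape_one_alpha_zero_hazard_is_constant(flat_traj):
    t = np.array([[1.0, 30.0, 100.0, 200.0]])
    h = ev.hazard(_params(shape=1.0), flat_traj, np.array([0.3]), t)
    np.testing.assert_allclose(h, h[0, 0], rtol=1e-12)


def test_shape_two_hazard_is_linear_in_t(flat_traj):
    p = _params(shape=2.0, alpha=(0.0,))
    t = np.array([[5.0, 50.0, 130.0]])
    h = ev.hazard(p, flat_traj, np.array([0.0]), t)
    np.testing.assert_allclose(h[0], 2.0 * t[0], rtol=1e-12)


def test_value_slope_with_zero_slope_coefficient_nests_value(wiggly_traj):
    eta = np.array([-2.0])
    t = np.array([[20.0, 90.0, 180.0]])
    pv = _params(shape=3.0, alpha=(-0.5,), assoc="value", t_scale=210.0)
    pvs = _params(shape=3.0, alpha=(-0.5, 0.0), assoc="value_slope", t_scale=210.0)
    np.testing.assert_allclose(
        ev.log_hazard(pv, wiggly_traj, eta, t), ev.log_hazard(pvs, wiggly_traj, eta, t)
    )
    np.testing.assert_allclose(
        ev.cumulative_hazard(pv, wiggly_traj, eta, t),
        ev.cumulative_hazard(pvs, wiggly_traj, eta, t),
        rtol=1e-12,
    )


@pytest.mark.parametrize("shape", [0.8, 1.0, 2.5, 45.0])
def test_cumulative_hazard_closed_form_at_alpha_zero(flat_traj, shape):
    p = _params(shape=shape, phi=(1.3, 0.0), t_scale=210.0)
    eta = np.array([1.3])
    t = np.array([[10.0, 120.0, 209.0]])
    H = ev.cumulative_hazard(p, flat_traj, eta, t)
    ref = np.exp(1.3) * (t / 210.0) ** shape
    np.testing.assert_allclose(H, ref, rtol=1e-8)


def test_cumulative_hazard_closed_form_constant_trajectory(flat_traj):
    """Value association with a flat trajectory: H = exp(eta + alpha*c) (t/s)^l."""
    p = _params(shape=5.0, alpha=(-0.7,), assoc="value", t_scale=210.0)
    eta = np.array([2.0])
    t = np.array([[30.0, 209.0]])
    H = ev.cumulative_hazard(p, flat_traj, eta, t)
    ref = np.exp(2.0 - 0.7 * 4.7) * (t / 210.0) ** 5.0
    np.testing.assert_allclose(H, ref, rtol=1e-8)


def test_cumulative_hazard_zero_at_origin_and_monotone(wiggly_traj):
    p = _params(shape=4.0, alpha=(-0.005,), assoc="auc", t_scale=210.0)
    eta = np.array([3.0])
    assert ev.cumulative_hazard(p, wiggly_traj, eta, np.array([0.0]))[0] == 0.0
    t = np.linspace(1.0, 230.0, 80)[None, :]
    H = ev.cumulative_hazard(p, wiggly_traj, eta, t)
    assert np.all(np.diff(H[0]) > 0)


def test_survival_bounds_and_link_to_cumulative_hazard(wiggly_traj):
    p = _params(shape=6.0, alpha=(-0.4,), assoc="value", t_scale=210.0)
    eta = np.array([1.0])
    t = np.linspace(0.0, 220.0, 50)[None, :]
    S = ev.survival(p, wiggly_traj, eta, t)
    assert S[0, 0] == 1.0
    assert np.all((S > 0) & (S <= 1))
    assert np.all(np.diff(S[0]) <= 0)
    H = ev.cumulative_hazard(p, wiggly_traj, eta, t)
    np.testing.assert_allclose(-np.log(S), H, rtol=1e-10, atol=1e-12)


def test_event_log_density_closed_form_and_normalisation(flat_traj):
    shape, eta0 = 3.0, -14.0
    p = _params(shape=shape, phi=(eta0, 0.0))
    eta = np.array([eta0])
    T = np.array([80.0])
    got = ev.event_log_density(p, flat_traj, eta, T)[0]
    ref = (
        np.log(shape) + (shape - 1) * np.log(T[0]) + eta0
        - np.exp(eta0) * T[0] ** shape
    )
    assert abs(got - ref) < 1e-8
    # density integrates to one over (0, inf)
    total, _ = quad(
        lambda t: np.exp(ev.event_log_density(p, flat_traj, eta, np.array([t]))[0]),
        1e-9, 2000.0, limit=400,
    )
    assert abs(total - 1.0) < 1e-6


def test_event_log_density_monotone_in_intercept_at_fixed_time(flat_traj):
    """At a time before the bulk of the density, raising the intercept
    raises the hazard and hence the log-density."""
    T = np.array([50.0])
    vals = [
        ev.event_log_density(
            _params(shape=2.0, phi=(phi0, 0.0)), flat_traj, np.array([phi0]), T
        )[0]
        for phi0 in (-12.0, -11.0, -10.0)
    ]
    assert vals[0] < vals[1] < vals[2]


@pytest.fixture(scope="module")
def representative_traj():
    """Generator-truth mean curve plus one seeded random-effect draw."""
    cfg = GeneratorConfig()
    basis = build_basis(n_interior_knots=4)
    rng = np.random.default_rng(1)
    coefs = np.asarray(cfg.spline_coefs) + rng.normal(0, cfg.re_sds[1], basis.n_basis)
    return LatentTrajectories(basis, np.array([cfg.beta0]), coefs[None, :])


@pytest.mark.parametrize(
    "assoc,alpha,shape",
    [("auc", (-0.01,), 45.0), ("value", (-1.0,), 20.0), ("value_slope", (-1.0, 5.0), 45.0)],
)
def test_quadrature_refinement_below_1e6(representative_traj, assoc, alpha, shape):
    """Doubling the node count moves H(t) by < 1e-6 relative on
    study-representative trajectories and association strengths."""
    p = _params(shape=shape, alpha=alpha, assoc=assoc, t_scale=210.0)
    eta = np.array([2.5])
    t = np.array([[60.0, 150.0, 209.0]])
    H15 = ev.cumulative_hazard(p, representative_traj, eta, t, n_nodes=15)
    H30 = ev.cumulative_hazard(p, representative_traj, eta, t, n_nodes=30)
    assert np.max(np.abs(H30 - H15) / H30) < 1e-6


def test_validation_errors(flat_traj):
    with pytest.raises(ValueError):
        _params(shape=-1.0)
    with pytest.raises(ValueError):
        _params(alpha=(0.1, 0.2), assoc="value")  # wrong alpha dimension
    with pytest.raises(ValueError):
        _params(assoc="nonsense")
    with pytest.raises(ValueError):
        ev.hazard(_params(), flat_traj, np.array([0.0]), np.array([[0.0]]))
    with pytest.raises(ValueError):
        ev.cumulative_hazard(_params(), flat_traj, np.array([0.0]), np.array([-1.0]))


def test_module_survival_matches_kaplan_meier_of_generator_draws():
    """Marginal survival (mean of per-woman S(t) over the cohort's own
    latent trajectories) must track the Kaplan-Meier curve of the drawn
    delivery times within Monte Carlo bounds."""
    cfg = GeneratorConfig(n_women=2000, **REDUCED_INTENSITY)
    c = generate_cohort(cfg, seed=17)
    truth = c.truth
    t_obs = c.subjects["delivery_day"].to_numpy() - 50.0
    grid = np.linspace(150.0, 225.0, 40)
    S = ev.survival(
        truth.event_params,
        truth.trajectories,
        truth.eta,
        np.broadcast_to(grid, (cfg.n_women, grid.size)),
        origin=50.0,
    ).mean(axis=0)
    km = (t_obs[None, :] > grid[:, None]).mean(axis=1)  # no censoring: KM = ECDF
    assert np.max(np.abs(S - km)) < 2.0 / np.sqrt(cfg.n_women) + 0.01
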