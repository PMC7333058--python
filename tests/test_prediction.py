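"""Dynamic risk prediction: closed-form oracle, sampler validity, coverage."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pretermjm.config import GeneratorConfig
from pretermjm.joint import JointModel, JointModelResults, MCMCSettings
from pretermjm.prediction import (
    _laplace_proposal,
    _log_target,
    _NewSubject,
    conditional_preterm_risk,
    risk_trajectory,
)
from pretermjm.simulate import generate_cohort, trajectory_truth

from conftest import ALPHA0_PHI, REDUCED_INTENSITY

COVS = {"age_lmp": 27.0, "age_onset": 12.0, "nephropathy": 0}
HIST = pd.DataFrame(
    {"day": [60.0, 90.0, 120.0, 150.0], "log_glucose": [4.8, 4.7, 4.75, 4.7]}
)


def _degenerate_results(cohort, shape=45.0, phi0=ALPHA0_PHI, phi1=0.8286, n_draws=40):
    """A posterior concentrated at known alpha=0 Weibull parameters."""
    model = JointModel(cohort, association="value", basis=cohort.truth.basis)
    d = model.design
    cfg = GeneratorConfig.from_dict(cohort.provenance["generator"])
    theta = np.concatenate([[cfg.beta0], cfg.spline_coefs, [cfg.beta_age, cfg.beta_onset]])
    chain = {
        "theta": np.tile(theta, (n_draws, 1)),
        "re_sds": np.tile(np.asarray(cfg.re_sds), (n_draws, 1)),
        "sigma_eps": np.full(n_draws, cfg.sigma_eps),
        "evec": np.tile([np.log(shape), phi0, phi1, 0.0], (n_draws, 1)),
        "b": np.zeros((n_draws, d.n_subjects, d.n_random)),
        "deviance": np.zeros(n_draws),
        "acceptance": {},
    }
    return JointModelResults(
        model, MCMCSettings(chains=1, warmup=0, draws=n_draws, seed=0), [chain], None
    )


def test_risk_matches_closed_form_weibull_at_alpha_zero(alpha0_cohort):
    """With alpha = 0 the survival ratio is independent of the random
    effects, so the MC risk must equal 1 - S(u)/S(t) exactly."""
    res = _degenerate_results(alpha0_cohort)
    rc = conditional_preterm_risk(res, HIST, COVS, draws=80, seed=1)
    t_a, t_u = 150.0 - 50.0, rc.horizon_days - 50.0
    H = lambda t: np.exp(ALPHA0_PHI) * (t / 210.0) ** 45.0
    ref = 1.0 - np.exp(-(H(t_u) - H(t_a)))
    np.testing.assert_allclose(rc.mean, ref, atol=1e-10)
    np.testing.assert_allclose(rc.upper, ref, atol=1e-10)  # bands collapse
    # nephropathy raises the conditional risk
    rc_n = conditional_preterm_risk(
        res, HIST, {**COVS, "nephropathy": 1}, draws=80, seed=1
    )
    assert rc_n.risk_at_threshold > rc.risk_at_threshold


def test_risk_vanishes_as_anchor_approaches_threshold(alpha0_cohort):
    res = _degenerate_results(alpha0_cohort)
    risks = [
        conditional_preterm_risk(
            res, HIST, COVS, anchor_day=a, draws=40, seed=2
        ).risk_at_threshold
        for a in (200.0, 240.0, 255.0, 258.9)
    ]
    assert risks[0] > risks[1] > risks[2] > risks[3]
    assert risks[-1] < 0.01  # ~0.1 day of hazard mass left


def test_validation_errors(alpha0_cohort):
    res = _degenerate_results(alpha0_cohort)
    with pytest.raises(ValueError, match="anchor"):
        conditional_preterm_risk(res, HIST, COVS, anchor_day=260.0)
    with pytest.raises(ValueError, match="after the anchor"):
        conditional_preterm_risk(res, HIST, COVS, anchor_day=100.0)
    with pytest.raises(ValueError, match="increasing"):
        risk_trajectory(res, HIST, COVS, [150.0, 120.0])
    with pytest.raises(ValueError, match="no readings"):
        risk_trajectory(res, HIST, COVS, [55.0])


def test_risk_trajectory_semantics_and_determinism(alpha0_cohort):
    res = _degenerate_results(alpha0_cohort)
    curves = risk_trajectory(res, HIST, COVS, [100.0, 150.0], draws=60, seed=5)
    assert len(curves) == 2
    assert curves[0].anchor_day == 100.0
    # single anchor reduces to the scalar op with the truncated history
    solo = conditional_preterm_risk(
        res, HIST[HIST["day"] <= 100.0], COVS, anchor_day=100.0, draws=60, seed=5
    )
    np.testing.assert_allclose(curves[0].mean, solo.mean, atol=1e-12)
    # anchors after the last reading extend event-freedom with full history
    late = risk_trajectory(res, HIST, COVS, [200.0], draws=60, seed=5)[0]
    assert late.anchor_day == 200.0
    again = risk_trajectory(res, HIST, COVS, [200.0], draws=60, seed=5)[0]
    np.testing.assert_array_equal(late.mean, again.mean)


def test_curve_export_layout(alpha0_cohort, tmp_path):
    res = _degenerate_results(alpha0_cohort)
    rc = conditional_preterm_risk(res, HIST, COVS, draws=30, seed=0)
    df = rc.to_frame()
    assert list(df.columns) == [
        "anchor_day", "horizon_day", "mean", "median", "lower_2.5", "upper_97.5"
    ]
    rc.to_csv(tmp_path / "rc.csv")
    back = pd.read_csv(tmp_path / "rc.csv")
    assert len(back) == len(df)
    ax = rc.plot()
    assert ax.get_ylim() == (0.0, 1.0)


def test_conditional_b_sampler_mean_matches_importance_sampling(small_cohort):
    """The independence-MH conditional random-effects sampler is validated
    against a heavy-tailed importance-sampling oracle at fixed parameters
    with a non-zero association."""
    cfg = GeneratorConfig.from_dict(small_cohort.provenance["generator"])
    model = JointModel(small_cohort, association="auc", basis=small_cohort.truth.basis)
    sub = _NewSubject(model, HIST, COVS)
    theta = np.concatenate([[cfg.beta0], cfg.spline_coefs, [cfg.beta_age, cfg.beta_onset]])
    sds = np.asarray(cfg.re_sds)
    eparams = small_cohort.truth.event_params
    t_anchor = 100.0

    mode, cov = _laplace_proposal(
        model, sub, theta, sds, cfg.sigma_eps, eparams, t_anchor
    )
    rng = np.random.default_rng(0)
    # IS oracle: multivariate-t proposal around the Laplace fit
    dof = 5
    L = np.linalg.cholesky(cov * 2.0)
    n_is = 4000
    z = rng.standard_normal((n_is, mode.size))
    g = rng.chisquare(dof, n_is) / dof
    draws = mode + (z @ L.T) / np.sqrt(g)[:, None]
    logq = -0.5 * (dof + mode.size) * np.log1p(
        np.einsum("ni,ij,nj->n", draws - mode,
                  np.linalg.inv(cov * 2.0), draws - mode) / dof
    )
    logp = np.array([
        _log_target(model, sub, theta, b, sds, cfg.sigma_eps, eparams, t_anchor)
        for b in draws
    ])
    w = np.exp(logp - logq - np.max(logp - logq))
    w /= w.sum()
    is_mean = w @ draws
    ess = 1.0 / np.sum(w**2)
    assert ess > 200  # oracle itself must be healthy

    # MH chain at the same fixed parameters
    prec = np.linalg.inv(cov)
    Lc = np.linalg.cholesky(cov)
    b_cur = mode.copy()
    lp_cur = _log_target(model, sub, theta, b_cur, sds, cfg.sigma_eps, eparams, t_anchor)
    acc = 0
    chain = []
    for _ in range(3000):
        prop = mode + Lc @ rng.standard_normal(mode.size)
        lp_prop = _log_target(
            model, sub, theta, prop, sds, cfg.sigma_eps, eparams, t_anchor
        )
        dq = -0.5 * (prop - mode) @ prec @ (prop - mode) + 0.5 * (
            b_cur - mode
        ) @ prec @ (b_cur - mode)
        if np.log(rng.uniform()) < (lp_prop - lp_cur) - dq:
            b_cur, lp_cur = prop, lp_prop
            acc += 1
        chain.append(b_cur.copy())
    chain = np.asarray(chain[200:])
    mh_mean = chain.mean(axis=0)
    mh_se = chain.std(axis=0) / np.sqrt(200)  # conservative ESS
    assert np.all(np.abs(mh_mean - is_mean) < 4 * mh_se + 1e-3)


def test_band_coverage_of_true_conditional_risk():
    """95% bands for pi should cover the truth-computed conditional risk
    for >= 85% of new synthetic women (documented MC slack)."""
    cfg = GeneratorConfig(n_women=40, **REDUCED_INTENSITY)
    train = generate_cohort(cfg, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = JointModel(train, association="auc", basis=train.truth.basis)
        res = model.fit(
            MCMCSettings(chains=2, warmup=400, draws=300, seed=8), on_bad_rhat="ignore"
        )
    new = generate_cohort(GeneratorConfig(n_women=20, **REDUCED_INTENSITY), seed=77)
    import pretermjm.event as ev

    covered = 0
    n_eval = 0
    for i, sid in enumerate(new.subjects["id"]):
        hist = new.readings_for(sid)[["day", "log_glucose"]]
        hist = hist[hist["day"] <= 150.0]
        if len(hist) < 3:
            continue
        srow = new.subject(sid)
        covs = {
            "age_lmp": srow["age_lmp"], "age_onset": srow["age_onset"],
            "nephropathy": srow["nephropathy"],
        }
        rc = conditional_preterm_risk(
            res, hist, covs, anchor_day=150.0, draws=300, seed=100 + i
        )
        # truth-computed conditional risk for this woman
        truth = new.truth
        traj_i = truth.trajectories.subset([i])
        eta_i = truth.eta[i : i + 1]
        S = ev.survival(
            truth.event_params, traj_i, eta_i, np.array([[100.0, 209.0]])
        )[0]
        pi_true = 1.0 - S[1] / S[0]
        n_eval += 1
        covered += int(rc.lower[-1] - 1e-9 <= pi_true <= rc.upper[-1] + 1e-9)
    assert n_eval >= 10
    assert covered / n_eval >= 0.85
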