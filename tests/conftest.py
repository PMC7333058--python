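"""Shared fixtures: small synthetic cohorts at desk scale.

Reading intensity is reduced relative to the study-scale defaults so the
suite stays fast; generator truth parameters are otherwise the defaults.
"""

import numpy as np
import pytest

from pretermjm.config import GeneratorConfig
from pretermjm.simulate import generate_cohort

# intercept matching ~28% preterm when the association is switched off
ALPHA0_PHI = -0.9

REDUCED_INTENSITY = dict(high_rate_mean=0.25, high_rate_sd=0.08, low_rate_prob=0.1)


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(n_women=40, **REDUCED_INTENSITY)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """AUC-truth cohort, 40 women, ~30-50 readings each."""
    return generate_cohort(small_cfg, seed=42)


@pytest.fixture(scope="session")
def alpha0_cfg():
    return GeneratorConfig(
        n_women=40, alpha=(0.0,), phi_intercept=ALPHA0_PHI, **REDUCED_INTENSITY
    )


@pytest.fixture(scope="session")
def alpha0_cohort(alpha0_cfg):
    """No-association cohort: delivery is covariate-only Weibull."""
    return generate_cohort(alpha0_cfg, seed=42)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """sigma_eps -> 0 cohort: readings sit exactly on the latent curve."""
    cfg = GeneratorConfig(n_women=12, sigma_eps=1e-12, **REDUCED_INTENSITY)
    return generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
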