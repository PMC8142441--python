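"""Shared fixtures: small synthetic cohorts and fitted models.

Session-scoped where fitting is involved, so the expensive mixed-model
optimizations run once.
"""

import numpy as np
import pytest

from dynarat.cohort import CohortConfig, ScheduleMix, generate_cohort, generate_model_faithful
from dynarat.design import model_spec
from dynarat.lmm import fit_lmm
from dynarat.splines import Knots


@pytest.fixture(scope="session")
def small_realistic_cohort():
    return generate_cohort(CohortConfig(n_subjects=80, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (one seed)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small time-only structure: cheap to fit, 3 random effects."""
    return model_spec(
        "model5_time",
        time_knots=Knots(internal=(14.0, 42.0), boundary=(0.0, 200.0)),
        re_knots=Knots(internal=(30.0,), boundary=(0.0, 200.0)),
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    """Known parameters for model-faithful simulation with tiny_spec."""
    beta = np.array([12.0, 20.0, 8.0, 5.0])
    G = np.array(
        [
            [36.0, 6.0, 2.0],
            [6.0, 16.0, 3.0],
            [2.0, 3.0, 9.0],
        ]
    )
    sigma2 = 9.0
    return beta, G, sigma2


@pytest.fixture(scope="session")
def faithful_cohort(tiny_spec, tiny_truth):
    beta, G, sigma2 = tiny_truth
    return generate_model_faithful(beta, G, sigma2, tiny_spec, n_subjects=150, seed=5)


@pytest.fixture(scope="session")
def faithful_fit(faithful_cohort, tiny_spec):
    return fit_lmm(faithful_cohort, tiny_spec, method="REML")


@pytest.fixture
def probe_schedule():
    """Deterministic 4-visit schedule: 3 early visits plus the 6-month one."""
    return ScheduleMix(
        templates={"probe": (3, 14, 35, 182)},
        weights={"probe": 1.0},
        jitter_sd=0.0,
        jitter_rel=0.0,
        target_visit_probs=None,
    )
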