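import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from causalpaf import (
    CategoricalCoding,
    CovariateRoles,
    LinearPredictorDecomposition,
    demo_cohort_model,
    demo_roles,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_lp(eta_x, eta_w=None, eta_z=None):
    n = len(eta_x)
    zero = np.zeros(n)
    return LinearPredictorDecomposition(
        subject_ids=np.arange(n),
        eta_x=np.asarray(eta_x, dtype=float),
        eta_w=zero if eta_w is None else np.asarray(eta_w, dtype=float),
        eta_z=zero if eta_z is None else np.asarray(eta_z, dtype=float),
    )


@pytest.fixture
def lp_uncorrelated():
    """Four subjects; exposure relative risks uncorrelated with confounders.

    eta_x = (0, ln2, 0, ln2), eta_z = (0, 0, ln3, ln3): A_f = 1 - 8/12 = 1/3.
    """
    return make_lp(np.log([1, 2, 1, 2]), eta_z=np.log([1, 1, 3, 3]))


@pytest.fixture
def lp_correlated():
    """Exposure positively correlated with confounders: A_f = 1 - 8/14 = 3/7."""
    return make_lp(np.log([1, 1, 2, 2]), eta_z=np.log([1, 1, 3, 3]))


@pytest.fixture(scope="session")
def roles_coding():
    return demo_roles()


@pytest.fixture(scope="session")
def demo_model():
    return demo_cohort_model()


@pytest.fixture(scope="session")
def small_cohort(demo_model):
    """20k-subject confounded cohort shared across fitting tests."""
    return simulate_cohort(demo_model, 20_000, seed=11)


@pytest.fixture
def simple_roles():
    roles = CovariateRoles(
        exposures=("smoking",),
        other_risks=(),
        confounders=("ses",),
        baseline={"smoking": "never", "ses": "low"},
    )
    coding = CategoricalCoding(
        {"smoking": ("never", "current"), "ses": ("low", "high")}
    )
    return roles, coding
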