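import logging

import numpy as np
import pytest

from zdiffkit import CohortSpec, fit_normative_model, gen_cross_sectional, make_reference_model

# age-clamping warnings from visit-2 ages just past the training range are
# expected in longitudinal fixtures; keep test output readable
logging.getLogger("zdiffkit.basis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ref_model():
    """Reference model with known sigma^2 = omega^2 = 1 (simulation truth).

    Trained on 20,000 synthetic subjects so the model-uncertainty term is
    negligible, as with released pre-trained normative models.
    """
    return make_reference_model(n_train=20_000, sigma2=1.0, omega2=1.0, seed=101)


@pytest.fixture(scope="session")
def tracking_spec():
    """Cohort with a moderate subject-stable component: rho = 0.7."""
    return CohortSpec(sigma_eta2=0.7, sigma_xi2=0.3, seed=5)


@pytest.fixture(scope="session")
def fitted_model(tracking_spec):
    """Model fitted the full way (hyper-parameters estimated) on 2000 subjects."""
    train = gen_cross_sectional(tracking_spec, seed=5)
    return fit_normative_model(train, tracking_spec.idp_names, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
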