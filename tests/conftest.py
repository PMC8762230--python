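import numpy as np
import pytest

from voripk import (CohortDesign, ModelSpec, generate_cohort,
                    generate_rich_cohort, phenotype_on_vmax,
                    reference_fixed_effects, reference_omega, reference_sigma)

#: fast-but-accurate fit settings used throughout the suite
FIT_OPTS = dict(surrogate_maxiter=12, max_sweeps=4)


@pytest.fixture(scope="session")
def fixed():
    return reference_fixed_effects()


@pytest.fixture(scope="session")
def omega():
    return reference_omega()


@pytest.fixture(scope="session")
def sigma():
    return reference_sigma()


@pytest.fixture(scope="session")
def final_spec(fixed, omega, sigma):
    """The full model: phenotype on Vmax plus diagonal IIV (13 parameters)."""
    return ModelSpec(fixed_init=fixed.with_updates(theta_IM=0.0, theta_PM=0.0),
                     omega_init=omega, sigma_init=sigma,
                     covariate_effects=(phenotype_on_vmax(),))


@pytest.fixture(scope="session")
def base_spec(fixed, omega, sigma):
    """The covariate-free model (11 parameters)."""
    return ModelSpec(fixed_init=fixed.with_updates(theta_IM=0.0, theta_PM=0.0),
                     omega_init=omega, sigma_init=sigma)


@pytest.fixture(scope="session")
def rich_cohort(fixed, omega, sigma):
    """Small dense-sampling cohort shared by estimation tests."""
    return generate_rich_cohort(24, fixed, omega, sigma, seed=3)


@pytest.fixture(scope="session")
def study_cohort(fixed, omega, sigma):
    """A cohort with the study's trough-only design."""
    return generate_cohort(CohortDesign(), fixed, omega, sigma, seed=5)
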