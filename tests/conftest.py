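import dataclasses

import numpy as np
import pytest

from lvpet.cohort import CohortConfig, GeneratingParameters, simulate_cohort
from lvpet.sem import LatentFactorModel, ModelSpec, prepare_design


@pytest.fixture(scope="session")
def default_params():
    return GeneratingParameters()


@pytest.fixture(scope="session")
def cohort144():
    """One study-sized cohort from the default generator."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def prepared144(cohort144):
    return prepare_design(cohort144)


@pytest.fixture(scope="session")
def final_fit(prepared144):
    """Final-specification ML fit on the study-sized cohort (shared by the
    inference tests; refitting per test would dominate the suite)."""
    return LatentFactorModel(prepared144, ModelSpec.final()).fit()


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment-convergence and recovery checks."""
    return simulate_cohort(CohortConfig(n_subjects=100_000, seed=42))


def null_generating_parameters(**latent_overrides) -> GeneratingParameters:
    """Default generator with the BDNF latent and direct paths zeroed."""
    base = GeneratingParameters()
    coeffs = dict(base.latent_coeffs)
    coeffs["bdnf_group"] = 0.0
    coeffs.update(latent_overrides)
    direct = {k: v for k, v in base.direct_effects.items() if k != ("bdnf_group", "neocortex")}
    return dataclasses.replace(base, latent_coeffs=coeffs, direct_effects=direct)
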