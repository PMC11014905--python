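import numpy as np
import pytest

from eln_aml_strat.classify import GROUPS, classify_eln2022, derive_profile
from eln_aml_strat.simulate import default_blueprint, generate_cohort, generate_genotypes


@pytest.fixture(scope="session")
def blueprint():
    return default_blueprint()


@pytest.fixture(scope="session")
def genotype_cohort(blueprint):
    """Default 624-patient genotype cohort (fixed seed; composition is
    seed-invariant by construction)."""
    return generate_genotypes(blueprint, seed=11)


@pytest.fixture(scope="session")
def simulated_cohort(blueprint):
    """Default cohort with outcomes, one fixed draw."""
    return generate_cohort(blueprint, seed=5)


@pytest.fixture(scope="session")
def group_indices_2022(genotype_cohort):
    groups = [classify_eln2022(derive_profile(p)).group for p in genotype_cohort]
    return np.array([GROUPS.index(g) for g in groups])
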