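import numpy as np
import pytest

from mpapk import CohortDesign, PopulationModel, generate_cohort


@pytest.fixture(scope="session")
def final_model():
    """The published renal-transplant population model."""
    return PopulationModel.renal_transplant()


@pytest.fixture(scope="session")
def small_cohort(final_model):
    """A reduced cohort (12 early + 12 stable) for fast integration tests."""
    design = CohortDesign(n_early=12, n_stable=12)
    return generate_cohort(final_model, design, seed=7)


@pytest.fixture(scope="session")
def full_cohort(final_model):
    """One cohort at the study's design size (51 early + 48 stable)."""
    return generate_cohort(final_model, CohortDesign(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
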