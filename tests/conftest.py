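import numpy as np
import pytest
from hypothesis import settings

from berrystage import enose, synthetic
from berrystage.design import StudyDesign

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign(seed=0)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        seed=0, samples_per_stage_per_harvest=2, reps_enose=4, reps_ftir=3,
        reps_image=2,
    )


@pytest.fixture(scope="session")
def enose_observations(default_design):
    return synthetic.gen_enose(default_design)


@pytest.fixture(scope="session")
def enose_table(enose_observations):
    return enose.assemble_feature_table(enose_observations)


@pytest.fixture(scope="session")
def ftir_spectra(default_design):
    return synthetic.gen_ftir(default_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
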