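import numpy as np
import pandas as pd
import pytest

from empasim import mease1, mease2, population


@pytest.fixture(scope="session")
def ease2_design():
    return population.StudyDesign.from_reference("EASE2")


@pytest.fixture(scope="session")
def ease2_patients(ease2_design):
    return population.sample_population(ease2_design, seed=7)


@pytest.fixture(scope="session")
def mease1_ref():
    """Reference semi-mechanistic parameters with theta_b calibrated."""
    return mease1.MEase1Params.reference()


@pytest.fixture(scope="session")
def mease2_synth():
    """Small synthetic dataset from the descriptive model (arms 0/10/25)."""
    design = population.StudyDesign("EASE2", (0.0, 10.0, 25.0), 52, 300)
    pats = population.sample_population(design, seed=31)
    obs = population.generate_observations(pats, "MEASE2", mease2.MEase2Params(),
                                           design, seed=32)
    obs = obs.merge(pats[["id", "hba1c0", "egfr", "modality_csii"]],
                    left_on="ID", right_on="id")
    return obs, pats[["id", "auc_ss"]], pats


@pytest.fixture(scope="session")
def mease1_synth(mease1_ref):
    """Low-noise synthetic dataset from the semi-mechanistic chain."""
    design = population.StudyDesign("EASE2", (0.0, 2.5, 10.0, 25.0), 52, 400)
    pats = population.sample_population(design, seed=41)
    err = population.ResidualSpec(hba1c_sd=0.05, mdg_cv=0.02, tdid_cv=0.02)
    obs = population.generate_observations(pats, "MEASE1", mease1_ref, design,
                                           error_model=err, seed=42)
    return obs, pats[["id", "auc_ss"]], pats
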