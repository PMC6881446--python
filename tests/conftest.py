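import numpy as np
import pandas as pd
import pytest

from tbidyn.preprocessing import preprocess
from tbidyn.synthetic import SimConfig, cohort_frames, simulate_cohort


@pytest.fixture(scope="session")
def small_patients():
    """Small synthetic cohort reused across tests (fixed seed)."""
    return simulate_cohort(SimConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def small_frames(small_patients):
    return cohort_frames(small_patients)


@pytest.fixture(scope="session")
def small_cohort(small_frames):
    vitals, baselines, _ = small_frames
    cohort, _ = preprocess(vitals, baselines)
    return cohort


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from tbidyn.features import build_feature_matrix

    return build_feature_matrix(small_cohort, "ICP-MAP-CPP")


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort (n = 300) under the generator's default conditions."""
    patients = simulate_cohort(SimConfig(n_patients=300, seed=11))
    vitals, baselines, _ = cohort_frames(patients)
    cohort, _ = preprocess(vitals, baselines)
    return cohort


@pytest.fixture(scope="session")
def study_features(study_cohort):
    from tbidyn.features import build_feature_matrix

    return build_feature_matrix(study_cohort, "ICP-MAP-CPP")
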