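import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    from neuropd.eeg_spectra import log_frequency_grid
    return log_frequency_grid()


@pytest.fixture(scope="session")
def pet_reference():
    """Noise-free reference TAC on the 26-frame 90-min schedule."""
    from neuropd.synth import PETStudyTruth, gen_pet_study
    study = gen_pet_study(PETStudyTruth())
    return study.scans["baseline"]["cerebellum"]


def make_cohort_frame():
    """Tiny hand-built autoradiography table with known arithmetic."""
    import pandas as pd
    rows = [
        ("v1", "vehicle", np.nan, "hippocampus", 404.0, np.nan),
        ("v2", "vehicle", np.nan, "hippocampus", 404.0, np.nan),
        ("b1", "blocker", np.nan, "hippocampus", 98.0, np.nan),
        ("b2", "blocker", np.nan, "hippocampus", 102.0, np.nan),
        ("d1", "drug", 30.0, "hippocampus", 191.2, 544.0),   # S = 0.30 x 304
        ("d2", "drug", 10.0, "hippocampus", 252.0, 250.0),   # S = 152 (50%)
    ]
    return pd.DataFrame(rows, columns=[
        "animal_id", "treatment", "dose_mg_kg", "region",
        "signal_fmol_mg", "plasma_ng_ml"])
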