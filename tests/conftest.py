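import numpy as np
import pytest

import qeegkit as qk


@pytest.fixture(scope="session")
def model():
    """Default generative spectrum (19-channel, 100 Hz)."""
    return qk.SpectralModel()


@pytest.fixture(scope="session")
def grid():
    """Default 48-bin analysis grid (0.78-19.14 Hz at 100 Hz / 256)."""
    return qk.band_grid(100.0)


@pytest.fixture(scope="session")
def normative_fit(model):
    """One normative model fitted on a 200-subject synthetic cohort,
    shared across tests the way a fixed normative database would be."""
    cohort = qk.make_normative_cohort(200, (5.0, 11.0), model, seed=42)
    feats = np.array([
        qk.subject_features(rec).values.ravel() for rec in cohort
    ])
    return qk.fit_normative_model(feats, cohort.table["age"].to_numpy())


def extract_z(cohort, fit):
    """Scalp z-spectra for every member of a cohort."""
    rows = []
    for rec in cohort:
        feats = qk.subject_features(rec).values.ravel()
        rows.append(fit.z_transform(feats, rec.age))
    return np.array(rows)
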