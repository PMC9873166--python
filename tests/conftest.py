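import numpy as np
import pytest

from hbcycle import PatientParams, TreatmentParams


@pytest.fixture
def patient() -> PatientParams:
    return PatientParams()


@pytest.fixture
def treatment() -> TreatmentParams:
    return TreatmentParams()


@pytest.fixture
def quiet_patient() -> PatientParams:
    """Reference physiology with physiological noise switched off."""
    return PatientParams(omega1=0.0)


@pytest.fixture
def quiet_treatment() -> TreatmentParams:
    """Reference treatment with measurement noise switched off."""
    return TreatmentParams(omega2=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
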