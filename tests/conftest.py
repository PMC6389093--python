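from datetime import datetime

import pytest
from hypothesis import settings

from tiatriage.classifier import example_model
from tiatriage.referrals import Cohort, Diagnosis, Referral
from tiatriage.risk import default_risk_curves

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_referral(
    id="r1",
    age=70.0,
    sbp=150.0,
    dbp=80.0,
    duration=70.0,
    diabetes=1,
    weakness=1,
    speech=0,
    onset=datetime(2015, 3, 2, 10, 0),
    referral=datetime(2015, 3, 3, 9, 0),
    arrival=None,
    diagnosis=Diagnosis.TIA_MINOR_STROKE,
    cohort=Cohort.POST_QUEUE,
    **kwargs,
):
    """A fully populated referral with convenient overrides."""
    symptoms = {"unilateral_weakness": weakness, "speech_disturbance": speech}
    symptoms.update(kwargs.pop("symptoms", {}))
    return Referral(
        id=id,
        age_years=age,
        systolic_mmHg=sbp,
        diastolic_mmHg=dbp,
        duration_minutes=duration,
        diabetes=diabetes,
        symptoms=symptoms,
        onset_datetime=onset,
        referral_datetime=referral,
        arrival_datetime=arrival,
        diagnosis=diagnosis,
        cohort=cohort,
        **kwargs,
    )


@pytest.fixture(scope="session")
def model():
    return example_model()


@pytest.fixture(scope="session")
def curves():
    return default_risk_curves()


@pytest.fixture
def referral_factory():
    return make_referral
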