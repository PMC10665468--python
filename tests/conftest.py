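import pytest
from hypothesis import settings

from malnut import PatientRecord, Sex

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def senior_complete() -> PatientRecord:
    """A 75-year-old man with a complete routine lab panel."""
    return PatientRecord(
        patient_id="P001",
        age=75,
        sex=Sex.MALE,
        abw=72.0,
        height=172.0,
        alb=40.0,
        palb=240.0,
        crp=3.0,
        lymc=2100.0,
        neutc=4200.0,
        ahb=142.0,
        mcv=91.0,
        mch=30.0,
        mchc=34.0,
        asaps=2,
    )


@pytest.fixture
def adult_complete(senior_complete) -> PatientRecord:
    """Same panel, 52 years old (adult age class)."""
    return PatientRecord(
        **{
            **{f: getattr(senior_complete, f)
               for f in senior_complete.__dataclass_fields__},
            "patient_id": "P002",
            "age": 52,
        }
    )
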