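import pytest

from pneumorisk import PatientRecord


def make_record(pid="p1", age=12.0, died=False, **overrides) -> PatientRecord:
    """A fully populated record, eligible for all three scores by default."""
    base = dict(
        sex="male", spo2=96.0, chest_indrawing=False, wheeze=False,
        refusal_to_feed=False, grunting=False, cough_history=True,
        unconscious=False, illness_duration_days=2.0, waz=0.0)
    base.update(overrides)
    return PatientRecord(patient_id=pid, age_months=age, died=died, **base)


@pytest.fixture
def complete_record():
    return make_record()
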