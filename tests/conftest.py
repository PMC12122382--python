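import pytest

from tsbdecay.datatypes import (
    CrpMeasurement,
    PatientRecord,
    TreatmentInterval,
    TsbMeasurement,
)


def make_patient(pid, ga_days=195.0, pna_tsb=(), treatments=(), crp=(), **kw):
    return PatientRecord(
        patient_id=pid,
        ga_days=ga_days,
        measurements=[TsbMeasurement(pid, t, y) for t, y in pna_tsb],
        treatments=[TreatmentInterval(pid, k, s, e) for k, s, e in treatments],
        crp=[CrpMeasurement(pid, t, v) for t, v in crp],
        **kw,
    )


@pytest.fixture
def two_patient_cohort():
    return [
        make_patient(
            "P001",
            ga_days=182.0,
            pna_tsb=[(4.0, 150.0), (6.5, 120.0), (9.0, 95.0), (12.0, 80.0)],
            treatments=[("phototherapy", 2.0, 3.5)],
            crp=[(5.0, 3.2), (8.0, 12.5)],
            birth_weight_g=980.0,
            sex="F",
        ),
        make_patient(
            "P002",
            ga_days=203.0,
            pna_tsb=[(3.5, 180.0), (5.0, 160.0), (8.0, 130.0), (10.0, 110.0),
                     (13.0, 90.0)],
            birth_weight_g=1210.0,
            sex="M",
        ),
    ]
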