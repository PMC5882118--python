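import pytest

from sgus import (
    AcrEularItems,
    GlandFindings,
    PatientRecord,
    builtin_model,
)


def make_patient(
    pid="P1",
    pg=(0, 0, 0),
    smg=(0, 0, 0),
    pg_right=None,
    smg_right=None,
    items=None,
    clinical="unknown",
    aecg="unknown",
    acr="unknown",
):
    """Build a patient from (hypo, band, irreg) triples per gland type."""
    pg_right = pg if pg_right is None else pg_right
    smg_right = smg if smg_right is None else smg_right
    glands = (
        GlandFindings("parotid", "left", *pg),
        GlandFindings("parotid", "right", *pg_right),
        GlandFindings("submandibular", "left", *smg),
        GlandFindings("submandibular", "right", *smg_right),
    )
    return PatientRecord(
        patient_id=pid,
        glands=glands,
        items=items,
        clinical_ss=clinical,
        aecg_ss=aecg,
        acr_ss=acr,
    )


@pytest.fixture
def aecg_model():
    return builtin_model("AECG")


@pytest.fixture
def acr_model():
    return builtin_model("ACR")


@pytest.fixture
def all_negative_patient():
    return make_patient()


@pytest.fixture
def all_positive_patient():
    return make_patient(pg=(1, 1, 1), smg=(1, 1, 1))
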