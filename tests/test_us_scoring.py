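"""US scoring: published constants, grades, probabilities, enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgus import (
    DataError,
    GlandFindings,
    ParameterError,
    assign_grade,
    builtin_model,
    enumerate_configurations,
    gland_logit,
    gland_probability,
    gland_score,
    grade_summary,
    patient_probability,
    patient_score_sum,
    round_half_up,
    ss_risk_percent,
    used_items,
)
from conftest import make_patient

#: Published per-grade (SS, nonSS) counts and risk percents.
PUBLISHED_RISKS = {
    "AECG": [((7, 21), 25.0), ((17, 31), 35.4), ((21, 17), 55.3),
             ((39, 7), 84.8), ((49, 4), 92.5)],
    "ACR": [((3, 25), 10.7), ((20, 36), 35.7), ((21, 16), 56.8),
            ((30, 6), 83.3), ((54, 2), 96.4)],
}

#: Published per-grade fitted-probability ranges (grade -> (min, max)).
PUBLISHED_RANGES = {
    "AECG": {0: (0.322, 0.322), 1: (0.358, 0.541), 2: (0.438, 0.768),
             3: (0.652, 0.848), 4: (0.805, 0.884)},
    "ACR": {0: (0.271, 0.271), 1: (0.298, 0.495), 2: (0.406, 0.782),
            3: (0.645, 0.863), 4: (0.879, 0.879)},
}


@pytest.mark.parametrize(
    "basis,gland_type,expected",
    [
        ("AECG", "parotid", {"hypoechoic_area", "hyperechoic_band"}),
        ("AECG", "submandibular",
         {"hypoechoic_area", "hyperechoic_band", "irregular_border"}),
        ("ACR", "parotid", {"hypoechoic_area"}),
        ("ACR", "submandibular",
         {"hypoechoic_area", "hyperechoic_band", "irregular_border"}),
    ],
)
def test_used_items(basis, gland_type, expected):
    assert used_items(basis, gland_type) == expected


def test_used_items_rejects_unknown_basis():
    with pytest.raises(ParameterError):
        used_items("AECG2016", "parotid")


@pytest.mark.parametrize(
    "basis,gland,expected",
    [
        ("AECG", GlandFindings("submandibular", "left", 1, 1, 1), 3),
        ("ACR", GlandFindings("parotid", "left", 0, 1, 0), 0),  # band unused
        ("AECG", GlandFindings("parotid", "left", 0, 0, 0), 0),
        ("ACR", GlandFindings("parotid", "left", 1, 1, 1), 1),  # only hypo counts
    ],
)
def test_gland_score(basis, gland, expected):
    assert gland_score(gland, basis) == expected


def test_parotid_irregular_border_never_scores():
    for basis in ("AECG", "ACR"):
        with_irreg = GlandFindings("parotid", "left", 1, 1, 1)
        without = GlandFindings("parotid", "left", 1, 1, 0)
        assert gland_score(with_irreg, basis) == gland_score(without, basis)


@pytest.mark.parametrize(
    "basis,gland_type,values,expected",
    [
        ("ACR", "submandibular", (0, 0, 0), -1.61),
        ("ACR", "submandibular", (1, 1, 1), -1.61 + 1.98 + 0.65 + 1.36),
        ("AECG", "parotid", (0, 0, 0), -0.33),
        ("AECG", "parotid", (1, 1, 0), -0.33 + 1.65 + 0.52),
    ],
)
def test_gland_logit_published_constants(basis, gland_type, values, expected):
    g = GlandFindings(gland_type, "left", *values)
    assert gland_logit(g, builtin_model(basis)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "logit,expected,tol",
    [(0.0, 0.5, 1e-12), (-0.33, 0.418, 5e-4), (2.38, 0.915, 5e-4)],
)
def test_gland_probability(logit, expected, tol):
    assert gland_probability(logit) == pytest.approx(expected, abs=tol)


def test_gland_probability_monotone_and_bounded():
    logits = np.linspace(-6, 6, 25)
    probs = [gland_probability(x) for x in logits]
    assert all(0 < p < 1 for p in probs)
    assert probs == sorted(probs)


@pytest.mark.parametrize(
    "basis,patient_kwargs,expected",
    [
        ("AECG", {}, 0.322),
        ("ACR", {}, 0.271),
        ("AECG", {"pg": (1, 1, 1), "smg": (1, 1, 1)}, 0.884),
        ("ACR", {"pg": (1, 1, 1), "smg": (1, 1, 1)}, 0.879),
    ],
)
def test_patient_probability_published_values(basis, patient_kwargs, expected):
    patient = make_patient(**patient_kwargs)
    model = builtin_model(basis)
    assert patient_probability(patient, model) == pytest.approx(expected, abs=0.002)


@pytest.mark.parametrize("basis,expected", [("AECG", 10), ("ACR", 8)])
def test_patient_score_sum_extremes(basis, expected, all_positive_patient,
                                    all_negative_patient):
    assert patient_score_sum(all_positive_patient, basis) == expected
    assert patient_score_sum(all_negative_patient, basis) == 0


@pytest.mark.parametrize(
    "basis,score,grade",
    [
        ("AECG", 0, 0), ("AECG", 1, 1), ("AECG", 2, 1), ("AECG", 3, 2),
        ("AECG", 5, 2), ("AECG", 6, 3), ("AECG", 8, 3), ("AECG", 9, 4),
        ("AECG", 10, 4),
        ("ACR", 0, 0), ("ACR", 2, 1), ("ACR", 5, 2), ("ACR", 7, 3), ("ACR", 8, 4),
    ],
)
def test_assign_grade(basis, score, grade):
    assert assign_grade(score, builtin_model(basis)) == grade


@pytest.mark.parametrize("basis", ["AECG", "ACR"])
def test_assign_grade_total_and_single_valued(basis):
    model = builtin_model(basis)
    for s in range(model.max_score_sum + 1):
        grades = [
            g for g, (lo, hi) in enumerate(model.grade_intervals) if lo <= s <= hi
        ]
        assert len(grades) == 1
        assert assign_grade(s, model) == grades[0]
    with pytest.raises(DataError):
        assign_grade(model.max_score_sum + 1, model)
    with pytest.raises(DataError):
        assign_grade(-1, model)


@pytest.mark.parametrize("basis", ["AECG", "ACR"])
def test_published_risk_percents_reproduced(basis):
    """All ten printed per-grade risks from the printed SS/non-SS counts."""
    for (n_ss, n_nonss), printed in PUBLISHED_RISKS[basis]:
        assert ss_risk_percent(n_ss, n_nonss) == printed


def test_risk_of_empty_grade_is_missing():
    assert ss_risk_percent(0, 0) is None


def test_round_half_up_convention():
    assert round_half_up(92.45, 1) == 92.5
    assert round_half_up(10.714285, 1) == 10.7
    assert round_half_up(0.25, 1) == 0.3


def test_grade_summary_single_patient():
    patient = make_patient(clinical="SS")
    summary = grade_summary([patient], builtin_model("AECG"), "clinical_ss")
    assert summary[0].risk_pct == 100.0
    assert summary[0].prob_mean == pytest.approx(0.322, abs=0.002)
    for g in range(1, 5):
        assert summary[g].risk_pct is None
        assert summary[g].total == 0


def test_grade_summary_requires_definite_label():
    with pytest.raises(DataError):
        grade_summary([make_patient()], builtin_model("AECG"), "clinical_ss")


@pytest.mark.parametrize("basis,n_rows", [("AECG", 1024), ("ACR", 256)])
def test_enumeration_row_count(basis, n_rows):
    assert len(enumerate_configurations(builtin_model(basis))) == n_rows


@pytest.mark.parametrize("basis", ["AECG", "ACR"])
def test_enumeration_contains_published_ranges(basis):
    """Theoretical per-grade probability intervals cover the printed ranges."""
    table = enumerate_configurations(builtin_model(basis))
    by_grade = table.groupby("grade")["probability"]
    for grade, (printed_min, printed_max) in PUBLISHED_RANGES[basis].items():
        assert by_grade.min()[grade] <= printed_min + 0.002
        assert by_grade.max()[grade] >= printed_max - 0.002


@pytest.mark.parametrize(
    "basis,lo,hi", [("AECG", 0.322, 0.884), ("ACR", 0.271, 0.879)]
)
def test_enumeration_extremes_match_closed_form(basis, lo, hi):
    table = enumerate_configurations(builtin_model(basis))
    assert table["probability"].min() == pytest.approx(lo, abs=0.002)
    assert table["probability"].max() == pytest.approx(hi, abs=0.002)
    # extreme rows are the unique all-negative / all-positive configurations
    assert (table["score_sum"] == 0).sum() == 1
    assert (table["score_sum"] == table["score_sum"].max()).sum() == 1


@pytest.mark.parametrize("basis", ["AECG", "ACR"])
def test_enumeration_consistent_with_grade_assignment(basis):
    model = builtin_model(basis)
    table = enumerate_configurations(model)
    assert all(
        assign_grade(s, model) == g
        for s, g in zip(table["score_sum"], table["grade"])
    )


_finding_bits = st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1))


@settings(max_examples=150, deadline=None)
@given(
    basis=st.sampled_from(["AECG", "ACR"]),
    pg=_finding_bits,
    pg_r=_finding_bits,
    smg=_finding_bits,
    smg_r=_finding_bits,
    gland_idx=st.integers(0, 3),
    finding_idx=st.integers(0, 2),
)
def test_flipping_a_used_finding_is_monotone(basis, pg, pg_r, smg, smg_r,
                                             gland_idx, finding_idx):
    """Setting any used finding 0->1 strictly raises the gland probability
    and never lowers the patient probability, score sum or grade."""
    from sgus.cohort import FINDINGS

    model = builtin_model(basis)
    patient = make_patient(pg=pg, pg_right=pg_r, smg=smg, smg_right=smg_r)
    gland = patient.glands[gland_idx]
    finding = FINDINGS[finding_idx]
    if gland.value(finding) == 1:
        return
    flipped_gland = GlandFindings(
        gland.gland_type, gland.side,
        **{f: (1 if f == finding else gland.value(f)) for f in FINDINGS},
    )
    glands = list(patient.glands)
    glands[gland_idx] = flipped_gland
    flipped = make_patient(
        pg=tuple(glands[0].value(f) for f in FINDINGS),
        pg_right=tuple(glands[1].value(f) for f in FINDINGS),
        smg=tuple(glands[2].value(f) for f in FINDINGS),
        smg_right=tuple(glands[3].value(f) for f in FINDINGS),
    )
    used = finding in used_items(basis, gland.gland_type)
    p0, p1 = (
        gland_probability(gland_logit(gland, model)),
        gland_probability(gland_logit(flipped_gland, model)),
    )
    if used:
        assert p1 > p0
    else:
        assert p1 == pytest.approx(p0)
    assert patient_probability(flipped, model) >= patient_probability(patient, model)
    s0, s1 = patient_score_sum(patient, basis), patient_score_sum(flipped, basis)
    assert s1 >= s0
    assert assign_grade(s1, model) >= assign_grade(s0, model)
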