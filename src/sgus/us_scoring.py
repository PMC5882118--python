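"""The US score / grade / probability / risk system.

Each salivary gland is scored by summing its positive binary US findings
(only the findings retained by the multivariable logistic screen for that
gland type and classification basis).  A per-gland logistic model converts
the findings into a probability of SS:

    P_L = intercept + sum_i beta_i * finding_i        (the logit)
    P   = 1 / (1 + exp(-P_L))

The patient-level probability is the arithmetic mean of the four gland
probabilities, and the patient's US score sum (0..10 for the AECG basis,
0..8 for the ACR basis) maps through a fixed interval table to an ordinal
US grade 0-4.  The per-grade empirical SS fraction is the "risk of SS".

Two model bases are built in, with the published coefficients:

* ``AECG`` — parotid: hypoechoic area, hyperechoic band;
  submandibular: hypoechoic area, hyperechoic band, irregular border.
* ``ACR`` — parotid: hypoechoic area only; submandibular: all three.

:func:`enumerate_configurations` exhaustively tabulates every possible
patient-level finding configuration (1024 for AECG, 256 for ACR) and is
used as a brute-force oracle for the grade/probability tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import FINDINGS, GLAND_TYPES, GlandFindings, PatientRecord, SIDES
from .errors import DataError, ParameterError

BASES = ("AECG", "ACR")

#: Findings retained per (basis, gland_type), in canonical order.
USED_FINDINGS: Dict[Tuple[str, str], Tuple[str, ...]] = {
    ("AECG", "parotid"): ("hypoechoic_area", "hyperechoic_band"),
    ("AECG", "submandibular"): ("hypoechoic_area", "hyperechoic_band", "irregular_border"),
    ("ACR", "parotid"): ("hypoechoic_area",),
    ("ACR", "submandibular"): ("hypoechoic_area", "hyperechoic_band", "irregular_border"),
}


@dataclass(frozen=True)
class GlandModel:
    """Intercept and per-finding log-odds coefficients for one gland type."""

    intercept: float
    coefficients: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        for f in self.coefficients:
            if f not in FINDINGS:
                raise ParameterError(f"unknown finding {f!r} in gland model")


@dataclass(frozen=True)
class UsModel:
    """A complete per-basis US scoring model.

    ``grade_intervals`` is an ordered 5-tuple of inclusive ``(lo, hi)``
    score-sum intervals for grades 0..4; the intervals must be disjoint,
    contiguous and cover ``0..max_score_sum``.
    """

    basis: str
    glands: Mapping[str, GlandModel]
    grade_intervals: Tuple[Tuple[int, int], ...]
    version: str = "builtin-1"

    def __post_init__(self):
        if self.basis not in BASES:
            raise ParameterError(f"unknown basis {self.basis!r}")
        object.__setattr__(self, "glands", dict(self.glands))
        for gt in GLAND_TYPES:
            if gt not in self.glands:
                raise ParameterError(f"model missing gland type {gt!r}")
        intervals = tuple((int(a), int(b)) for a, b in self.grade_intervals)
        object.__setattr__(self, "grade_intervals", intervals)
        if len(intervals) != 5:
            raise ParameterError("grade_intervals must have 5 entries (grades 0-4)")
        expect_lo = 0
        for lo, hi in intervals:
            if lo != expect_lo or hi < lo:
                raise ParameterError(
                    f"grade intervals must be contiguous and ordered, got {intervals}"
                )
            expect_lo = hi + 1
        if intervals[-1][1] != self.max_score_sum:
            raise ParameterError(
                f"grade intervals cover 0..{intervals[-1][1]} but the maximum "
                f"score sum is {self.max_score_sum}"
            )

    @property
    def max_score_sum(self) -> int:
        return 2 * sum(len(self.glands[gt].coefficients) for gt in GLAND_TYPES)

    def used(self, gland_type: str) -> Tuple[str, ...]:
        if gland_type not in GLAND_TYPES:
            raise ParameterError(f"unknown gland_type {gland_type!r}")
        coefs = self.glands[gland_type].coefficients
        return tuple(f for f in FINDINGS if f in coefs)


AECG_MODEL = UsModel(
    basis="AECG",
    glands={
        "parotid": GlandModel(-0.33, {"hypoechoic_area": 1.65, "hyperechoic_band": 0.52}),
        "submandibular": GlandModel(
            -1.23,
            {"hypoechoic_area": 1.91, "hyperechoic_band": 0.69, "irregular_border": 0.89},
        ),
    },
    grade_intervals=((0, 0), (1, 2), (3, 5), (6, 8), (9, 10)),
)

ACR_MODEL = UsModel(
    basis="ACR",
    glands={
        "parotid": GlandModel(-0.51, {"hypoechoic_area": 2.20}),
        "submandibular": GlandModel(
            -1.61,
            {"hypoechoic_area": 1.98, "hyperechoic_band": 0.65, "irregular_border": 1.36},
        ),
    },
    grade_intervals=((0, 0), (1, 2), (3, 5), (6, 7), (8, 8)),
)

_BUILTIN = {"AECG": AECG_MODEL, "ACR": ACR_MODEL}


def builtin_model(basis: str) -> UsModel:
    """Return the built-in published model for ``basis`` (AECG or ACR)."""
    basis = str(basis).upper()
    if basis not in _BUILTIN:
        raise ParameterError(f"unknown basis {basis!r}; expected one of {BASES}")
    return _BUILTIN[basis]


def used_items(basis: str, gland_type: str) -> frozenset:
    """Finding names that contribute to the score of ``gland_type`` under ``basis``."""
    basis = str(basis).upper()
    if basis not in BASES:
        raise ParameterError(f"unknown basis {basis!r}")
    if gland_type not in GLAND_TYPES:
        raise ParameterError(f"unknown gland_type {gland_type!r}")
    return frozenset(USED_FINDINGS[(basis, gland_type)])


def gland_score(findings: GlandFindings, basis: str) -> int:
    """Number of positive scored findings in one gland (0..1, 0..2 or 0..3)."""
    basis = str(basis).upper()
    if basis not in BASES:
        raise ParameterError(f"unknown basis {basis!r}")
    return sum(findings.value(f) for f in USED_FINDINGS[(basis, findings.gland_type)])


def gland_logit(findings: GlandFindings, model: UsModel) -> float:
    """Linear predictor P_L of the per-gland logistic model."""
    gm = model.glands[findings.gland_type]
    return gm.intercept + sum(
        beta * findings.value(f) for f, beta in gm.coefficients.items()
    )


def gland_probability(logit: float) -> float:
    """Logistic transform 1 / (1 + exp(-logit))."""
    if not np.isfinite(logit):
        raise ParameterError(f"logit must be finite, got {logit}")
    return float(expit(logit))


def _four_glands(patient: PatientRecord):
    try:
        return [patient.gland(gt, s) for gt in GLAND_TYPES for s in SIDES]
    except DataError as exc:
        raise DataError(f"patient {patient.patient_id!r}: {exc}") from exc


def patient_probability(patient: PatientRecord, model: UsModel) -> float:
    """Mean of the four gland probabilities (2 PG + 2 SMG)."""
    glands = _four_glands(patient)
    return float(
        np.mean([gland_probability(gland_logit(g, model)) for g in glands])
    )


def patient_score_sum(patient: PatientRecord, basis: str) -> int:
    """Total US score over the four glands."""
    return sum(gland_score(g, basis) for g in _four_glands(patient))


def assign_grade(score_sum: int, model: UsModel) -> int:
    """Map a score sum to its US grade 0-4 via the model's interval table."""
    s = int(score_sum)
    if s != score_sum:
        raise DataError(f"score_sum must be an integer, got {score_sum!r}")
    for grade, (lo, hi) in enumerate(model.grade_intervals):
        if lo <= s <= hi:
            return grade
    raise DataError(
        f"score sum {s} outside 0..{model.max_score_sum} for basis {model.basis}"
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the published tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def ss_risk_percent(n_ss: int, n_nonss: int) -> Optional[float]:
    """Per-grade risk of SS: 100 * n_SS / total, rounded to one decimal.

    Returns ``None`` for an empty grade (risk is undefined, not 0).
    """
    total = n_ss + n_nonss
    if total == 0:
        return None
    return round_half_up(100.0 * n_ss / total, 1)


@dataclass(frozen=True)
class GradeSummaryRow:
    """Counts, fitted-probability statistics and SS risk for one US grade."""

    grade: int
    n_ss: int
    n_nonss: int
    prob_mean: Optional[float]
    prob_sd: Optional[float]
    prob_min: Optional[float]
    prob_max: Optional[float]
    risk_pct: Optional[float]

    @property
    def total(self) -> int:
        return self.n_ss + self.n_nonss


def grade_summary(
    cohort: Sequence[PatientRecord], model: UsModel, label_field: str = "clinical_ss"
) -> Dict[int, GradeSummaryRow]:
    """Per-grade counts, probability statistics and SS risk for a cohort.

    Every patient must carry a definite (SS / nonSS) value of
    ``label_field``.  The probability standard deviation uses the n-1
    denominator and is ``None`` for grades holding fewer than two patients.
    """
    per_grade_probs: Dict[int, list] = {g: [] for g in range(5)}
    per_grade_counts: Dict[int, list] = {g: [0, 0] for g in range(5)}
    for patient in cohort:
        label = patient.label(label_field)
        if label not in ("SS", "nonSS"):
            raise DataError(
                f"patient {patient.patient_id!r}: {label_field} is {label!r}; "
                "grade_summary requires a definite SS/nonSS label"
            )
        grade = assign_grade(patient_score_sum(patient, model.basis), model)
        per_grade_probs[grade].append(patient_probability(patient, model))
        per_grade_counts[grade][0 if label == "SS" else 1] += 1
    out = {}
    for g in range(5):
        probs = per_grade_probs[g]
        n_ss, n_nonss = per_grade_counts[g]
        if probs:
            arr = np.asarray(probs)
            mean, lo, hi = float(arr.mean()), float(arr.min()), float(arr.max())
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        else:
            mean = lo = hi = sd = None
        out[g] = GradeSummaryRow(
            grade=g,
            n_ss=n_ss,
            n_nonss=n_nonss,
            prob_mean=mean,
            prob_sd=sd,
            prob_min=lo,
            prob_max=hi,
            risk_pct=ss_risk_percent(n_ss, n_nonss),
        )
    return out


def _gland_configurations(model: UsModel, gland_type: str):
    used = model.used(gland_type)
    for values in itertools.product((0, 1), repeat=len(used)):
        yield dict(zip(used, values))


def enumerate_configurations(model: UsModel) -> pd.DataFrame:
    """Exhaustive table of every patient-level configuration of used findings.

    One row per combination of the used findings over the four glands
    (4·4·8·8 = 1024 rows for the AECG basis, 2·2·8·8 = 256 for ACR), with
    the score sum, grade and patient probability computed through the same
    operations used for real patients.  Unused findings are held at 0.
    """
    pg = list(_gland_configurations(model, "parotid"))
    smg = list(_gland_configurations(model, "submandibular"))
    prefix = {("parotid", "left"): "pg_l", ("parotid", "right"): "pg_r",
              ("submandibular", "left"): "smg_l", ("submandibular", "right"): "smg_r"}
    suffix = {"hypoechoic_area": "hypo", "hyperechoic_band": "band",
              "irregular_border": "irreg"}
    rows = []
    for pg_l, pg_r, smg_l, smg_r in itertools.product(pg, pg, smg, smg):
        glands = (
            GlandFindings("parotid", "left", **pg_l),
            GlandFindings("parotid", "right", **pg_r),
            GlandFindings("submandibular", "left", **smg_l),
            GlandFindings("submandibular", "right", **smg_r),
        )
        patient = PatientRecord(patient_id="cfg", glands=glands)
        row = {}
        for g in glands:
            p = prefix[(g.gland_type, g.side)]
            for f in model.used(g.gland_type):
                row[f"{p}_{suffix[f]}"] = g.value(f)
        row["score_sum"] = patient_score_sum(patient, model.basis)
        row["grade"] = assign_grade(row["score_sum"], model)
        row["probability"] = patient_probability(patient, model)
        rows.append(row)
    return pd.DataFrame(rows)
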