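"""Confusion metrics, the threshold-grid sweep and k-fold cross-validation.

The sweep evaluates, against a chosen truth label (by default the
rheumatologists' clinical diagnosis), every member of the four classifier
families on one cohort:

* ACR/EULAR alone at its standard threshold (1 row);
* US grade alone at grade thresholds 1-4 (4 rows);
* the simple conjunction of the two (4 rows);
* the integrated score over the full grid of grade threshold (1-4) x
  assigned US score (1-3) x integrated threshold (4-7) (48 rows);

57 rows per basis in total, with the accuracy-maximal row(s) flagged.

Cross-validation mirrors the published procedure: patients are partitioned
into k nearly equal folds; for each fold in turn the family's free
thresholds are selected by training-set accuracy on the remaining folds
(ties resolved toward the lexicographically smallest configuration), the
selected configuration classifies the held-out fold, and the pooled
accuracy over all patients is reported.  For the ACR/EULAR-alone family
the item-score threshold is searched over 1-9; US model coefficients are
held fixed throughout — the US grade depends only on the binary score
sums, not on the logistic coefficients, so per-fold coefficient
re-estimation cannot change any classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .criteria import (
    ACR_EULAR_MAX,
    DEFAULT_ACR_EULAR_THRESHOLD,
    IntegratedConfig,
    acr_eular_score,
)
from .errors import DataError, ParameterError
from .us_scoring import UsModel, assign_grade, patient_score_sum, round_half_up

logger = logging.getLogger(__name__)

FAMILIES = ("acr_eular", "us", "simple", "integrated")

DEFAULT_GRADE_THRESHOLDS = (1, 2, 3, 4)
DEFAULT_ASSIGNED_SCORES = (1, 2, 3)
DEFAULT_INTEGRATED_THRESHOLDS = (4, 5, 6, 7)


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with sensitivity/specificity/accuracy in percent.

    Percent values are unrounded; table display rounds to integers.  A
    metric whose denominator is empty is ``None`` (undefined, not 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    @property
    def accuracy(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    def display(self) -> str:
        def fmt(x):
            return "--" if x is None else f"{round_half_up(x, 0):.0f}"

        return f"{fmt(self.sensitivity)}/{fmt(self.specificity)}/{fmt(self.accuracy)}"


def _as_bool(values, name):
    out = []
    for v in values:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif v in (0, 1):
            out.append(bool(v))
        elif v == "SS":
            out.append(True)
        elif v == "nonSS":
            out.append(False)
        else:
            raise DataError(f"{name} contains non-binary value {v!r}")
    return np.asarray(out, dtype=bool)


def evaluate(predictions: Sequence, truth_labels: Sequence) -> EvalResult:
    """Confusion counts of binary predictions against binary truth."""
    pred = _as_bool(predictions, "predictions")
    truth = _as_bool(truth_labels, "truth_labels")
    if len(pred) != len(truth):
        raise DataError(
            f"length mismatch: {len(pred)} predictions vs {len(truth)} labels"
        )
    if len(pred) == 0:
        raise DataError("empty inputs")
    return EvalResult(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


@dataclass(frozen=True)
class SweepRow:
    family: str
    basis: str
    us_grade_threshold: Optional[int]
    assigned_us_score: Optional[int]
    integrated_threshold: Optional[int]
    result: EvalResult
    best: bool = False


def _cohort_arrays(cohort, model: UsModel, label_field: str):
    """Precompute (grade, item score, truth) arrays, excluding incomplete patients."""
    grades, scores, truth = [], [], []
    excluded = 0
    for patient in cohort:
        label = patient.label(label_field)
        if label not in ("SS", "nonSS") or patient.items is None or not patient.items.complete:
            excluded += 1
            continue
        grades.append(assign_grade(patient_score_sum(patient, model.basis), model))
        scores.append(acr_eular_score(patient.items))
        truth.append(label == "SS")
    if excluded:
        logger.info("excluded %d patient(s) with unknown items or label", excluded)
    if not grades:
        raise DataError("no evaluable patients (all had unknown items or labels)")
    return (
        np.asarray(grades),
        np.asarray(scores),
        np.asarray(truth, dtype=bool),
        excluded,
    )


def _predict(family, config, grades, scores):
    """Vectorized predictions for one configuration of one family."""
    if family == "acr_eular":
        (thr,) = config
        return scores >= thr
    if family == "us":
        (gthr,) = config
        return grades >= gthr
    if family == "simple":
        (gthr,) = config
        return (scores >= DEFAULT_ACR_EULAR_THRESHOLD) & (grades >= gthr)
    if family == "integrated":
        gthr, assigned, ithr = config
        total = scores + np.where(grades >= gthr, assigned, 0)
        return total >= ithr
    raise ParameterError(f"unknown family {family!r}")


def sweep(
    cohort: Sequence[PatientRecord],
    model: UsModel,
    label_field: str = "clinical_ss",
    grade_thresholds: Sequence[int] = DEFAULT_GRADE_THRESHOLDS,
    assigned_scores: Sequence[int] = DEFAULT_ASSIGNED_SCORES,
    integrated_thresholds: Sequence[int] = DEFAULT_INTEGRATED_THRESHOLDS,
) -> List[SweepRow]:
    """Evaluate every classifier configuration on one cohort.

    Patients with unknown items or truth label are excluded (logged).
    Rows attaining the maximal accuracy are flagged ``best``.
    """
    grades, scores, truth, _ = _cohort_arrays(cohort, model, label_field)

    raw: List[Tuple[str, tuple]] = [("acr_eular", (DEFAULT_ACR_EULAR_THRESHOLD,))]
    raw += [("us", (g,)) for g in grade_thresholds]
    raw += [("simple", (g,)) for g in grade_thresholds]
    raw += [
        ("integrated", (g, a, t))
        for a in assigned_scores
        for t in integrated_thresholds
        for g in grade_thresholds
    ]

    rows = []
    for family, config in raw:
        res = evaluate(_predict(family, config, grades, scores), truth)
        if family == "acr_eular":
            gthr = assigned = ithr = None
        elif family == "integrated":
            gthr, assigned, ithr = config
        else:
            (gthr,), assigned, ithr = config, None, None
        rows.append(
            SweepRow(
                family=family,
                basis=model.basis,
                us_grade_threshold=gthr,
                assigned_us_score=assigned,
                integrated_threshold=ithr,
                result=res,
            )
        )
    best_acc = max(r.result.accuracy for r in rows)
    return [
        SweepRow(
            r.family,
            r.basis,
            r.us_grade_threshold,
            r.assigned_us_score,
            r.integrated_threshold,
            r.result,
            best=(r.result.accuracy == best_acc),
        )
        for r in rows
    ]


def sweep_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Tabular view of sweep rows, unrounded metrics plus display rounding."""
    recs = []
    for r in rows:
        recs.append(
            {
                "family": r.family,
                "basis": r.basis,
                "us_grade_threshold": r.us_grade_threshold,
                "assigned_us_score": r.assigned_us_score,
                "integrated_threshold": r.integrated_threshold,
                "tp": r.result.tp,
                "fp": r.result.fp,
                "tn": r.result.tn,
                "fn": r.result.fn,
                "sensitivity": r.result.sensitivity,
                "specificity": r.result.specificity,
                "accuracy": r.result.accuracy,
                "sens_spec_acc": r.result.display(),
                "best": r.best,
            }
        )
    return pd.DataFrame(recs)


def kfold_partition(n: int, k: int, seed: int) -> np.ndarray:
    """Assign ``n`` indices to ``k`` folds of nearly equal size.

    A seeded uniform shuffle (not stratified); fold sizes differ by at most
    one, with the larger folds first.
    """
    n, k = int(n), int(k)
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not 2 <= k <= n:
        raise ParameterError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds[order[start:start + size]] = f
        start += size
    return folds


def _family_grid(family, grade_thresholds, assigned_scores, integrated_thresholds):
    if family == "acr_eular":
        return [(t,) for t in range(1, ACR_EULAR_MAX + 1)]
    if family == "us":
        return [(g,) for g in grade_thresholds]
    if family == "simple":
        return [(g,) for g in grade_thresholds]
    if family == "integrated":
        return [
            (g, a, t)
            for g in grade_thresholds
            for a in assigned_scores
            for t in integrated_thresholds
        ]
    raise ParameterError(f"unknown family {family!r}; expected one of {FAMILIES}")


def cross_validate(
    cohort: Sequence[PatientRecord],
    model: UsModel,
    family: str,
    k: int = 7,
    seed: int = 0,
    label_field: str = "clinical_ss",
    grade_thresholds: Sequence[int] = DEFAULT_GRADE_THRESHOLDS,
    assigned_scores: Sequence[int] = DEFAULT_ASSIGNED_SCORES,
    integrated_thresholds: Sequence[int] = DEFAULT_INTEGRATED_THRESHOLDS,
) -> float:
    """Pooled k-fold cross-validated accuracy (percent, one decimal).

    Per fold, the configuration of ``family`` with the highest training-set
    accuracy is selected (ties broken toward the lexicographically smallest
    configuration tuple) and applied to the held-out fold; metrics are
    pooled over all patients, so a fold containing a single class never
    yields an undefined per-fold metric.
    """
    grades, scores, truth, _ = _cohort_arrays(cohort, model, label_field)
    n = len(truth)
    grid = _family_grid(family, grade_thresholds, assigned_scores, integrated_thresholds)
    folds = kfold_partition(n, k, seed)
    correct = 0
    for f in range(k):
        test = folds == f
        train = ~test
        best_config, best_acc = None, -1.0
        for config in grid:
            pred = _predict(family, config, grades[train], scores[train])
            acc = float((pred == truth[train]).mean())
            if acc > best_acc or (acc == best_acc and config < best_config):
                best_config, best_acc = config, acc
        pred_test = _predict(family, best_config, grades[test], scores[test])
        correct += int((pred_test == truth[test]).sum())
    return round_half_up(100.0 * correct / n, 1)
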