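"""ACR/EULAR item scoring and the four classifier families.

The 2016 ACR/EULAR classification assigns weight 3 to anti-SSA/Ro serology
and labial gland biopsy and weight 1 to ocular staining, Schirmer's test
and the salivary flow test, declaring SS at a total of >= 4.  Salivary-flow
positivity is treated as a plain binary regardless of the underlying test
(Saxon or unstimulated flow).

Four classifiers are built from this score and the US grade:

* ACR/EULAR alone (item score >= threshold, default 4);
* US alone (grade >= grade threshold);
* simple combination (positive iff both of the above are positive);
* integrated score: the item score plus an assigned US score (0 below the
  grade threshold, a fixed 1-3 at or above it), compared against an
  integrated threshold.  The recommended configuration assigns US score 3
  at grade >= 2 and declares SS at an integrated score >= 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .cohort import ITEMS, AcrEularItems
from .errors import DataError, ParameterError

ITEM_WEIGHTS = {
    "anti_ssa": 3,
    "labial_biopsy": 3,
    "ocular_staining": 1,
    "schirmer": 1,
    "salivary_flow": 1,
}

ACR_EULAR_MAX = sum(ITEM_WEIGHTS.values())  # 9
DEFAULT_ACR_EULAR_THRESHOLD = 4


@dataclass(frozen=True)
class IntegratedConfig:
    """One configuration of the integrated ACR/EULAR + US classifier.

    An ``assigned_us_score`` of 4 is outside the evaluated grid (1-3) but is
    accepted with a warning for exploratory use; 0 degenerates to the plain
    ACR/EULAR classifier.
    """

    us_grade_threshold: int = 2
    assigned_us_score: int = 3
    integrated_threshold: int = 5
    acr_eular_threshold: int = DEFAULT_ACR_EULAR_THRESHOLD

    def __post_init__(self):
        if not 1 <= self.us_grade_threshold <= 4:
            raise ParameterError(
                f"us_grade_threshold must be 1-4, got {self.us_grade_threshold}"
            )
        if not 0 <= self.assigned_us_score <= 4:
            raise ParameterError(
                f"assigned_us_score must be 0-4, got {self.assigned_us_score}"
            )
        if self.assigned_us_score == 4:
            warnings.warn(
                "assigned_us_score=4 is outside the evaluated 1-3 grid",
                stacklevel=2,
            )
        if not 0 <= self.integrated_threshold <= 13:
            raise ParameterError(
                f"integrated_threshold must be 0-13, got {self.integrated_threshold}"
            )
        if not 0 <= self.acr_eular_threshold <= ACR_EULAR_MAX:
            raise ParameterError(
                f"acr_eular_threshold must be 0-{ACR_EULAR_MAX}, "
                f"got {self.acr_eular_threshold}"
            )


RECOMMENDED_CONFIG = IntegratedConfig(
    us_grade_threshold=2, assigned_us_score=3, integrated_threshold=5
)


def acr_eular_score(items: AcrEularItems) -> int:
    """Weighted ACR/EULAR item score, 0-9.  Unknown items are rejected."""
    if not items.complete:
        missing = [i for i in ITEMS if getattr(items, i) is None]
        raise DataError(f"unknown ACR/EULAR items: {missing}")
    return sum(ITEM_WEIGHTS[i] * getattr(items, i) for i in ITEMS)


def _check_range(name, value, lo, hi):
    if not lo <= value <= hi:
        raise ParameterError(f"{name} must be in {lo}..{hi}, got {value}")


def classify_acr_eular(score: int, threshold: int = DEFAULT_ACR_EULAR_THRESHOLD) -> str:
    """SS iff the ACR/EULAR item score reaches the threshold."""
    _check_range("score", score, 0, ACR_EULAR_MAX)
    return "SS" if score >= threshold else "nonSS"


def classify_us(grade: int, grade_threshold: int) -> str:
    """SS iff the US grade reaches the grade threshold."""
    _check_range("grade", grade, 0, 4)
    _check_range("grade_threshold", grade_threshold, 1, 4)
    return "SS" if grade >= grade_threshold else "nonSS"


def classify_simple_combination(acr_eular_positive: bool, us_positive: bool) -> str:
    """SS iff positive for both the ACR/EULAR and the US classifier."""
    return "SS" if (acr_eular_positive and us_positive) else "nonSS"


def integrated_score(acr_score: int, grade: int, config: IntegratedConfig) -> int:
    """ACR/EULAR item score plus the assigned US score (0-12 on the 1-3 grid)."""
    _check_range("acr_score", acr_score, 0, ACR_EULAR_MAX)
    _check_range("grade", grade, 0, 4)
    us = config.assigned_us_score if grade >= config.us_grade_threshold else 0
    return acr_score + us


def classify_integrated(score: int, config: IntegratedConfig) -> str:
    """SS iff the integrated score reaches the configured threshold."""
    _check_range("score", score, 0, ACR_EULAR_MAX + 4)
    return "SS" if score >= config.integrated_threshold else "nonSS"
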