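"""Re-derivation of the US model from a labeled cohort.

The published coefficients were obtained by, per gland type and basis,
(1) screening each binary finding univariately against the SS label, and
(2) fitting a multivariable logistic regression of the label on the
findings that passed the screen.  Glands — not patients — are the unit of
analysis, pooling left and right; intra-patient correlation is deliberately
ignored, reproducing the published modelling choice.

For a single binary predictor the logistic maximum-likelihood fit has a
closed form in the 2x2 table (log odds ratio with Wald standard error
sqrt(1/a + 1/b + 1/c + 1/d)), which :func:`univariate_screen` uses directly;
a chi-square test on the same table is reported alongside.  The candidate
gate uses the logistic Wald p-value at alpha = 0.05.

:func:`steel_dwass` implements the nonparametric all-pairs comparison used
to confirm that fitted probabilities separate the US grades: pairwise
rank-sum statistics with midrank ties, referred to the studentized-range
distribution (large-sample), with an exact-style permutation alternative
for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import FINDINGS, GLAND_TYPES, GlandFindings
from .errors import DataError, ParameterError

ALPHA = 0.05


def _normalize_label(label) -> int:
    if label in (0, 1):
        return int(label)
    if label == "SS":
        return 1
    if label == "nonSS":
        return 0
    raise DataError(f"label must be 0/1 or SS/nonSS, got {label!r}")


def _collect(glands, gland_type):
    if gland_type not in GLAND_TYPES:
        raise ParameterError(f"unknown gland_type {gland_type!r}")
    X, y = [], []
    for g, label in glands:
        if g.gland_type != gland_type:
            continue
        X.append([g.value(f) for f in FINDINGS])
        y.append(_normalize_label(label))
    if not X:
        raise DataError(f"no glands of type {gland_type!r} in input")
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


@dataclass(frozen=True)
class UnivariateResult:
    """Single-predictor association of one finding with the SS label."""

    finding: str
    table: Tuple[int, int, int, int]  # (a, b, c, d) = (pos/SS, pos/non, neg/SS, neg/non)
    odds_ratio: float
    coef: float
    ci95_low: float
    ci95_high: float
    p_value: float
    chi2_p: float
    candidate: bool
    continuity: bool


def univariate_screen(
    glands: Iterable[Tuple[GlandFindings, object]],
    gland_type: str,
    alpha: float = ALPHA,
) -> Dict[str, UnivariateResult]:
    """Screen each finding univariately against the label, per gland type.

    Returns one :class:`UnivariateResult` per finding.  A table with a zero
    cell is flagged ``continuity``: the raw odds ratio is reported as
    ``inf`` / 0 / ``nan`` and the Wald CI and p-value are computed with a
    Haldane-Anscombe 0.5 correction so the screen never crashes on
    separation.
    """
    X, y = _collect(glands, gland_type)
    n_case = int(y.sum())
    if n_case < 2 or (len(y) - n_case) < 2:
        raise DataError("univariate screen needs at least 2 glands per label")
    out = {}
    for j, finding in enumerate(FINDINGS):
        x = X[:, j]
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        continuity = 0 in (a, b, c, d)
        if continuity:
            if b * c == 0 and a * d == 0:
                odds_ratio = float("nan")
            elif b * c == 0:
                odds_ratio = float("inf")
            else:
                odds_ratio = 0.0
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            odds_ratio = (a * d) / (b * c)
            aa, bb, cc, dd = a, b, c, d
        coef = math.log((aa * dd) / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        z = coef / se
        p = 2 * stats.norm.sf(abs(z))
        ci_low = math.exp(coef - 1.959963984540054 * se)
        ci_high = math.exp(coef + 1.959963984540054 * se)
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2_p = float("nan")
        else:
            chi2_p = float(stats.chi2_contingency(table, correction=False)[1])
        out[finding] = UnivariateResult(
            finding=finding,
            table=(a, b, c, d),
            odds_ratio=float(odds_ratio),
            coef=float(coef),
            ci95_low=float(ci_low),
            ci95_high=float(ci_high),
            p_value=float(p),
            chi2_p=chi2_p,
            candidate=bool(p < alpha),
            continuity=continuity,
        )
    return out


@dataclass(frozen=True)
class FindingFit:
    finding: str
    coef: float
    se: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass(frozen=True)
class FitResult:
    """Multivariable logistic fit of the SS label on candidate findings."""

    gland_type: str
    intercept: float
    intercept_se: float
    findings: Dict[str, FindingFit]
    converged: bool
    separation: bool
    n_glands: int
    log_likelihood: float

    def coefficients(self) -> Dict[str, float]:
        return {f: fr.coef for f, fr in self.findings.items()}


def fit_multivariable(
    glands: Iterable[Tuple[GlandFindings, object]],
    gland_type: str,
    candidates: Sequence[str],
) -> FitResult:
    """Maximum-likelihood logistic fit of the label on candidate findings.

    Deterministic given the data (Newton-Raphson, tolerance 1e-8, at most
    100 iterations).  Complete or quasi-complete separation is flagged and
    the (diverging) coefficients are still reported, with
    ``converged=False``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("candidates must be non-empty")
    if len(set(candidates)) != len(candidates):
        raise ParameterError("duplicate findings in candidates")
    for f in candidates:
        if f not in FINDINGS:
            raise ParameterError(f"unknown finding {f!r}")
    X, y = _collect(glands, gland_type)
    if y.min() == y.max():
        raise DataError("labels have no variation; cannot fit")
    cols = [FINDINGS.index(f) for f in candidates]
    design = sm.add_constant(X[:, cols], has_constant="add")
    model = sm.Logit(y, design)
    separation = False
    converged = True
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=100, tol=1e-8, warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        separation = True
        converged = False
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, method="lbfgs", maxiter=200)
    params = np.asarray(res.params, dtype=float)
    # very large fitted log-odds are a signature of (quasi-)separation
    if np.any(np.abs(params) > 15):
        separation = True
        converged = False
    try:
        ci = np.asarray(res.conf_int())
        pvals = np.asarray(res.pvalues, dtype=float)
        ses = np.asarray(res.bse, dtype=float)
    except Exception:  # singular Hessian under separation
        ci = np.full((len(params), 2), np.nan)
        pvals = np.full(len(params), np.nan)
        ses = np.full(len(params), np.nan)
    findings = {}
    for i, f in enumerate(candidates, start=1):
        findings[f] = FindingFit(
            finding=f,
            coef=float(params[i]),
            se=float(ses[i]),
            odds_ratio=float(np.exp(params[i])),
            ci95_low=float(np.exp(ci[i, 0])),
            ci95_high=float(np.exp(ci[i, 1])),
            p_value=float(pvals[i]),
        )
    return FitResult(
        gland_type=gland_type,
        intercept=float(params[0]),
        intercept_se=float(ses[0]),
        findings=findings,
        converged=converged,
        separation=separation,
        n_glands=len(y),
        log_likelihood=float(res.llf),
    )


def _pair_statistic(xi: np.ndarray, xj: np.ndarray) -> float:
    """Standardized midrank pairwise rank-sum statistic (tie-corrected)."""
    ni, nj = len(xi), len(xj)
    N = ni + nj
    ranks = stats.rankdata(np.concatenate([xi, xj]))
    R = ranks[:ni].sum()
    E = ni * (N + 1) / 2.0
    V = ni * nj / (N * (N - 1.0)) * float(((ranks - (N + 1) / 2.0) ** 2).sum())
    if V <= 0:
        return 0.0
    return float((R - E) / math.sqrt(V))


def steel_dwass(
    groups: Sequence[Sequence[float]],
    method: str = "asymptotic",
    n_permutations: int = 2000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """All-pairs nonparametric comparison of k groups.

    For every pair of groups the midrank pairwise rank-sum statistic ``t``
    is computed; ``sqrt(2)*|t|`` is referred to the studentized-range
    distribution with ``k`` groups and infinite degrees of freedom
    (``method="asymptotic"``), giving family-wise adjusted p-values.  With
    ``method="permutation"`` the joint null is simulated instead: group
    labels are permuted and each pair's p-value is the fraction of
    permutations whose *maximum* pairwise statistic reaches that pair's
    observed statistic (single-step max-T adjustment), which is preferable
    for small samples.

    Returns a symmetric (k, k) array of p-values with ``nan`` on the
    diagonal and for pairs involving a group of fewer than 2 observations.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ParameterError("steel_dwass needs at least 2 groups")
    for g in groups:
        if g.size == 0:
            raise ParameterError("groups must be non-empty")
    if method not in ("asymptotic", "permutation"):
        raise ParameterError(f"unknown method {method!r}")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    q_obs = np.full((k, k), np.nan)
    for i, j in pairs:
        if len(groups[i]) < 2 or len(groups[j]) < 2:
            continue
        q_obs[i, j] = q_obs[j, i] = math.sqrt(2.0) * abs(
            _pair_statistic(groups[i], groups[j])
        )
    p = np.full((k, k), np.nan)
    if method == "asymptotic":
        for i, j in pairs:
            if np.isnan(q_obs[i, j]):
                continue
            p[i, j] = p[j, i] = float(
                stats.studentized_range.sf(q_obs[i, j], k, np.inf)
            )
    else:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        edges = np.cumsum([0] + sizes)
        exceed = np.zeros((k, k))
        testable = [(i, j) for i, j in pairs if not np.isnan(q_obs[i, j])]
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = [perm[edges[m]:edges[m + 1]] for m in range(k)]
            q_max = 0.0
            for i, j in testable:
                q = math.sqrt(2.0) * abs(_pair_statistic(parts[i], parts[j]))
                q_max = max(q_max, q)
            for i, j in testable:
                if q_max >= q_obs[i, j]:
                    exceed[i, j] += 1
        for i, j in testable:
            p[i, j] = p[j, i] = (1.0 + exceed[i, j]) / (1.0 + n_permutations)
    return p
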