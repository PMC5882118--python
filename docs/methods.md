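# Methods

## The grading model

Each of a patient's four major salivary glands (left/right parotid, PG;
left/right submandibular, SMG) is described by up to three binary
ultrasound findings: hypoechoic areas, hyperechoic bands, and an irregular
gland border. For each classification basis (AECG or ACR) and gland type, a
logistic model maps the findings of one gland to a probability of Sjögren's
syndrome (SS):

    P_L = b0 + Σ_i  β_i · x_i,        P = 1 / (1 + exp(−P_L))

with the built-in coefficients

| basis | gland | b0 | hypoechoic | band | irregular |
|---|---|---|---|---|---|
| AECG | PG  | −0.33 | 1.65 | 0.52 | — |
| AECG | SMG | −1.23 | 1.91 | 0.69 | 0.89 |
| ACR  | PG  | −0.51 | 2.20 | —    | — |
| ACR  | SMG | −1.61 | 1.98 | 0.65 | 1.36 |

A "—" marks a finding not used for that gland type; a parotid irregular
border may be recorded but never scores. The patient-level probability is
the arithmetic mean of the four gland probabilities. Separately, each gland
contributes the *count* of its positive used findings to a patient score
sum (0–10 for AECG, 0–8 for ACR), which maps to an ordinal US grade 0–4
through a fixed interval table (AECG: {0}, {1–2}, {3–5}, {6–8}, {9–10};
ACR: {0}, {1–2}, {3–5}, {6–7}, {8}). The per-grade "risk of SS" is the
empirical SS fraction among patients in the grade, reported in percent
rounded half away from zero to one decimal; an empty grade has an
*undefined* (missing) risk, never 0.

The two-decimal printed coefficients are the canonical constants. Analytic
reproductions of table probabilities therefore carry a tolerance of ±0.002,
absorbing rounding performed before publication (e.g. the all-positive
ACR patient evaluates to 0.8798 against a printed 0.879).

## Classifier families and the integrated score

The ACR/EULAR item score weights anti-SSA/Ro serology and labial gland
biopsy 3 each and ocular staining, Schirmer's test and the salivary flow
test 1 each (0–9; SS at ≥4). Salivary-flow positivity is treated as plain
binary whatever the underlying test (Saxon or unstimulated flow). Four
classifiers are evaluated: the item score alone; the US grade alone
(grade ≥ threshold); their conjunction; and the integrated score — item
score plus an assigned US score (0 below the grade threshold, a fixed 1–3
at or above it) against an integrated threshold 4–7. The evaluated grid
caps the assigned score at 3; 4 is accepted with a warning but is outside
the grid, because an assigned score ≥4 would let a patient reach the
SS threshold with no weight-3 item at all, breaking the face validity of
the original criteria. The recommended configuration assigns US score 3 at
grade ≥2 with integrated threshold ≥5. With an assigned score of 0 the
integrated classifier reduces exactly to the item-score classifier, which
is exercised as a property test.

## Model re-derivation

The refit path mirrors how the constants were originally obtained. Glands
— not patients — are the regression unit, pooling left and right;
intra-patient correlation is deliberately ignored, reproducing the
published modelling choice (a GEE/mixed-model correction is a non-goal).
The univariate screen is the closed-form 2×2 log odds ratio with Wald
standard error √(1/a+1/b+1/c+1/d) — identical to the single-binary-
predictor logistic MLE — plus a chi-square test on the same table; the
candidate gate uses the Wald p at α = 0.05. Tables with a zero cell are
flagged and handled with a Haldane–Anscombe 0.5 correction for the CI and
p-value while the raw odds ratio is reported as ∞/0/NaN; the screen never
crashes on separation. The multivariable fit is Newton–Raphson maximum
likelihood (tolerance 1e-8, ≤100 iterations) via statsmodels; complete or
quasi-complete separation (|log-odds| > 15 or a solver failure) is flagged
and the coefficients are still reported with `converged=False`.

Grade separation of the fitted probabilities is checked with the
Steel–Dwass all-pairs test: pairwise midrank rank-sum statistics, tie-
corrected variance, √2·|t| referred to the studentized-range distribution
with k groups and infinite degrees of freedom. For small samples a
permutation mode simulates the joint null and applies a single-step max-T
adjustment (each pair's p is the fraction of permutations whose maximum
pairwise statistic reaches that pair's observed one). Pairs involving a
group of fewer than two observations are reported as not testable (NaN).

## Evaluation and cross-validation

Sensitivity, specificity and accuracy are computed from pooled confusion
counts and kept unrounded internally (display rounds to integers, risks to
one decimal). A metric with an empty denominator is missing, not 0. The
sweep emits 57 rows per basis: 1 item-score row, 4 US rows, 4 conjunction
rows and the 4×3×4 integrated grid, flagging the accuracy-maximal row(s).

Cross-validation partitions patients by a seeded uniform shuffle (not
stratified) into k folds whose sizes differ by at most one, larger folds
first. What "training" means was not fully specified in the source
procedure; here, per fold, the family's free thresholds are selected by
training-set accuracy — for the item-score family the threshold is
searched over 1–9 — with ties resolved toward the lexicographically
smallest configuration tuple, for determinism. Metrics are pooled over all
patients rather than averaged per fold, so single-class folds never
produce undefined values. US logistic coefficients are held fixed
throughout: the US grade is a function of the binary score sums only, so
re-estimating coefficients per training fold provably cannot change any
classification; the CLI's `--refit` flag states this and proceeds with
fixed coefficients.

## Synthetic cohort generator

`table2_preset()` emulates the development-cohort conditions: 213 patients
at SS prevalence 133/213, left/right concordance 0.85 (one gland's
findings are copied to the contralateral gland with that probability, else
redrawn — the simplest mechanism consistent with left/right severities
matching in practice), findings independent within a gland given status,
and item positivities governed by per-item sensitivity/specificity. The
finding rates (SS: PG hypo 0.78, band 0.62; SMG hypo 0.80, band 0.62,
irregular 0.58; non-SS: PG 0.22/0.26, SMG 0.15/0.28/0.18; parotid
irregular border 0.10 in both statuses, carrying no signal) were chosen so
that simulated cohorts spread over all five grades with monotonically
increasing per-grade risk and grade-4 risk above 90%. Item sensitivities
(0.55–0.75) and deliberately moderate specificities (0.50–0.85) reflect a
sicca referral population in which single items are often positive without
SS, leaving the item score informative but imperfect.

What the generator does **not** reproduce: patient-level severity
heterogeneity. The published cohort shows simultaneously a 25% SS risk at
grade 0 and 37% of SS patients at grade 4, which requires SS severity to
be bimodal across patients; with findings independent given a binary
status the simulated risk curve is steeper (near 0% at grade 0, near 100%
at grade 4). Passing tests therefore demonstrate the machinery and the
qualitative orderings (risk monotone in grade, integrated classifier
dominating the item score), not the exact published operating points,
which also depend on the undeposited cohort. The generator likewise sets
the clinical, AECG and ACR status labels equal (the bases largely agreed
in the development cohort), so label disagreement effects are out of its
scope.

## Problem sizes and numerical choices

Desk-scale checks are closed-form or exhaustive (1024/256 configurations).
Simulation-based checks use: marginal convergence at n = 20 000 patients;
risk monotonicity at n = 5 000; parameter recovery at n = 4 000 glands ×
40 seeds; cross-validated dominance at n = 62 patients × 50 seeds, 7
folds — sizes at which the binomial/Wald error bands in the assertions are
comfortably wide. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state. Ties in rank statistics use
midranks; risk/accuracy rounding is half away from zero.

## Known limitations

* The per-gland logistic models treat the printed two-decimal coefficients
  as exact; refit models will differ within sampling error.
* No correction for the paired structure of left/right glands in the
  regressions (by design, matching the source procedure).
* No ROC/AUC machinery or confidence intervals on sensitivity/specificity.
* The CSV cohort schema is the only supported interchange format; imaging
  data are out of scope.
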