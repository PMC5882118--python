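# sgus — salivary-gland ultrasound grading for Sjögren's syndrome

Sjögren's syndrome (SS) has no laboratory gold standard: the working
diagnosis is made by rheumatologists weighing serology, histology,
gland-function tests and imaging. `sgus` implements a salivary-gland
ultrasound (US) grading system and its integration with the 2016 ACR/EULAR
classification score, for researchers studying how imaging items improve
classification criteria.

The core model scores each of the four major salivary glands (left/right
parotid and submandibular) on binary US findings — hypoechoic areas,
hyperechoic bands, irregular border — and converts them per gland to an SS
probability via a logistic model,

    P = 1 / (1 + exp(−P_L)),    P_L = b0 + Σ β_i x_i,

with published coefficients for each classification basis (AECG or ACR).
The patient's US score sum (0–10 AECG / 0–8 ACR) maps to an ordinal US
grade 0–4, and the per-grade empirical SS fraction is the "risk of SS".
The integrated classifier adds an assigned US score (3 at grade ≥2 in the
recommended configuration) to the ACR/EULAR item score (0–9) and declares
SS at an integrated score ≥5. The package provides:

* the scoring/grading/probability operations with the built-in published
  coefficients, plus an exhaustive configuration enumerator as an oracle;
* a synthetic cohort generator emulating the study's statistical structure
  (no patient data were deposited);
* model re-derivation (univariate screen, multivariable logistic fit,
  Steel–Dwass grade-separation test);
* the full threshold-grid sweep (57 configurations per basis) and k-fold
  cross-validation with per-fold threshold selection;
* a CSV/YAML I/O layer and a `sgus` command-line interface
  (`simulate`, `score`, `refit`, `classify`, `sweep`, `crossval`).

## Worked example

Simulate a 213-patient cohort with the default study-like parameters and
grade it under the AECG basis:

```sh
sgus simulate --n 213 --seed 1 --out cohort.csv
sgus score --cohort cohort.csv --basis aecg --label aecg \
     --out-scores scores.csv --out-summary summary.csv
```

`summary.csv` (columns abridged):

```
grade,n_ss,n_nonss,prob_mean,risk_pct
0,1,17,0.322,5.6
1,6,36,0.450,14.3
2,18,22,0.570,45.0
3,89,4,0.761,95.7
4,20,0,0.876,100.0
```

Grade 0 patients (no positive findings) sit at the model's floor
probability 0.322 and are rarely SS; the risk of SS rises monotonically
with grade and reaches 100% at grade 4 in this draw. Cross-validating the
integrated classifier against the item score alone on the same cohort:

```sh
sgus crossval --cohort cohort.csv --basis aecg --family integrated --k 7 --seed 1
# integrated 7-fold CV accuracy: 86.9%
sgus crossval --cohort cohort.csv --basis aecg --family acr_eular --k 7 --seed 1
# acr_eular 7-fold CV accuracy: 81.7%
```

The integrated score outperforms the item score alone because the US grade
carries disease signal independent of the five clinical items.

The same operations are available as a library:

```python
from sgus import builtin_model, patient_probability, enumerate_configurations

model = builtin_model("AECG")
table = enumerate_configurations(model)   # all 1024 finding configurations
table.groupby("grade")["probability"].agg(["min", "max"])
```

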