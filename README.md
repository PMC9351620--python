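# ckdbioage

Biological-age (BA) estimation for chronic kidney disease (CKD) cohorts
using a composite biomarker severity index.

Chronological age (CA) counts years since birth; biological age tries to
express how far a patient's physiology has actually deteriorated.  For
CKD patients every clinically relevant biomarker tends to sit on the
unfavourable side of normal, so this package models BA as CA plus an
illness-severity premium:

1. **Screening** — candidate biomarkers (height, weight, gender, BMI,
   creatinine, eGFR, systolic/diastolic blood pressure, CTCA calcium
   score, CKD stage) are correlated with CA; those with |r| > 0.15 enter
   the model.  Clinically redundant, inter-correlated pairs
   (weight vs BMI, creatinine vs eGFR) are resolved to the standard
   clinical measure.
2. **Weighting** — each retained biomarker *i* gets weight
   `w_i = |r_i| / Σ_j |r_j|`, so weights are nonnegative and sum to 1.
3. **Severity indexing** — each reading *x* maps through a
   piecewise-linear index `Index_i(x) ∈ [0, 1]`: 0 at the clinical
   normal reference (21.75 kg/m² BMI, 125/82 mmHg BP, eGFR ≥ 90,
   CTCA ≤ 100) and 1 at or beyond the high-risk threshold.
4. **Composite index and BA** —

   ```
   I_x  = Σ_i w_i · Index_i(x_i)          (I_x ∈ [0, 1])
   BA_x = I_x · SD + CA_x
   ```

   where SD is the sample standard deviation of CA in the scored
   cohort.  Since every index is nonnegative, BA ≥ CA: the gain
   BA − CA (0 … SD years) quantifies excess biological ageing.
5. **Diagnostics** — Bland–Altman agreement of CA vs BA (differences
   CA − BA, limits of agreement d̄ ± 1.96 s) and normality descriptives
   (QQ correlation, skewness, excess kurtosis) of the differences.

Because raw patient data of this kind is rarely redistributable, the
package includes a synthetic-cohort generator (latent Gaussian copula
matched to published per-gender marginals and age–biomarker
correlations) plus two packaged published tables: the 11×11 age/biomarker
correlation matrix and a 133-patient training cohort of
(CA, stage, index, BA).

Intended users: biostatisticians and epidemiologists prototyping
composite-index BA models, and anyone needing a reproducible reference
implementation of this estimator family.

## Worked example

```python
import ckdbioage as ck

cohort = ck.generate(n=190, seed=42)          # synthetic CKD cohort
train, test = ck.split(cohort, 0.70, seed=42)

res = ck.BioAgeIndex(train).fit()
print(res.summary())

s = res.gain_summary(stage_column="ckd_stage")
print(f"mean gain {s.mean_gain:.2f} y (min {s.min_gain}, max {s.max_gain})")

agree = res.bland_altman(test)
print(f"test set: mean diff {agree.mean_diff:.2f} y, "
      f"LOA [{agree.loa_low:.2f}, {agree.loa_high:.2f}]")
```

prints

```
Biological Age Index Model
==============================================================
Training patients:      133
|r| threshold:          0.15
Chronological-age SD:   9.961 years
Selected biomarkers:    6 (creatinine, egfr, sbp, dbp, ctca, ckd_stage)
Retained after redundancy: 4 (egfr, sbp, dbp, ctca)
--------------------------------------------------------------
biomarker          r   p-value    weight
--------------------------------------------------------------
height         0.074     0.399         -
weight        -0.064     0.461         -
gender         0.144     0.097         -
bmi           -0.097     0.265         -
creatinine    -0.186     0.032         -
egfr          -0.200     0.021    0.1940
sbp           -0.176     0.043    0.1705
dbp           -0.408     0.000    0.3948
ctca           0.249     0.004    0.2407
ckd_stage      0.199     0.021         -
--------------------------------------------------------------
BA_x = I_x * SD + CA_x, I_x = sum_i w_i * Index_i(x)
mean gain 7.68 y (min 3, max 10)
test set: mean diff -7.70 y, LOA [-11.15, -4.25]
```

The screening table shows which biomarkers correlate with age strongly
enough to enter the model in this particular draw (sampling noise at
n = 133 moves individual correlations by roughly ±0.09, so the selected
set varies between draws); the weights are the normalized |r| of the
retained, scorable biomarkers.  Every gain is positive — a CKD cohort is
biologically older than its chronological age — and the Bland–Altman
mean difference of −7.7 years on the held-out split mirrors the mean
gain on the training split.

The same pipeline is available from the shell:

```sh
ckd-bioage simulate --n 190 --seed 42 --out cohort.csv
ckd-bioage fit      --cohort cohort.csv --out model.yaml
ckd-bioage score    --model model.yaml --cohort cohort.csv --out scored.csv
ckd-bioage diagnose --scored scored.csv --out-prefix diag
```

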