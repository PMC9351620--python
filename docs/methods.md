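# Methods

## Model

The estimator is a composite-severity-index biological-age model for
chronic kidney disease cohorts.  For patient *x* with chronological age
CA_x and biomarker readings x_i:

```
Index_i(x_i) ∈ [0, 1]                      per-biomarker severity index
I_x  = Σ_i w_i · Index_i(x_i)              composite index, I_x ∈ [0, 1]
BA_x = I_x · SD + CA_x                     biological age, years
```

SD is the sample standard deviation (n−1 denominator) of CA in the
scored cohort.  Key assumptions, stated explicitly:

- **Severity is one-directional.**  Every index is nonnegative, so
  BA ≥ CA always; the model measures excess ageing attributable to
  illness, and cannot report a patient as biologically younger than
  their CA.  This is appropriate for a disease cohort, not for a general
  population.
- **Anchoring at the individual's own CA** (rather than the cohort mean)
  makes the gain BA − CA equal to I_x · SD, independent of CA itself.
- **Linear weighting by age correlation.**  w_i = |r_i| / Σ_j |r_j|
  treats the absolute Pearson correlation with CA as the evidence that a
  biomarker tracks ageing.  Weights are scale-invariant in r and sum
  to 1, so I_x inherits the [0, 1] range of the component indices.

## Severity index functions

Each index is continuous and piecewise linear.  The five built-ins:

| biomarker | shape | knots (reading → index) |
|---|---|---|
| BMI (kg/m²) | two-sided | 18.5 → 1, 21.75 → 0, 30 → 1; 1 outside |
| systolic BP (mmHg) | two-sided | 120 → 1, 125 → 0, 140 → 1; 1 outside |
| diastolic BP (mmHg) | two-sided | 80 → 1, 82 → 0, 90 → 1; 1 outside |
| eGFR (mL/min/1.73 m²) | decreasing risk | ≤ 15 → 1, linear, ≥ 90 → 0 |
| CTCA calcium score | increasing risk | ≤ 100 → 0, linear, ≥ 400 → 1 |

Conventions worth recording:

- The normal reference of a two-sided index is the **midpoint of the
  normal clinical band** (21.75, 125, 82).  The generic builder
  (`build_index_from_levels`) derives exactly these shapes from band
  tables, so configured biomarkers follow the same convention.
- Readings below the lowest stated band (BMI < 18.5, SBP < 120,
  DBP < 80) take index 1: being under the at-risk floor is treated as
  fully severe, per the "otherwise" branch of the piecewise definitions.
- A CTCA score anywhere at or below 100 maps to 0; the clinical
  distinction between "no risk" (0) and "low risk" (< 100) is not
  reflected in the index value.
- Knot ownership follows the printed inequalities (the first branch is
  closed at its upper knot); the functions are continuous, so this
  matters only for exactness testing.  Slopes are stored as exact
  rationals (4/13, 4/33, 1/5, 1/15, 1/2, 1/8, 1/75, 1/300) and evaluate
  within 1e−12 of hand-coded references.
- Non-finite readings raise an error naming the biomarker; evaluated
  values are clamped to [0, 1] against last-bit float overshoot.

## Screening and weighting parameters

| parameter | default | rationale |
|---|---|---|
| selection threshold on \|r\| | 0.15, strict `>` | conventional cutoff for weak-but-usable age association in BA modelling |
| redundancy rules | weight/BMI → BMI; creatinine/eGFR → eGFR | BMI is the standard adiposity measure; eGFR is the standard renal-function index |
| global inter-correlation threshold | 0.6 | both clinical pairs above show \|r\| ≈ 0.64–0.79; unruled pairs above 0.6 keep the member with the larger \|age r\| (ties keep the earlier label) |
| gender encoding | 0 = female, 1 = male | needed only to give the point-biserial correlation a definite sign; configurable |
| p-values | two-sided t with n−2 df | reported for context; selection is driven by \|r\| alone, with no multiple-testing correction |
| missing data | pairwise complete cases for correlations (dropped counts logged); whole-row complete case for scoring (skipped ids logged) |

Selection by |r| with significance merely reported is a deliberate
choice: the weighting formula consumes r directly, and at n ≈ 133 the
0.15 cutoff roughly coincides with p < 0.1 anyway.

## BA reporting conventions

- Reported BA rounds **half-up** to integer years; the unrounded value
  is retained in all outputs.  Integer gains are reported BA minus
  (rounded) CA.
- The SD policy defaults to *from-this-cohort*: each scored cohort uses
  its own CA dispersion.  A fixed SD can be pinned (model artifact,
  `--sd` flag) to score new patients on the training cohort's scale.
  The packaged 133-patient training table was produced with an SD that
  back-solves inconsistently across rows (≈ 8.8–9.9 years), so
  row-level BA values from that table are treated as data to summarize,
  never as targets to regenerate.
- Gain summaries bin the percent increase 100·(BA − CA)/CA at 3-point
  width ([0, 3), [3, 6), …), overall and per CKD stage.

## Bland–Altman and normality diagnostics

Differences are oriented **CA − BA**, so a CKD cohort plots entirely
below zero.  Limits of agreement are d̄ ± 1.96 s with s the sample SD of
the differences; the proportion of differences inside the LOA is
reported (→ 0.95 for normal differences).  Normality is described, not
tested: the normal-QQ correlation uses plotting positions (i − 0.5)/n
(Weibull positions i/(n+1) selectable), skewness is the adjusted
Fisher–Pearson statistic and kurtosis is excess (normal → 0), both
bias-corrected.  Published normality statistics of this kind often omit
their convention, so cross-study comparison of exact values is
unreliable; the package documents its own.

## Synthetic cohort generator

The generator emulates the *summary structure* of a 190-patient CKD
cohort: per-gender means/SDs for eight biomarkers, ages clipped to
35–82, a male fraction of 115/190, target age–biomarker correlations,
and a CKD stage mix near 4/50/38/8% for stages 2–5.

Mechanism: one latent multivariate-normal draw per patient, whose
correlation matrix combines the target age row with published
inter-biomarker correlations (nearest-PSD repair by eigenvalue clipping;
the adjustment norm is logged, and a repair moving any entry by more
than 0.1 raises a configuration error naming the offending pair).
Marginals are affine per gender except CTCA, which gets a lognormal
marginal matched to the per-gender mean/SD — monotone in the latent
normal, so the sign of its age correlation survives.  BMI is recomputed
as weight/height², eGFR is clipped to [1, 120], and CKD stage is derived
from eGFR through the clinical bands (≥ 90 → 1, 60–89 → 2, 30–59 → 3,
15–29 → 4, < 15 → 5), so stage and eGFR are consistent by construction.
The stage mix is *emergent* from the eGFR marginal — a normal mean 32.7,
SD ≈ 14 eGFR already lands near the target mix — and is matched
approximately, not enforced.

What the generator does **not** emulate: renal physiology (no
CKD-EPI/MDRD equation), longitudinal decline, measurement error
structure, or the exact joint distribution of the clinical data.
Consequently, tests that pass on synthetic cohorts demonstrate that the
pipeline recovers the structure it was told to generate (correlations
within sampling tolerance, marginals, internal consistency) — they do
not validate the model's clinical calibration on real patients.

Rank-order note: clipping age to [35, 82] and the lognormal CTCA
transform attenuate Pearson correlations slightly; recovery tolerances
(±0.05 at n = 2000) absorb this.

## Problem sizes and numerical choices

Simulation-based checks use n = 2000 cohorts for correlation recovery
and n = 10,000 difference vectors for LOA coverage — sizes at which
sampling error (≈ 0.02 both cases) sits comfortably inside the asserted
tolerances while the whole suite runs in seconds.  Exactness checks
(index knots, weight reproduction) use tolerance 1e−12 or printed-digit
rounding.  The 70/30 split takes round(n·0.7) training rows from a
seeded permutation; all randomness flows through
`numpy.random.default_rng(seed)` and fixed seeds give bit-identical
cohorts and artifacts.

At n ≈ 130–190, empirical age correlations carry sampling noise of
roughly ±0.09, so which biomarkers clear the 0.15 threshold varies
between synthetic draws (the systolic-BP target of −0.151 sits
essentially on the cutoff).  Pipeline tests on synthetic cohorts
therefore assert consistency between the fitted model and the manually
composed operations; the exact seven-selected/five-retained outcome is
asserted where it is determined — on the packaged correlation-matrix
fixture.

## Known limitations

- Weights depend on the training cohort's correlation structure; they
  are not transportable across diseases or populations.
- The severity bands are adult, sex- and age-agnostic clinical cutoffs;
  no nonlinear index shapes are supported.
- Equal-direction aggregation means a single fully severe biomarker can
  dominate through its weight but can never push I beyond 1.
- The model is cross-sectional; it says nothing about rate of ageing.
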