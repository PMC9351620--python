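"""Composite biological-age index model.

The composite index for patient x is the weighted sum of the per-biomarker
severity indices,

    I_x = sum_i w_i * Index_i(x_i),        I_x in [0, 1],

and is translated into years by anchoring at the patient's own
chronological age and scaling by the cohort's age dispersion:

    BA_x = I_x * SD + CA_x,

where SD is the sample standard deviation of chronological age in the
scored cohort (or a fixed value supplied by the caller).  Because every
severity index is nonnegative, BA >= CA: the model quantifies excess
biological ageing attributable to illness severity, not rejuvenation.

:class:`BioAgeIndex` is the model object (statsmodels-style): construct
it from a cohort DataFrame, call :meth:`~BioAgeIndex.fit` to run the
screening/weighting pipeline, and use the returned
:class:`BioAgeIndexResults` to score cohorts, summarize BA-CA gains and
run agreement diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import diagnostics as _diag
from .screening import (
    DEFAULT_INTER_CORR_THRESHOLD,
    DEFAULT_REDUNDANCY_RULES,
    DEFAULT_THRESHOLD,
    CorrelationResult,
    DegenerateInputError,
    RedundancyRule,
    SchemaError,
    WeightVector,
    compute_weights,
    resolve_redundancy,
    screen_cohort,
    screening_table,
    select_by_threshold,
)
from .severity import PiecewiseIndex, build_builtin_indices

__all__ = [
    "BAEstimate",
    "GainSummary",
    "BioAgeIndex",
    "BioAgeIndexResults",
    "ModelConfigError",
    "composite_index",
    "estimate_ba",
    "cohort_sd",
    "score_cohort",
    "gain_summary",
    "estimates_from_table",
    "estimates_frame",
    "round_half_up",
]

logger = logging.getLogger(__name__)

#: Candidate biomarkers screened against chronological age.
DEFAULT_CANDIDATES = (
    "height", "weight", "gender", "bmi", "creatinine",
    "egfr", "sbp", "dbp", "ctca", "ckd_stage",
)


class ModelConfigError(ValueError):
    """Model configuration is unusable (e.g. nonpositive SD)."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BAEstimate:
    """Biological-age estimate for one patient."""

    patient_id: str
    ca: float
    component_indices: Mapping[str, float]
    composite: float
    sd: float
    ba: float                 # unrounded, years
    ba_reported: int          # half-up integer years
    gain: int                 # ba_reported - ca, integer years

    @property
    def gain_unrounded(self) -> float:
        return self.ba - self.ca


@dataclass(frozen=True)
class GainSummary:
    """Cohort summary of BA - CA gains (integer reported years)."""

    n: int
    mean_gain: float
    mean_gain_years: int
    min_gain: int
    max_gain: int
    pct_increase_bins: pd.Series
    pct_increase_bins_by_stage: pd.DataFrame | None = None


def composite_index(
    weights: WeightVector, components: Mapping[str, float]
) -> float:
    """Weighted sum of per-biomarker severity indices: sum_i w_i Index_i."""
    missing = [lab for lab in weights.labels if lab not in components]
    if missing:
        raise SchemaError(f"component indices missing for: {missing}")
    for lab in weights.labels:
        v = components[lab]
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"component index {lab}={v} outside [0, 1]")
    total = float(sum(weights[lab] * components[lab] for lab in weights.labels))
    # guard against float accumulation at the boundary
    return min(1.0, max(0.0, total))


def estimate_ba(
    composite: float,
    ca: float,
    sd: float,
    patient_id: str = "",
    component_indices: Mapping[str, float] | None = None,
) -> BAEstimate:
    """Translate a composite index into biological age: BA = I * SD + CA."""
    if sd <= 0:
        raise ModelConfigError(f"SD must be positive, got {sd}")
    if not (-1e-9 <= composite <= 1.0 + 1e-9):
        raise ValueError(f"composite index {composite} outside [0, 1]")
    composite = min(1.0, max(0.0, composite))
    ba = composite * sd + ca
    ba_rep = round_half_up(ba)
    return BAEstimate(
        patient_id=str(patient_id),
        ca=float(ca),
        component_indices=dict(component_indices or {}),
        composite=float(composite),
        sd=float(sd),
        ba=float(ba),
        ba_reported=ba_rep,
        gain=int(ba_rep - round_half_up(ca)),
    )


def cohort_sd(ca_values) -> float:
    """Sample standard deviation (n-1 denominator) of chronological age."""
    ca = np.asarray(ca_values, dtype=float)
    if ca.size < 2:
        raise DegenerateInputError(
            f"need at least 2 ages for a cohort SD, got {ca.size}"
        )
    sd = float(np.std(ca, ddof=1))
    if sd == 0:
        logger.warning("cohort SD is 0; BA degenerates to CA")
    return sd


def score_cohort(
    cohort: pd.DataFrame,
    indices: Mapping[str, PiecewiseIndex],
    weights: WeightVector,
    sd: float | None = None,
    age_column: str = "age",
    id_column: str | None = None,
) -> list[BAEstimate]:
    """Score every complete row of a cohort.

    ``sd=None`` uses the sample SD of this cohort's chronological age
    ("from-this-cohort" policy); a float pins a fixed SD.  Rows with any
    missing weighted biomarker are skipped with a logged identifier.
    """
    if cohort.empty:
        raise DegenerateInputError("empty cohort")
    needed = [age_column, *weights.labels]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    for lab in weights.labels:
        if lab not in indices:
            raise SchemaError(f"no severity index for weighted biomarker {lab!r}")
    complete = cohort.dropna(subset=needed)
    skipped = cohort.index.difference(complete.index)
    for idx in skipped:
        logger.info("score: skipping incomplete row %r", idx)
    if complete.empty:
        raise DegenerateInputError("no complete rows to score")
    if sd is None:
        sd = cohort_sd(complete[age_column])
    estimates = []
    for idx, row in complete.iterrows():
        pid = str(row[id_column]) if id_column else str(idx)
        comps = {lab: indices[lab](float(row[lab])) for lab in weights.labels}
        comp = composite_index(weights, comps)
        estimates.append(
            estimate_ba(comp, float(row[age_column]), sd,
                        patient_id=pid, component_indices=comps)
        )
    return estimates


def _pct_bins(pct: np.ndarray) -> pd.IntervalIndex:
    hi = max(15.0, 3.0 * math.ceil(float(np.max(pct)) / 3.0)) if pct.size else 15.0
    edges = np.arange(0.0, hi + 3.0, 3.0)
    return pd.IntervalIndex.from_breaks(edges, closed="left")


def gain_summary(
    estimates: Sequence[BAEstimate],
    stages: Sequence | None = None,
) -> GainSummary:
    """Summarize BA - CA gains and percent-increase bins across a cohort.

    Percent increase is 100 * (BA - CA)/CA, binned at 3-point width
    ([0, 3), [3, 6), ...), overall and optionally by CKD stage.
    """
    if not estimates:
        raise DegenerateInputError("no estimates to summarize")
    gains = np.array([e.gain for e in estimates])
    ca = np.array([e.ca for e in estimates])
    ba = np.array([e.ba_reported for e in estimates])
    pct = 100.0 * (ba - ca) / ca
    bins = _pct_bins(pct)
    cut = pd.cut(pct, bins)
    overall = pd.Series(cut).value_counts(sort=False)
    by_stage = None
    if stages is not None:
        df = pd.DataFrame({"stage": list(stages), "bin": pd.Series(cut)})
        by_stage = df.groupby("stage", observed=False)["bin"].value_counts(
            sort=False).unstack(fill_value=0)
    mean = float(gains.mean())
    return GainSummary(
        n=len(estimates),
        mean_gain=mean,
        mean_gain_years=round_half_up(mean),
        min_gain=int(gains.min()),
        max_gain=int(gains.max()),
        pct_increase_bins=overall,
        pct_increase_bins_by_stage=by_stage,
    )


def estimates_from_table(
    table: pd.DataFrame,
    ca_column: str = "ca",
    ba_column: str = "ba",
    index_column: str | None = None,
    id_column: str | None = None,
) -> list[BAEstimate]:
    """Wrap an already-scored (CA, BA) table as :class:`BAEstimate` rows.

    Useful for summarizing externally produced per-patient BA tables
    (e.g. the packaged training-cohort fixture) with
    :func:`gain_summary` and the agreement diagnostics.  The SD is
    unknown for such tables and recorded as NaN.
    """
    ests = []
    for idx, row in table.iterrows():
        ca = float(row[ca_column])
        ba = float(row[ba_column])
        comp = float(row[index_column]) if index_column else float("nan")
        pid = str(row[id_column]) if id_column else str(idx)
        ba_rep = round_half_up(ba)
        ests.append(BAEstimate(
            patient_id=pid, ca=ca, component_indices={}, composite=comp,
            sd=float("nan"), ba=ba, ba_reported=ba_rep,
            gain=int(ba_rep - round_half_up(ca)),
        ))
    return ests


def estimates_frame(estimates: Sequence[BAEstimate]) -> pd.DataFrame:
    """Per-patient output table: CA, component indices, composite, BA, gain."""
    rows = []
    for e in estimates:
        row = {"patient_id": e.patient_id, "ca": e.ca}
        row.update({f"index_{k}": v for k, v in e.component_indices.items()})
        row.update({
            "composite": e.composite,
            "sd": e.sd,
            "ba_unrounded": e.ba,
            "ba": e.ba_reported,
            "gain": e.gain,
            "pct_increase": 100.0 * (e.ba_reported - e.ca) / e.ca,
        })
        rows.append(row)
    return pd.DataFrame(rows)


class BioAgeIndex:
    """Index-model biological-age estimator for a CKD cohort.

    Parameters
    ----------
    cohort
        Training cohort, one row per patient.  Must contain ``age_column``
        and the candidate biomarker columns (gender numerically encoded,
        0 = female / 1 = male).
    candidates
        Biomarkers screened against chronological age.
    severity_indices
        Per-biomarker severity index functions; defaults to the five
        built-ins (BMI, SBP, DBP, eGFR, CTCA).
    threshold
        Selection cutoff on |r| (strict inequality), default 0.15.
    redundancy_rules, inter_corr_threshold
        Resolution of clinically redundant inter-correlated pairs.
    sd
        Fixed SD (years) for the BA transform; ``None`` uses the sample
        SD of each scored cohort.

    Examples
    --------
    >>> model = BioAgeIndex(cohort)           # doctest: +SKIP
    >>> res = model.fit()                     # doctest: +SKIP
    >>> res.weights                           # doctest: +SKIP
    WeightVector(bmi=0.1422, ctca=0.2046, ...)
    >>> scored = res.predict()                # doctest: +SKIP
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        age_column: str = "age",
        candidates: Sequence[str] = DEFAULT_CANDIDATES,
        severity_indices: Mapping[str, PiecewiseIndex] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
        redundancy_rules: Sequence[RedundancyRule] = DEFAULT_REDUNDANCY_RULES,
        inter_corr_threshold: float = DEFAULT_INTER_CORR_THRESHOLD,
        sd: float | None = None,
    ):
        if not 0 < threshold < 1:
            raise ModelConfigError(f"threshold must be in (0, 1), got {threshold}")
        if len(cohort) < 3:
            raise DegenerateInputError(
                f"cohort too small to fit ({len(cohort)} rows)"
            )
        self.cohort = cohort
        self.age_column = age_column
        self.candidates = tuple(candidates)
        self.severity_indices = dict(severity_indices or build_builtin_indices())
        self.threshold = threshold
        self.redundancy_rules = tuple(redundancy_rules)
        self.inter_corr_threshold = inter_corr_threshold
        self.sd = sd

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "BioAgeIndex":
        return cls(cohort, **kwargs)

    def fit(self) -> "BioAgeIndexResults":
        """Run screening, selection, redundancy resolution and weighting."""
        results = screen_cohort(self.cohort, self.candidates, self.age_column)
        selected = select_by_threshold(results, self.threshold)
        age_corrs = {r.biomarker_name: r.r for r in results}
        numeric = self.cohort[list(self.candidates)].apply(
            pd.to_numeric, errors="coerce")
        corr_matrix = numeric.corr()
        retained = resolve_redundancy(
            selected, corr_matrix, self.redundancy_rules, age_corrs,
            self.inter_corr_threshold,
        )
        scorable = [b for b in retained if b in self.severity_indices]
        dropped = [b for b in retained if b not in self.severity_indices]
        if dropped:
            logger.warning(
                "no severity index for retained biomarker(s) %s; excluded "
                "from weighting", dropped,
            )
        weights = compute_weights({b: age_corrs[b] for b in scorable})
        sd = self.sd if self.sd is not None else cohort_sd(
            self.cohort[self.age_column])
        return BioAgeIndexResults(
            model=self,
            screen_results=results,
            selected=selected,
            retained=scorable,
            weights=weights,
            sd=sd,
        )


class BioAgeIndexResults:
    """Fitted biological-age index model.

    Attributes
    ----------
    weights : WeightVector
        Normalized |r|-proportional weights for the retained biomarkers.
    sd : float
        Chronological-age SD (years) used by default when scoring the
        training cohort.
    selected, retained : list of str
        Biomarkers passing the |r| threshold, and surviving redundancy
        resolution.
    """

    def __init__(self, model, screen_results, selected, retained, weights, sd):
        self.model = model
        self.screen_results: list[CorrelationResult] = list(screen_results)
        self.selected: list[str] = list(selected)
        self.retained: list[str] = list(retained)
        self.weights: WeightVector = weights
        self.sd: float = float(sd)

    def screening_table(self) -> pd.DataFrame:
        return screening_table(
            self.screen_results, self.selected, self.retained, self.weights)

    def predict(
        self,
        cohort: pd.DataFrame | None = None,
        sd: float | None = None,
        id_column: str | None = None,
    ) -> list[BAEstimate]:
        """Score a cohort (default: the training cohort with its SD)."""
        if cohort is None:
            cohort = self.model.cohort
            if sd is None:
                sd = self.sd
        elif sd is None and self.model.sd is not None:
            sd = self.model.sd
        return score_cohort(
            cohort, self.model.severity_indices, self.weights, sd=sd,
            age_column=self.model.age_column, id_column=id_column,
        )

    def predict_frame(self, cohort: pd.DataFrame | None = None, **kw) -> pd.DataFrame:
        return estimates_frame(self.predict(cohort, **kw))

    def gain_summary(
        self, cohort: pd.DataFrame | None = None, stage_column: str | None = None
    ) -> GainSummary:
        target = self.model.cohort if cohort is None else cohort
        stages = target[stage_column] if stage_column and stage_column in target else None
        if stages is not None:
            # align to the complete-case rows that actually get scored
            needed = [self.model.age_column, *self.weights.labels]
            stages = target.dropna(subset=needed)[stage_column]
        return gain_summary(self.predict(cohort), stages)

    def bland_altman(self, cohort: pd.DataFrame | None = None):
        """Agreement diagnostics between CA and predicted BA."""
        est = self.predict(cohort)
        ca = [e.ca for e in est]
        ba = [e.ba_reported for e in est]
        return _diag.bland_altman(ca, ba)

    def summary(self) -> str:
        """Plain-text fit summary in the style of statsmodels results."""
        tab = self.screening_table()
        lines = [
            "Biological Age Index Model",
            "=" * 62,
            f"Training patients:      {len(self.model.cohort)}",
            f"|r| threshold:          {self.model.threshold}",
            f"Chronological-age SD:   {self.sd:.3f} years",
            f"Selected biomarkers:    {len(self.selected)} "
            f"({', '.join(self.selected)})",
            f"Retained after redundancy: {len(self.retained)} "
            f"({', '.join(self.retained)})",
            "-" * 62,
            f"{'biomarker':<12}{'r':>8}{'p-value':>10}{'weight':>10}",
            "-" * 62,
        ]
        for _, row in tab.iterrows():
            w = f"{row['weight']:.4f}" if pd.notna(row["weight"]) else "-"
            lines.append(
                f"{row['biomarker']:<12}{row['r']:>8.3f}"
                f"{row['p_value']:>10.3f}{w:>10}"
            )
        lines.append("-" * 62)
        lines.append("BA_x = I_x * SD + CA_x, I_x = sum_i w_i * Index_i(x)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<BioAgeIndexResults: {len(self.retained)} biomarkers, "
            f"sd={self.sd:.3f}>"
        )
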