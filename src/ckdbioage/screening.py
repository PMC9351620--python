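"""Correlation-based biomarker screening and weighting.

Candidate biomarkers are screened by their Pearson correlation with
chronological age; those with |r| above a threshold (default 0.15) enter
the model.  Clinically redundant pairs (e.g. weight vs BMI, creatinine vs
eGFR) are resolved to a single member, and the survivors receive weights
proportional to their absolute age correlation,

    w_i = |r_i| / sum_j |r_j|,

so the weights are nonnegative and sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "WeightVector",
    "RedundancyRule",
    "DegenerateInputError",
    "SchemaError",
    "ScreenConfigError",
    "pearson_r",
    "screen_cohort",
    "select_by_threshold",
    "resolve_redundancy",
    "compute_weights",
    "DEFAULT_THRESHOLD",
    "DEFAULT_INTER_CORR_THRESHOLD",
    "DEFAULT_REDUNDANCY_RULES",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.15
DEFAULT_INTER_CORR_THRESHOLD = 0.6


class DegenerateInputError(ValueError):
    """Input has no usable variation (constant vector, empty cohort, ...)."""


class SchemaError(KeyError):
    """A required column or label is missing from the input table."""


class ScreenConfigError(ValueError):
    """Screening configuration references unknown labels or bad thresholds."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one biomarker with chronological age."""

    biomarker_name: str
    r: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1 for {self.biomarker_name}: {self.r}")


@dataclass(frozen=True)
class RedundancyRule:
    """Keep ``preferred`` when its pair is inter-correlated above threshold."""

    member_pair: tuple[str, str]
    preferred: str
    inter_corr_threshold: float = DEFAULT_INTER_CORR_THRESHOLD

    def __post_init__(self) -> None:
        if self.preferred not in self.member_pair:
            raise ScreenConfigError(
                f"preferred label {self.preferred!r} is not in pair "
                f"{self.member_pair}"
            )


#: The two clinically motivated rules used for the CKD pipeline: BMI is
#: the more reliable adiposity measure than raw weight, and eGFR is the
#: standard renal-function index over raw creatinine.
DEFAULT_REDUNDANCY_RULES: tuple[RedundancyRule, ...] = (
    RedundancyRule(("weight", "bmi"), preferred="bmi"),
    RedundancyRule(("creatinine", "egfr"), preferred="egfr"),
)


class WeightVector:
    """Ordered nonnegative biomarker weights summing to one."""

    def __init__(self, entries: Iterable[tuple[str, float]]):
        entries = tuple((str(k), float(v)) for k, v in entries)
        if not entries:
            raise DegenerateInputError("empty weight vector")
        total = sum(v for _, v in entries)
        if any(v < -1e-12 or v > 1 + 1e-12 for _, v in entries):
            raise ValueError("weights must lie in [0, 1]")
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        self._entries = entries

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self._entries)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self._entries])

    def __getitem__(self, label: str) -> float:
        for k, v in self._entries:
            if k == label:
                return v
        raise KeyError(label)

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightVector) and self._entries == other._entries

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v:.4f}" for k, v in self._entries)
        return f"WeightVector({body})"

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self._entries), name="weight")


def pearson_r(x, y, name: str = "") -> CorrelationResult:
    """Pearson correlation with a two-sided p-value (t with n-2 df).

    Raises :class:`DegenerateInputError` when either vector is constant
    and ``ValueError`` on length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            f"zero variance in correlation input{f' for {name}' if name else ''}"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        biomarker_name=name, r=float(res.statistic), n=int(x.size),
        p_value=float(res.pvalue),
    )


def screen_cohort(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    age_column: str = "age",
) -> list[CorrelationResult]:
    """Correlate each candidate biomarker with chronological age.

    Missing values are dropped pairwise (complete cases per biomarker);
    the number of dropped rows is logged.  Gender, if present, must
    already be numerically encoded (0 = female, 1 = male by package
    convention).
    """
    missing = [c for c in (age_column, *candidates) if c not in cohort.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    results = []
    for cand in candidates:
        pair = cohort[[age_column, cand]].apply(pd.to_numeric, errors="coerce")
        complete = pair.dropna()
        dropped = len(pair) - len(complete)
        if dropped:
            logger.info("screen %s: dropped %d incomplete rows", cand, dropped)
        results.append(
            pearson_r(complete[age_column], complete[cand], name=cand)
        )
    return results


def select_by_threshold(
    results: Sequence[CorrelationResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[str]:
    """Labels with |r| strictly greater than ``threshold``, order preserved."""
    return [res.biomarker_name for res in results if abs(res.r) > threshold]


def resolve_redundancy(
    selected: Sequence[str],
    corr_matrix: pd.DataFrame,
    rules: Sequence[RedundancyRule] = DEFAULT_REDUNDANCY_RULES,
    age_corrs: Mapping[str, float] | None = None,
    inter_corr_threshold: float = DEFAULT_INTER_CORR_THRESHOLD,
) -> list[str]:
    """Drop the redundant member of inter-correlated biomarker pairs.

    For each explicit rule whose pair is fully selected and whose absolute
    inter-correlation exceeds the rule's threshold, the non-preferred
    member is dropped.  Remaining unruled pairs above the global
    ``inter_corr_threshold`` keep the member with the larger absolute age
    correlation (ties keep the earlier label).  Survivor order follows the
    input order.
    """
    for rule in rules:
        for lab in rule.member_pair:
            if lab not in corr_matrix.index or lab not in corr_matrix.columns:
                raise ScreenConfigError(
                    f"redundancy rule references unknown label {lab!r}"
                )
    retained = list(selected)
    for rule in rules:
        a, b = rule.member_pair
        if a in retained and b in retained:
            inter = abs(float(corr_matrix.loc[a, b]))
            if inter > rule.inter_corr_threshold:
                loser = b if rule.preferred == a else a
                logger.info(
                    "redundancy rule %s/%s (|r|=%.3f): dropping %s",
                    a, b, inter, loser,
                )
                retained.remove(loser)
    # unruled pairs above the global threshold: keep the stronger age signal
    if age_corrs is not None:
        changed = True
        while changed:
            changed = False
            for i, a in enumerate(retained):
                for b in retained[i + 1:]:
                    if abs(float(corr_matrix.loc[a, b])) > inter_corr_threshold:
                        loser = b if abs(age_corrs[a]) >= abs(age_corrs[b]) else a
                        logger.info(
                            "unruled redundancy %s/%s: dropping %s", a, b, loser
                        )
                        retained.remove(loser)
                        changed = True
                        break
                if changed:
                    break
    return retained


def compute_weights(age_corrs: Mapping[str, float] | Sequence[tuple[str, float]]) -> WeightVector:
    """Weighted-average weights: w_i = |r_i| / sum_j |r_j|.

    Scale-invariant in the correlations and permutation-equivariant.
    Raises :class:`DegenerateInputError` when all correlations are zero.
    """
    items = list(age_corrs.items()) if isinstance(age_corrs, Mapping) else list(age_corrs)
    if not items:
        raise DegenerateInputError("no biomarkers to weight")
    total = sum(abs(float(r)) for _, r in items)
    if total == 0:
        raise DegenerateInputError("all correlations are zero")
    return WeightVector((name, abs(float(r)) / total) for name, r in items)


def screening_table(
    results: Sequence[CorrelationResult],
    selected: Sequence[str],
    retained: Sequence[str],
    weights: WeightVector | None = None,
) -> pd.DataFrame:
    """Flat report of the screening pipeline, one row per candidate."""
    rows = []
    for res in results:
        w = None
        if weights is not None and res.biomarker_name in weights.labels:
            w = weights[res.biomarker_name]
        rows.append({
            "biomarker": res.biomarker_name,
            "r": res.r,
            "n": res.n,
            "p_value": res.p_value,
            "selected": res.biomarker_name in selected,
            "retained": res.biomarker_name in retained,
            "weight": w,
        })
    return pd.DataFrame(rows)
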