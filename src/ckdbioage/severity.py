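"""Piecewise-linear biomarker severity indices.

Each clinical biomarker is mapped to a severity index in [0, 1]: 0 at the
clinically normal reference reading, 1 at (and beyond) the high-risk
threshold.  Two-sided biomarkers (BMI, blood pressure) have a V-shaped
index anchored at the midpoint of the normal band; one-sided biomarkers
ramp monotonically (eGFR: risk grows as the reading falls; CTCA calcium
score: risk grows as the score rises).

The five built-in index functions are::

    BMI   : 1 - (4/13)(x - 18.5)  on [18.5, 21.75],  1 + (4/33)(x - 30) on (21.75, 30],  else 1
    SBP   : 1 - (1/5)(x - 120)    on [120, 125],     1 + (1/15)(x - 140) on (125, 140],  else 1
    DBP   : 1 - (1/2)(x - 80)     on [80, 82],       1 + (1/8)(x - 90)  on (82, 90],     else 1
    eGFR  : 1 for x <= 15,  (90 - x)/75 on (15, 90),  0 for x >= 90
    CTCA  : 0 for x <= 100, (x - 100)/300 on (100, 400),  1 for x >= 400

A generic builder (:func:`build_index_from_levels`) constructs the same
shapes from a table of clinical reading bands, so new biomarkers can be
added from configuration without hand-deriving slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "Band",
    "SeverityLevelTable",
    "Segment",
    "PiecewiseIndex",
    "InvalidReadingError",
    "SeverityConfigError",
    "eval_index",
    "build_builtin_indices",
    "build_index_from_levels",
    "BUILTIN_LEVEL_TABLES",
]

SEVERITY_LABELS = {
    "no risk",
    "at risk",
    "low risk",
    "normal",
    "moderate risk",
    "moderately high risk",
    "high risk",
}


class InvalidReadingError(ValueError):
    """A biomarker reading is not a finite real number."""


class SeverityConfigError(ValueError):
    """A severity-level table cannot be turned into an index function."""


@dataclass(frozen=True)
class Band:
    """One clinical reading band: ``[lower, upper)`` with a severity label.

    ``lower``/``upper`` may be ``None`` for an open end.
    """

    lower: float | None
    upper: float | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in SEVERITY_LABELS:
            raise SeverityConfigError(
                f"unknown severity label {self.label!r}; expected one of "
                f"{sorted(SEVERITY_LABELS)}"
            )
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise SeverityConfigError(
                f"band bounds out of order: [{self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class SeverityLevelTable:
    """Ordered, contiguous clinical bands for one biomarker.

    Bands must tile the reading axis without overlap, ascending.  Exactly
    one band is labelled ``normal`` (or ``no risk`` for score-type
    biomarkers such as the CTCA calcium score).
    """

    biomarker_name: str
    bands: tuple[Band, ...]
    units: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise SeverityConfigError(f"{self.biomarker_name}: no bands given")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper is None or b.lower is None or a.upper != b.lower:
                raise SeverityConfigError(
                    f"{self.biomarker_name}: bands not contiguous at "
                    f"{a.upper!r} / {b.lower!r}"
                )
        n_normal = sum(1 for b in self.bands if b.label in ("normal", "no risk"))
        if n_normal != 1:
            raise SeverityConfigError(
                f"{self.biomarker_name}: expected exactly one normal/no-risk "
                f"band, found {n_normal}"
            )

    def band(self, label: str) -> Band:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(label)

    @property
    def normal_band(self) -> Band:
        for b in self.bands:
            if b.label in ("normal", "no risk"):
                return b
        raise SeverityConfigError(f"{self.biomarker_name}: no normal band")


@dataclass(frozen=True)
class Segment:
    """Affine piece ``slope * x + intercept`` on ``(lower, upper]`` /
    ``[lower, upper]`` depending on ``closed_lower``."""

    lower: float
    upper: float
    slope: Fraction
    intercept: Fraction
    closed_lower: bool = False

    def contains(self, x: float) -> bool:
        if self.closed_lower:
            return self.lower <= x <= self.upper
        return self.lower < x <= self.upper

    def __call__(self, x: float) -> float:
        return float(self.slope) * x + float(self.intercept)


@dataclass(frozen=True)
class PiecewiseIndex:
    """Continuous piecewise-linear severity index for one biomarker.

    Evaluates to a value in [0, 1] for every finite reading.  Segments are
    ordered along the reading axis; ``default_value`` applies outside all
    segments (the printed "otherwise" branch).  Segment slopes are stored
    as exact rationals so the printed coefficients round-trip exactly.
    """

    biomarker_name: str
    segments: tuple[Segment, ...]
    default_value: float = 1.0

    def __call__(self, x):
        return eval_index(self, x)

    @property
    def knots(self) -> tuple[float, ...]:
        ks: list[float] = []
        for s in self.segments:
            for k in (s.lower, s.upper):
                if k not in ks:
                    ks.append(k)
        return tuple(sorted(ks))


def _eval_scalar(fn: PiecewiseIndex, x: float) -> float:
    if not math.isfinite(x):
        raise InvalidReadingError(
            f"{fn.biomarker_name}: reading must be finite, got {x!r}"
        )
    for seg in fn.segments:
        if seg.contains(x):
            # clamp tiny float overshoot at knots
            return min(1.0, max(0.0, seg(x)))
    return fn.default_value


def eval_index(fn: PiecewiseIndex, x):
    """Evaluate a severity index at reading(s) ``x``.

    Scalar in, scalar out; array-like in, ndarray out.  Non-finite
    readings raise :class:`InvalidReadingError` naming the biomarker.
    """
    if np.isscalar(x) or isinstance(x, (int, float)):
        return _eval_scalar(fn, float(x))
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidReadingError(
            f"{fn.biomarker_name}: readings must be finite"
        )
    out = np.empty(arr.shape, dtype=float)
    for idx, val in np.ndenumerate(arr):
        out[idx] = _eval_scalar(fn, float(val))
    return out


def _two_sided(name: str, low: float, mid: float, high: float) -> PiecewiseIndex:
    """V-shaped index: 1 at ``low``, 0 at ``mid``, 1 at ``high``, 1 outside.

    The lower branch owns both of its knots (closed interval), matching
    the printed inequalities; the upper branch is half-open on the left.
    Continuity at ``mid`` makes the ownership numerically immaterial.
    """
    down = Fraction(-1, 1) / Fraction(mid - low)  # slope of falling branch
    up = Fraction(1, 1) / Fraction(high - mid)
    return PiecewiseIndex(
        biomarker_name=name,
        segments=(
            Segment(low, mid, down, 1 - down * Fraction(low), closed_lower=True),
            Segment(mid, high, up, 1 - up * Fraction(high)),
        ),
        default_value=1.0,
    )


def _monotone(name: str, anchor0: float, anchor1: float, *, decreasing: bool) -> PiecewiseIndex:
    """Ramp between two anchors.

    decreasing=True: index 1 at/below ``anchor0``, 0 at/above ``anchor1``
    (eGFR-style); decreasing=False: 0 at/below ``anchor0``, 1 at/above
    ``anchor1`` (CTCA-style).  Plateaus are explicit segments so the
    default value is never consulted for finite readings.
    """
    lo, hi = float(anchor0), float(anchor1)
    span = Fraction(hi - lo)
    if decreasing:
        slope = Fraction(-1) / span
        inner = Segment(lo, hi, slope, -slope * Fraction(hi))
        left = Segment(-math.inf, lo, Fraction(0), Fraction(1), closed_lower=False)
        right = Segment(hi, math.inf, Fraction(0), Fraction(0))
        default = 0.0
    else:
        slope = Fraction(1) / span
        inner = Segment(lo, hi, slope, -slope * Fraction(lo))
        left = Segment(-math.inf, lo, Fraction(0), Fraction(0))
        right = Segment(hi, math.inf, Fraction(0), Fraction(1))
        default = 1.0
    return PiecewiseIndex(name, (left, inner, right), default_value=default)


#: Clinical reading-level tables for the five built-in biomarkers.  The
#: normal/moderate boundaries follow the knots of the printed index
#: equations (e.g. the BMI normal band ends at 25, making its midpoint the
#: 21.75 normal reference).
BUILTIN_LEVEL_TABLES: dict[str, tuple[SeverityLevelTable, str]] = {
    "bmi": (
        SeverityLevelTable(
            "bmi",
            (
                Band(None, 18.5, "at risk"),
                Band(18.5, 25.0, "normal"),
                Band(25.0, 30.0, "moderate risk"),
                Band(30.0, None, "high risk"),
            ),
            units="kg/m^2",
        ),
        "two-sided",
    ),
    "sbp": (
        SeverityLevelTable(
            "sbp",
            (
                Band(None, 120.0, "at risk"),
                Band(120.0, 130.0, "normal"),
                Band(130.0, 140.0, "moderate risk"),
                Band(140.0, None, "high risk"),
            ),
            units="mmHg",
        ),
        "two-sided",
    ),
    "dbp": (
        SeverityLevelTable(
            "dbp",
            (
                Band(None, 80.0, "at risk"),
                Band(80.0, 84.0, "normal"),
                Band(84.0, 90.0, "moderate risk"),
                Band(90.0, None, "high risk"),
            ),
            units="mmHg",
        ),
        "two-sided",
    ),
    "egfr": (
        SeverityLevelTable(
            "egfr",
            (
                Band(None, 15.0, "high risk"),
                Band(15.0, 30.0, "moderately high risk"),
                Band(30.0, 60.0, "moderate risk"),
                Band(60.0, 90.0, "low risk"),
                Band(90.0, None, "normal"),
            ),
            units="mL/min/1.73m^2",
        ),
        "decreasing-risk",
    ),
    "ctca": (
        SeverityLevelTable(
            "ctca",
            (
                Band(None, 100.0, "no risk"),
                Band(100.0, 400.0, "moderately high risk"),
                Band(400.0, None, "high risk"),
            ),
            units="score",
        ),
        "increasing-risk",
    ),
}


def build_builtin_indices() -> dict[str, PiecewiseIndex]:
    """The five shipped severity index functions keyed by biomarker name.

    BMI and blood pressures are two-sided around the normal midpoint
    (21.75 kg/m^2, 125 mmHg systolic, 82 mmHg diastolic); eGFR ramps from
    1 at 15 down to 0 at 90; CTCA ramps from 0 at 100 up to 1 at 400.
    """
    return {
        "bmi": _two_sided("bmi", 18.5, 21.75, 30.0),
        "sbp": _two_sided("sbp", 120.0, 125.0, 140.0),
        "dbp": _two_sided("dbp", 80.0, 82.0, 90.0),
        "egfr": _monotone("egfr", 15.0, 90.0, decreasing=True),
        "ctca": _monotone("ctca", 100.0, 400.0, decreasing=False),
    }


def _risk_boundary(table: SeverityLevelTable, direction: str) -> tuple[float, float]:
    """Anchor readings for a monotone index: (start-of-ramp, end-of-ramp)."""
    try:
        hi_band = table.band("high risk")
    except KeyError:
        raise SeverityConfigError(
            f"{table.biomarker_name}: monotone index needs a high-risk band"
        ) from None
    normal = table.normal_band
    if direction == "decreasing-risk":
        # risk falls as the reading rises: 1 below the high-risk upper
        # bound, 0 from the normal lower bound on
        if hi_band.upper is None or normal.lower is None:
            raise SeverityConfigError(
                f"{table.biomarker_name}: cannot anchor a decreasing-risk ramp"
            )
        return hi_band.upper, normal.lower
    # increasing-risk: 0 up to the end of the benign band(s), 1 from the
    # high-risk lower bound on
    if hi_band.lower is None:
        raise SeverityConfigError(
            f"{table.biomarker_name}: high-risk band has no lower bound"
        )
    benign_upper = None
    for b in table.bands:
        if b.label in ("no risk", "low risk", "normal"):
            benign_upper = b.upper
    if benign_upper is None:
        raise SeverityConfigError(
            f"{table.biomarker_name}: cannot anchor an increasing-risk ramp"
        )
    return benign_upper, hi_band.lower


def build_index_from_levels(
    table: SeverityLevelTable, direction: str
) -> PiecewiseIndex:
    """Build a :class:`PiecewiseIndex` from a clinical reading-level table.

    Parameters
    ----------
    table
        Contiguous severity bands for one biomarker.
    direction
        ``"two-sided"`` — index 0 at the midpoint of the normal band,
        rising linearly to 1 at the normal band's lower bound and at the
        high-risk band's lower bound, 1 outside (BMI/BP shape).
        ``"decreasing-risk"`` — reading high is good (eGFR shape).
        ``"increasing-risk"`` — reading high is bad (CTCA shape).
    """
    if direction == "two-sided":
        normal = table.normal_band
        try:
            hi_band = table.band("high risk")
        except KeyError:
            raise SeverityConfigError(
                f"{table.biomarker_name}: two-sided index needs a high-risk band"
            ) from None
        if normal.lower is None or normal.upper is None:
            raise SeverityConfigError(
                f"{table.biomarker_name}: two-sided index needs a bounded "
                "normal band"
            )
        if hi_band.lower is None:
            raise SeverityConfigError(
                f"{table.biomarker_name}: two-sided index needs a bounded "
                "high-risk lower edge"
            )
        mid = (normal.lower + normal.upper) / 2.0
        return _two_sided(table.biomarker_name, normal.lower, mid, hi_band.lower)
    if direction == "decreasing-risk":
        a0, a1 = _risk_boundary(table, direction)
        return _monotone(table.biomarker_name, a0, a1, decreasing=True)
    if direction == "increasing-risk":
        a0, a1 = _risk_boundary(table, direction)
        return _monotone(table.biomarker_name, a0, a1, decreasing=False)
    raise SeverityConfigError(f"unknown direction {direction!r}")
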