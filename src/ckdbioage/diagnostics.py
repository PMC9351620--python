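"""Agreement and normality diagnostics for CA vs BA.

Bland-Altman analysis treats chronological and biological age as two
measurements of the same patient and examines their differences
d_i = CA_i - BA_i against their means.  Under approximate normality of
the differences, about 95% should fall inside the limits of agreement
d-bar +/- 1.96 s.  Because the severity indices are nonnegative, a CKD
cohort has every difference below zero: biological age always meets or
exceeds chronological age here.

Normality of the differences is assessed descriptively: a normal QQ
correlation, the adjusted Fisher-Pearson skewness, and excess kurtosis
(normal distribution -> 0 for both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screening import DegenerateInputError

__all__ = ["AgreementSummary", "bland_altman", "qq_normal", "moments"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of CA - BA differences."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_within_loa: float
    qq_correlation: float
    skewness: float
    excess_kurtosis: float
    #: (mean, difference) coordinates for the Bland-Altman plot
    plot_coords: pd.DataFrame

    def report(self) -> dict[str, float]:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "prop_within_loa": self.prop_within_loa,
            "qq_correlation": self.qq_correlation,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
        }


def bland_altman(ca, ba) -> AgreementSummary:
    """Bland-Altman agreement between chronological and biological age.

    Differences are oriented CA - BA, so a cohort whose BA always exceeds
    CA plots entirely below zero.  Limits of agreement are
    d-bar +/- 1.96 s with s the sample SD of the differences.
    """
    ca = np.asarray(ca, dtype=float)
    ba = np.asarray(ba, dtype=float)
    if ca.shape != ba.shape:
        raise ValueError(f"length mismatch: {ca.shape} vs {ba.shape}")
    if ca.size < 3:
        raise ValueError(f"need at least 3 pairs, got {ca.size}")
    d = ca - ba
    mean = float(d.mean())
    s = float(np.std(d, ddof=1))
    loa_low, loa_high = mean - 1.96 * s, mean + 1.96 * s
    within = float(np.mean((d >= loa_low) & (d <= loa_high)))
    if np.ptp(d) == 0:
        logger.warning("all CA-BA differences identical: zero-width LOA")
        qq_r = float("nan")
        skew = kurt = float("nan")
    else:
        qq_r, _ = qq_normal(d)
        skew, kurt = moments(d) if d.size >= 4 else (float("nan"), float("nan"))
    coords = pd.DataFrame({"mean": (ca + ba) / 2.0, "difference": d})
    return AgreementSummary(
        mean_diff=mean, sd_diff=s, loa_low=loa_low, loa_high=loa_high,
        prop_within_loa=within, qq_correlation=qq_r, skewness=skew,
        excess_kurtosis=kurt, plot_coords=coords,
    )


def qq_normal(d, plotting_positions: str = "midpoint"):
    """Normal QQ pairing of a difference vector.

    Sorted values are paired with standard-normal quantiles at plotting
    positions (i - 0.5)/n (``"midpoint"``, the default) or i/(n + 1)
    (``"weibull"``).  Returns ``(correlation, coords)`` where ``coords``
    has columns ``theoretical`` and ``empirical``.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        raise ValueError(f"need at least 3 values, got {d.size}")
    if np.ptp(d) == 0:
        raise DegenerateInputError("zero variance in QQ input")
    n = d.size
    i = np.arange(1, n + 1)
    if plotting_positions == "midpoint":
        p = (i - 0.5) / n
    elif plotting_positions == "weibull":
        p = i / (n + 1.0)
    else:
        raise ValueError(f"unknown plotting positions {plotting_positions!r}")
    theo = stats.norm.ppf(p)
    emp = np.sort(d)
    r = float(np.corrcoef(theo, emp)[0, 1])
    coords = pd.DataFrame({"theoretical": theo, "empirical": emp})
    return r, coords


def moments(d) -> tuple[float, float]:
    """Adjusted Fisher-Pearson skewness and excess kurtosis.

    Both are bias-corrected for sample size and are 0 for normal data;
    both are invariant to location and positive scale changes.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 4:
        raise ValueError(f"need at least 4 values, got {d.size}")
    if np.ptp(d) == 0:
        raise DegenerateInputError("zero variance in moments input")
    skew = float(stats.skew(d, bias=False))
    kurt = float(stats.kurtosis(d, fisher=True, bias=False))
    return skew, kurt
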