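"""Synthetic CKD cohort generation and packaged fixtures.

The published study's raw patient data is not redistributable, so this
module generates cohorts with the same *summary* structure: per-gender
biomarker means/SDs, an age range of 35-82 years, the printed
age-biomarker correlations, and a CKD stage mix of roughly 4/50/38/8%
for stages 2-5.

Construction is a latent Gaussian-copula-style model: a jointly normal
draw whose correlation matrix combines the target age-biomarker
correlations with the published inter-biomarker correlations, mapped
through per-gender marginal transforms (affine for most biomarkers,
lognormal for the right-skewed CTCA calcium score).  BMI is recomputed
from weight/height^2 and CKD stage is derived from the generated eGFR via
the clinical bands, so the table is internally consistent by
construction.  The generator emulates marginals and pairwise
correlations only; it makes no claim to renal physiology.

Two published tables ship as fixtures: the 11x11 age/biomarker
correlation matrix and the 133-patient training cohort of
(CA, CKD stage, BA index, BA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .screening import ScreenConfigError

__all__ = ["CohortSpec", "generate", "split", "load_fixture", "ckd_stage_from_egfr"]

logger = logging.getLogger(__name__)

#: Biomarkers represented in the latent normal (BMI and CKD stage are
#: derived, not drawn).
_LATENT_VARS = ("age", "ctca", "creatinine", "weight", "height",
                "sbp", "dbp", "egfr", "gender")

#: Per-gender marginal (mean, SD) for the generated biomarkers, from the
#: published cohort characteristics (male n=115, female n=75).
TABLE2_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "age": (62.88, 9.463),
        "weight": (76.77, 12.305),
        "height": (1.66, 0.0647),
        "ctca": (558.997, 733.855),
        "creatinine": (242.11, 130.025),
        "egfr": (35.513, 14.857),
        "sbp": (146.88, 23.808),
        "dbp": (76.47, 14.906),
    },
    "female": {
        "age": (61.97, 9.988),
        "weight": (68.60, 14.347),
        "height": (1.523, 0.060),
        "ctca": (291.853, 470.753),
        "creatinine": (229.59, 105.253),
        "egfr": (28.481, 12.432),
        "sbp": (148.20, 21.075),
        "dbp": (76.23, 13.736),
    },
}

#: Published age-biomarker Pearson correlations (training cohort).
TABLE4_AGE_CORRELATIONS: dict[str, float] = {
    "ctca": 0.249,
    "creatinine": -0.202,
    "weight": -0.234,
    "height": -0.138,
    "bmi": -0.173,
    "egfr": -0.233,
    "sbp": -0.151,
    "dbp": -0.411,
    "ckd_stage": 0.122,
    "gender": 0.017,
}

_COLUMNS = ("patient_id", "age", "gender", "height", "weight", "bmi",
            "sbp", "dbp", "creatinine", "egfr", "ctca", "ckd_stage")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic CKD cohort.

    Defaults reproduce the published cohort's summary structure: 190
    patients, 115/190 male, ages 35-82, published per-gender marginals
    and age correlations, and a stage 2/3/4/5 mix of 4/50/38/8% (the mix
    is emergent from the eGFR marginal and the stage bands, matched
    approximately rather than enforced).
    """

    n: int = 190
    sex_ratio: float = 115 / 190
    age_range: tuple[float, float] = (35.0, 82.0)
    marginals: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in TABLE2_MARGINALS.items()})
    target_age_correlations: dict = field(
        default_factory=lambda: dict(TABLE4_AGE_CORRELATIONS))
    stage_mix: tuple[float, float, float, float] = (0.04, 0.50, 0.38, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ValueError("stage_mix must sum to 1")
        for sex, marg in self.marginals.items():
            for name, (_, sd) in marg.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {sex}/{name}")


def ckd_stage_from_egfr(egfr) -> np.ndarray:
    """CKD stage (1-5) from eGFR via the clinical bands.

    >=90 stage 1; 60-89 stage 2; 30-59 stage 3; 15-29 stage 4; <15
    stage 5.
    """
    e = np.asarray(egfr, dtype=float)
    stage = np.full(e.shape, 5, dtype=int)
    stage[e >= 15] = 4
    stage[e >= 30] = 3
    stage[e >= 60] = 2
    stage[e >= 90] = 1
    return stage


def _latent_correlation(spec: CohortSpec) -> np.ndarray:
    """Latent correlation over ``_LATENT_VARS``.

    Age-biomarker entries come from the spec's targets; biomarker-
    biomarker entries from the published correlation matrix.  A nearest-
    PSD repair (eigenvalue clipping, diagonal renormalized) is applied;
    a repair that moves any entry by more than 0.1 means the requested
    targets are jointly infeasible and raises a configuration error
    naming the worst pair.
    """
    full = load_fixture("table4_correlations")
    k = len(_LATENT_VARS)
    R = np.eye(k)
    for i, a in enumerate(_LATENT_VARS):
        for j, b in enumerate(_LATENT_VARS):
            if i == j:
                continue
            if a == "age":
                R[i, j] = spec.target_age_correlations.get(b, 0.0)
            elif b == "age":
                R[i, j] = spec.target_age_correlations.get(a, 0.0)
            else:
                R[i, j] = float(full.loc[a, b])
    R = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-10:
        clipped = np.clip(vals, 1e-8, None)
        R_psd = vecs @ np.diag(clipped) @ vecs.T
        d = np.sqrt(np.diag(R_psd))
        R_psd = R_psd / np.outer(d, d)
        delta = np.abs(R_psd - R)
        np.fill_diagonal(delta, 0.0)
        worst = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[worst] > 0.1:
            pair = (_LATENT_VARS[worst[0]], _LATENT_VARS[worst[1]])
            raise ScreenConfigError(
                f"correlation targets are jointly infeasible; the "
                f"{pair[0]}-{pair[1]} entry cannot be honored "
                f"(required adjustment {delta[worst]:.3f})"
            )
        logger.info(
            "nearest-PSD repair applied to latent correlation matrix "
            "(adjustment Frobenius norm %.4f)", float(np.linalg.norm(R_psd - R)),
        )
        R = R_psd
    return R


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - sigma**2 / 2.0
    return mu, sigma


def generate(spec: CohortSpec | None = None, **kwargs) -> pd.DataFrame:
    """Generate a synthetic CKD cohort.

    Keyword arguments override :class:`CohortSpec` fields when ``spec``
    is omitted.  Deterministic under a fixed ``seed``.
    """
    if spec is None:
        spec = CohortSpec(**kwargs)
    if spec.n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in _COLUMNS})
    rng = np.random.default_rng(spec.seed)
    R = _latent_correlation(spec)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
    z = rng.standard_normal((spec.n, R.shape[0])) @ L.T
    zcol = {name: z[:, i] for i, name in enumerate(_LATENT_VARS)}

    male = stats.norm.cdf(zcol["gender"]) < spec.sex_ratio
    sex = np.where(male, "male", "female")

    def scaled(name: str) -> np.ndarray:
        out = np.empty(spec.n)
        for s in ("male", "female"):
            m, sd = spec.marginals[s][name]
            sel = sex == s
            out[sel] = m + sd * zcol[name][sel]
        return out

    age = np.clip(scaled("age"), *spec.age_range)
    height = np.clip(scaled("height"), 1.2, 2.2)
    weight = np.clip(scaled("weight"), 30.0, None)
    sbp = np.clip(scaled("sbp"), 70.0, None)
    dbp = np.clip(scaled("dbp"), 40.0, None)
    creatinine = np.clip(scaled("creatinine"), 20.0, None)
    egfr = np.clip(scaled("egfr"), 1.0, 120.0)

    # CTCA: right-skewed nonnegative score; lognormal marginal matched to
    # the per-gender mean and SD, monotone in the latent normal so the
    # sign of its age correlation is preserved.
    ctca = np.empty(spec.n)
    for s in ("male", "female"):
        m, sd = spec.marginals[s]["ctca"]
        mu, sigma = _lognormal_params(m, sd)
        sel = sex == s
        ctca[sel] = np.exp(mu + sigma * zcol["ctca"][sel])

    bmi = weight / height**2
    stage = ckd_stage_from_egfr(egfr)

    return pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(spec.n)],
        "age": age,
        "gender": male.astype(int),  # 0 = female, 1 = male
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "sbp": sbp,
        "dbp": dbp,
        "creatinine": creatinine,
        "egfr": egfr,
        "ctca": ctca,
        "ckd_stage": stage,
    })


def split(
    cohort: pd.DataFrame, train_fraction: float = 0.70, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test split; sizes round(n*f) and remainder."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(cohort)
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = cohort.iloc[np.sort(perm[:n_train])]
    test = cohort.iloc[np.sort(perm[n_train:])]
    return train, test


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged published-table fixture.

    ``"table4_correlations"`` — 11x11 symmetric age/biomarker Pearson
    correlation matrix (unit diagonal), indexed by biomarker label.
    ``"table6_training"`` — 133-row training cohort of (no, ca,
    ckd_stage, ba_index, ba).
    """
    files = {
        "table4_correlations": "table4_correlations.csv",
        "table6_training": "table6_training.csv",
    }
    if name not in files:
        raise LookupError(
            f"unknown fixture {name!r}; available: {sorted(files)}")
    ref = resources.files("ckdbioage.fixtures") / files[name]
    with ref.open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    if name == "table4_correlations":
        df = df.set_index("biomarker")
        df.columns.name = None
    return df
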