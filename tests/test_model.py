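"""Composite index, BA transform, cohort scoring and gain summaries."""

import numpy as np
import pandas as pd
import pytest

from ckdbioage import (
    BioAgeIndex,
    WeightVector,
    build_builtin_indices,
    cohort_sd,
    composite_index,
    estimate_ba,
    gain_summary,
    generate,
    score_cohort,
)
from ckdbioage.model import (
    ModelConfigError,
    estimates_from_table,
    estimates_frame,
    round_half_up,
)
from ckdbioage.screening import DegenerateInputError, SchemaError

EQ11_WEIGHTS = WeightVector([
    ("bmi", 0.173 / 1.217), ("ctca", 0.249 / 1.217), ("egfr", 0.233 / 1.217),
    ("sbp", 0.151 / 1.217), ("dbp", 0.411 / 1.217),
])


class TestCompositeIndex:
    def test_all_zero_components(self):
        comps = {b: 0.0 for b in EQ11_WEIGHTS.labels}
        assert composite_index(EQ11_WEIGHTS, comps) == 0.0

    def test_all_one_components(self):
        comps = {b: 1.0 for b in EQ11_WEIGHTS.labels}
        assert composite_index(EQ11_WEIGHTS, comps) == pytest.approx(1.0, abs=1e-12)

    def test_single_active_component_recovers_weight(self):
        comps = dict.fromkeys(EQ11_WEIGHTS.labels, 0.0)
        comps["bmi"] = 1.0
        assert composite_index(EQ11_WEIGHTS, comps) == pytest.approx(
            0.1422, abs=5e-5)

    def test_matches_brute_force_dot_product(self, rng):
        for _ in range(30):
            k = rng.integers(1, 8)
            raw = rng.uniform(0.05, 1.0, size=k)
            w = WeightVector((f"b{i}", v) for i, v in enumerate(raw / raw.sum()))
            comps = {f"b{i}": rng.uniform(0, 1) for i in range(k)}
            brute = sum(w[f"b{i}"] * comps[f"b{i}"] for i in range(k))
            assert composite_index(w, comps) == pytest.approx(brute, abs=1e-12)

    def test_label_mismatch_is_schema_error(self):
        with pytest.raises(SchemaError):
            composite_index(EQ11_WEIGHTS, {"bmi": 0.5})


class TestEstimateBA:
    def test_zero_index_gives_ca(self):
        est = estimate_ba(0.0, ca=60, sd=9.5)
        assert est.ba == 60.0 and est.ba_reported == 60 and est.gain == 0

    def test_direct_evaluation(self):
        est = estimate_ba(0.5, ca=60, sd=10.0)
        assert est.ba == pytest.approx(65.0)
        assert est.ba_reported == 65

    def test_full_index_at_published_extreme(self):
        # oldest critically ill patient in the published training table:
        # CA 81, index 1.0000 -> BA 90 under a cohort SD of 9 years
        est = estimate_ba(1.0, ca=81, sd=9.0)
        assert est.ba_reported == 90

    def test_reported_ba_rounds_half_up(self):
        assert estimate_ba(0.5, ca=60, sd=9.0).ba_reported == 65  # 64.5 up
        assert estimate_ba(0.49, ca=60, sd=9.0).ba_reported == 64

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ModelConfigError):
            estimate_ba(0.5, ca=60, sd=0.0)

    def test_monotone_in_composite_and_gain_bounds(self):
        sd, ca = 9.657, 55.0
        comps = np.linspace(0, 1, 101)
        bas = [estimate_ba(c, ca, sd).ba for c in comps]
        assert np.all(np.diff(bas) > 0)
        for c in comps:
            est = estimate_ba(c, ca, sd)
            assert 0.0 <= est.gain_unrounded <= sd
            assert est.gain_unrounded == pytest.approx(c * sd, abs=1e-12)

    def test_gain_invariant_to_ca(self):
        for ca in (40.0, 60.0, 80.0):
            assert estimate_ba(0.7, ca, 10.0).gain_unrounded == pytest.approx(7.0)


class TestCohortSD:
    def test_hand_computed(self):
        assert cohort_sd([50, 60, 70]) == pytest.approx(10.0)

    def test_constant_cohort_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert cohort_sd([60, 60, 60]) == 0.0
        assert any("SD" in r.message for r in caplog.records)

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            cohort_sd([60.0])


class TestScoreCohort:
    def test_cross_module_consistency_on_toy(self, builtin_indices):
        cohort = pd.DataFrame({
            "age": [60.0, 70.0],
            "bmi": [25.0, 32.0],
            "sbp": [132.5, 118.0],
            "dbp": [86.0, 95.0],
            "egfr": [52.5, 12.0],
            "ctca": [250.0, 450.0],
        })
        est = score_cohort(cohort, builtin_indices, EQ11_WEIGHTS, sd=9.0)
        for i, row in cohort.iterrows():
            for b in EQ11_WEIGHTS.labels:
                assert est[i].component_indices[b] == pytest.approx(
                    builtin_indices[b](row[b]), abs=1e-12)
            brute = sum(EQ11_WEIGHTS[b] * est[i].component_indices[b]
                        for b in EQ11_WEIGHTS.labels)
            assert est[i].composite == pytest.approx(brute, abs=1e-12)
            assert est[i].ba == pytest.approx(row["age"] + 9.0 * brute)

    def test_all_normal_readings_give_zero_gain(
            self, builtin_indices, normal_cohort_row):
        cohort = pd.DataFrame([
            dict(normal_cohort_row, age=a) for a in (45.0, 60.0, 75.0)])
        est = score_cohort(cohort, builtin_indices, EQ11_WEIGHTS)
        assert all(e.composite == 0.0 and e.gain == 0 for e in est)

    def test_synthetic_cohort_gains_nonnegative(
            self, builtin_indices, synthetic_cohort):
        est = score_cohort(synthetic_cohort.head(500), builtin_indices,
                           EQ11_WEIGHTS)
        assert all(e.gain >= 0 for e in est)
        assert all(e.ba >= e.ca for e in est)

    def test_incomplete_rows_skipped(self, builtin_indices):
        cohort = pd.DataFrame({
            "age": [60.0, 61.0, 62.0],
            "bmi": [25.0, np.nan, 26.0],
            "sbp": [130.0] * 3, "dbp": [85.0] * 3,
            "egfr": [40.0] * 3, "ctca": [150.0] * 3,
        })
        est = score_cohort(cohort, builtin_indices, EQ11_WEIGHTS, sd=9.0)
        assert len(est) == 2

    def test_empty_cohort(self, builtin_indices):
        with pytest.raises(DegenerateInputError):
            score_cohort(pd.DataFrame(), builtin_indices, EQ11_WEIGHTS)

    def test_missing_biomarker_column_named(self, builtin_indices):
        cohort = pd.DataFrame({"age": [60.0, 61.0, 62.0]})
        with pytest.raises(SchemaError, match="bmi"):
            score_cohort(cohort, builtin_indices, EQ11_WEIGHTS, sd=9.0)


class TestGainSummary:
    def test_published_training_table(self, table6):
        est = estimates_from_table(table6, index_column="ba_index")
        summary = gain_summary(est, stages=table6["ckd_stage"])
        assert summary.n == 133
        assert summary.min_gain == 3
        assert summary.max_gain == 9
        assert summary.mean_gain_years == 7
        assert summary.pct_increase_bins.sum() == 133
        assert summary.pct_increase_bins_by_stage.to_numpy().sum() == 133

    def test_single_estimate(self):
        est = estimate_ba(0.5, ca=60, sd=10.0)  # gain 5
        s = gain_summary([est])
        assert s.mean_gain == s.min_gain == s.max_gain == 5

    def test_two_estimates_mean(self):
        ests = [estimate_ba(0.3, 60, 10.0), estimate_ba(0.9, 60, 10.0)]
        s = gain_summary(ests)
        assert (s.min_gain, s.max_gain) == (3, 9)
        assert s.mean_gain == pytest.approx(6.0)


class TestModelObject:
    def test_fit_consistent_with_manual_pipeline(self, small_cohort):
        """fit() wires screening, selection, redundancy and weighting the
        same way the individual operations do when run by hand."""
        from ckdbioage import (
            compute_weights, resolve_redundancy, screen_cohort,
            select_by_threshold,
        )
        from ckdbioage.model import DEFAULT_CANDIDATES

        res = BioAgeIndex(small_cohort).fit()
        manual = screen_cohort(small_cohort, DEFAULT_CANDIDATES)
        age_corrs = {r.biomarker_name: r.r for r in manual}
        selected = select_by_threshold(manual)
        corr = small_cohort[list(DEFAULT_CANDIDATES)].corr()
        retained = resolve_redundancy(selected, corr, age_corrs=age_corrs)
        scorable = [b for b in retained if b in res.model.severity_indices]
        assert res.selected == selected
        assert res.retained == scorable
        assert res.weights == compute_weights(
            {b: age_corrs[b] for b in scorable})
        assert sum(v for _, v in res.weights) == pytest.approx(1.0, abs=1e-12)
        assert res.sd == pytest.approx(cohort_sd(small_cohort["age"]))
        # the redundancy rules never let both members of a ruled pair
        # survive together
        assert not {"weight", "bmi"} <= set(res.retained)
        assert not {"creatinine", "egfr"} <= set(res.retained)

    def test_predict_frame_and_summary(self, small_cohort):
        res = BioAgeIndex(small_cohort).fit()
        frame = res.predict_frame()
        assert {"ca", "composite", "ba", "gain"} <= set(frame.columns)
        assert (frame["gain"] >= 0).all()
        text = res.summary()
        assert "Biological Age Index Model" in text
        assert "dbp" in text

    def test_predict_on_new_cohort_uses_its_own_sd(self, small_cohort):
        res = BioAgeIndex(small_cohort).fit()
        test = generate(n=57, seed=99)
        est = res.predict(test)
        assert est[0].sd == pytest.approx(cohort_sd(test["age"]))

    def test_gain_summary_by_stage(self, small_cohort):
        res = BioAgeIndex(small_cohort).fit()
        s = res.gain_summary(stage_column="ckd_stage")
        assert s.pct_increase_bins_by_stage is not None
        assert s.pct_increase_bins_by_stage.to_numpy().sum() == s.n

    def test_bland_altman_all_negative(self, small_cohort):
        res = BioAgeIndex(small_cohort).fit()
        summary = res.bland_altman()
        assert summary.mean_diff < 0

    def test_tiny_cohort_rejected(self):
        with pytest.raises(DegenerateInputError):
            BioAgeIndex(generate(n=2, seed=0))


def test_round_half_up():
    assert round_half_up(64.5) == 65
    assert round_half_up(63.5) == 64  # not banker's rounding
    assert round_half_up(64.49) == 64
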