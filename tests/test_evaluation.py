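"""Discrimination statistics, thresholds, lead time, calibration, case mix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hemodyn as h
from hemodyn.evaluation import year_groups

from _oracles import pair_counting_auroc


class TestAuroc:
    def test_perfect_separation(self):
        assert h.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert h.auroc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_tie_counts_half(self):
        assert h.auroc([0.5, 0.5], [1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            h.auroc([0.5, 0.6], [1, 1])

    def test_missing_scores_dropped_pairwise(self):
        assert h.auroc([0.9, np.nan, 0.1], [1, 1, 0]) == 1.0

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = rng.normal(size=30)
            y = rng.integers(0, 2, size=30)
            if 0 < y.sum() < 30:
                assert h.auroc(s, y) + h.auroc(-s, y) == pytest.approx(1.0)

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            s = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
            y = rng.integers(0, 2, size=n)
            if 0 < y.sum() < n:
                assert h.auroc(s, y) == pytest.approx(
                    pair_counting_auroc(s, y), abs=1e-12
                )


class TestDelong:
    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.normal(size=100) + rng.integers(0, 2, size=100)
            y = rng.integers(0, 2, size=100)
            if y.sum() < 2 or y.sum() > 98:
                continue
            res = h.delong_ci(s, y)
            assert 0.0 <= res.ci_low <= res.auroc <= res.ci_high <= 1.0

    def test_perfect_separation_degenerate_flagged(self):
        res = h.delong_ci([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.auroc == 1.0
        assert res.ci_low == res.ci_high == 1.0
        assert res.degenerate

    def test_paired_identical_scores(self):
        s = np.linspace(0, 1, 40)
        y = (np.arange(40) % 2 == 0).astype(int)
        z, p = h.delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_paired_antisymmetry(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=120)
        a = rng.normal(size=120) + y
        b = rng.normal(size=120) + 0.3 * y
        z1, p1 = h.delong_paired_test(a, b, y)
        z2, p2 = h.delong_paired_test(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_paired_detects_clear_difference(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1, 0], 200)
        good = y + rng.normal(0, 0.05, 400)  # nearly separating
        noise = rng.normal(size=400)
        _, p = h.delong_paired_test(good, noise, y)
        assert p < 0.001


class TestTimeVarying:
    @staticmethod
    def _samples(n_pos=30, n_neg=60, leads=(1, 2, 3)):
        rows = []
        for lead in leads:
            for i in range(n_pos):
                rows.append({"lead_hours": lead, "label": 1})
        for i in range(n_neg):
            rows.append({"lead_hours": 0, "label": 0})
        return pd.DataFrame(rows)

    def test_constant_score_gives_half_everywhere(self):
        samples = self._samples()
        table = h.time_varying_auroc(samples, np.full(len(samples), 0.4), leads=[1, 2, 3])
        assert (table["auroc"] == 0.5).all()

    def test_single_lead_table(self):
        samples = self._samples(leads=(1,))
        rng = np.random.default_rng(0)
        table = h.time_varying_auroc(samples, rng.random(len(samples)), leads=[1])
        assert len(table) == 1
        assert table.loc[0, "lead_hours"] == 1

    def test_empty_lead_omitted(self):
        samples = self._samples(leads=(1,))
        table = h.time_varying_auroc(
            samples, np.random.default_rng(0).random(len(samples)), leads=[1, 7]
        )
        assert set(table["lead_hours"]) == {1}


class TestThresholds:
    def test_extreme_thresholds(self):
        s = np.array([0.2, 0.6, 0.8, 0.4])
        y = np.array([0, 1, 1, 0])
        sweep = h.threshold_sweep(s, y)
        at0 = sweep.iloc[0]
        assert at0["threshold"] == 0.0 and at0["recall"] == 1.0
        at1 = sweep.iloc[-1]
        assert at1["recall"] == 0.0 and at1["specificity"] == 1.0

    def test_monotonicity_and_cell_sums(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 200
            s = rng.random(n)
            y = rng.integers(0, 2, size=n)
            sweep = h.threshold_sweep(s, y)
            assert (np.diff(sweep["recall"]) <= 1e-12).all()
            assert (np.diff(sweep["specificity"]) >= -1e-12).all()
            assert (sweep[["tp", "fp", "tn", "fn"]].sum(axis=1) == n).all()

    def test_select_policies(self):
        sweep = pd.DataFrame(
            {
                "threshold": [0.1, 0.5, 0.9],
                "recall": [1.0, 0.7, 0.2],
                "specificity": [0.1, 0.65, 0.99],
            }
        )
        assert h.select_threshold(sweep, "fixed", value=0.7) == 0.7
        assert h.select_threshold(sweep, "break_even") == 0.5
        assert h.select_threshold(sweep, "min_recall", min_recall=0.6) == 0.5
        with pytest.raises(ValueError, match="empty"):
            h.select_threshold(sweep.iloc[:0])
        with pytest.raises(ValueError, match="unknown threshold policy"):
            h.select_threshold(sweep, "magic")


class TestLeadTime:
    @staticmethod
    def _series():
        rows = []
        # u1: onset 30, scores cross 0.7 from lead 7 onward (times 23..29)
        for t in range(6, 30):
            lead = 30 - t
            rows.append(("u1", float(t), 0.9 if lead <= 7 else 0.1))
        # u2: onset 30, never crosses
        for t in range(6, 30):
            rows.append(("u2", float(t), 0.2))
        # s1: stable, hourly for 24 h, crosses at hours 3 and 4
        for t in range(1, 25):
            rows.append(("s1", float(t), 0.8 if t in (3, 4) else 0.1))
        return pd.DataFrame(rows, columns=["patient_id", "reference_time", "score"])

    @staticmethod
    def _labels():
        return pd.DataFrame(
            {
                "patient_id": ["u1", "u2", "s1"],
                "group": ["unstable", "unstable", "stable"],
                "onset_time": [30.0, 30.0, np.nan],
            }
        )

    def test_first_alarm_is_earliest_crossing(self):
        res = h.lead_time_analysis(self._series(), self._labels(), threshold=0.7)
        fa = res.first_alarms.set_index("patient_id")["first_alarm_lead_h"]
        assert fa["u1"] == 7.0
        assert np.isnan(fa["u2"])
        assert res.missed_fraction == 0.5

    def test_coverage_monotone_non_increasing(self):
        res = h.lead_time_analysis(self._series(), self._labels(), threshold=0.7)
        assert (np.diff(res.lead_coverage["fraction_alarmed"]) <= 1e-12).all()
        assert res.lead_coverage.loc[0, "fraction_alarmed"] == 0.5  # lead >= 1

    def test_true_alarm_fractions(self):
        res = h.lead_time_analysis(self._series(), self._labels(), threshold=0.7)
        ta = res.true_alarm_by_lead.set_index("lead_hours")["fraction"]
        assert ta[1] == 0.5  # u1 above, u2 below
        assert ta[8] == 0.0

    def test_false_alarm_rate(self):
        res = h.lead_time_analysis(self._series(), self._labels(), threshold=0.7)
        assert res.false_alarm_rate == pytest.approx(2 / 24)
        by_hour = res.false_alarm_by_hour.set_index("hour")["fraction"]
        assert by_hour[3] == 1.0 and by_hour[5] == 0.0


class TestCalibration:
    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        s = rng.random(500)
        y = rng.integers(0, 2, 500)
        table = h.calibration_table(s, y)
        assert table["count"].sum() == 500

    def test_all_negative_labels(self):
        s = np.linspace(0.01, 0.99, 100)
        table = h.calibration_table(s, np.zeros(100, dtype=int))
        nonempty = table[table["count"] > 0]
        assert (nonempty["observed_rate"] == 0.0).all()

    def test_self_consistent_bernoulli_draws(self):
        rng = np.random.default_rng(12)
        s = rng.random(4000)
        y = (rng.random(4000) < s).astype(int)
        table = h.calibration_table(s, y)
        for r in table[table["count"] > 0].itertuples():
            se = np.sqrt(max(r.mean_predicted * (1 - r.mean_predicted), 1e-12) / r.count)
            assert abs(r.observed_rate - r.mean_predicted) < 3 * se + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= n_bins"):
            h.calibration_table([0.5] * 5, [1, 0, 1, 0, 1])


class TestSubgroups:
    @staticmethod
    def _data(n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        s = np.clip(0.3 * y + rng.random(n) * 0.7, 0, 1)
        return s, y

    def test_whole_cohort_group_equals_global(self):
        s, y = self._data()
        table, _ = h.subgroup_metrics(s, y, np.repeat("all", len(s)))
        assert table.loc[0, "auroc"] == pytest.approx(h.delong_ci(s, y).auroc)

    def test_identical_groups_identical_metrics(self):
        s, y = self._data()
        g = np.where(np.arange(len(s)) % 2 == 0, "a", "b")
        # duplicate each sample into both groups
        s2 = np.concatenate([s, s])
        y2 = np.concatenate([y, y])
        g2 = np.concatenate([np.repeat("a", len(s)), np.repeat("b", len(s))])
        table, _ = h.subgroup_metrics(s2, y2, g2)
        a = table[table["group"] == "a"].drop(columns="group").reset_index(drop=True)
        b = table[table["group"] == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_group_skipped(self):
        s, y = self._data()
        g = np.where((y == 1) & (np.arange(len(y)) < 50), "onlypos", "mixed")
        table, skipped = h.subgroup_metrics(s, y, g)
        assert skipped == ["onlypos"]
        assert set(table["group"]) == {"mixed"}


def test_year_groups_merges_sparse_final_year():
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(110)],
            "admit_time": ["2018-05-01"] * 50 + ["2019-06-01"] * 50 + ["2020-02-01"] * 10,
        }
    )
    groups = year_groups(patients, min_count=50)
    assert set(groups) == {"2018", "2019-2020"}


class TestCaseMix:
    def test_identical_cohorts_zero_shift(self, registry, samples400):
        feats = samples400.frame
        report = h.case_mix_report(feats, feats, registry)
        comparable = report.feature_medians.query("comparable")
        assert (comparable["pct_diff"].abs() < 1e-12).all()

    def test_engineered_median_shifts(self, registry):
        # odd-length samples pin the medians exactly
        a = pd.DataFrame({"glucose": [100.0, 123.0, 140.0],
                          "bun": [10.0, 18.0, 25.0],
                          "ast": [20.0, 27.0, 30.0]})
        b = pd.DataFrame({"glucose": [150.0, 168.0, 190.0],
                          "bun": [20.0, 31.0, 40.0],
                          "ast": [40.0, 47.0, 60.0]})
        report = h.case_mix_report(a, b, registry)
        med = report.feature_medians.set_index("variable")["pct_diff"]
        assert med["glucose"] == pytest.approx(36.585, abs=0.01)
        assert med["bun"] == pytest.approx(72.222, abs=0.01)
        assert med["ast"] == pytest.approx(74.074, abs=0.01)

    def test_baseline_tests_reported(self, registry):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(
            {"age": rng.normal(65, 10, 80), "gender": rng.choice(["M", "F"], 80),
             "glucose": rng.normal(120, 20, 80)}
        )
        b = pd.DataFrame(
            {"age": rng.normal(70, 10, 80), "gender": rng.choice(["M", "F"], 80),
             "glucose": rng.normal(160, 20, 80)}
        )
        report = h.case_mix_report(a, b, registry, baseline_a=a, baseline_b=b,
                                   continuous=("age",), categorical=("gender",))
        assert set(report.continuous_tests["variable"]) == {"age"}
        assert set(report.categorical_tests["variable"]) == {"gender"}
        assert ((report.categorical_tests["p_value"] > 0)
                & (report.categorical_tests["p_value"] <= 1)).all()


class TestFisherExact:
    def test_matches_scipy_on_2x2(self):
        table = np.array([[8, 2], [1, 5]])
        assert h.fisher_exact_p(table) == pytest.approx(
            stats.fisher_exact(table)[1]
        )

    def test_monte_carlo_rxc_close_to_exact_2x2(self):
        # MC path forced via a 2x3 table collapsible to a clear association
        rng = np.random.default_rng(0)
        table = np.array([[40, 5, 5], [5, 40, 5]])
        p = h.fisher_exact_p(table, n_mc=5000, seed=1)
        assert p < 0.001

    def test_null_table_large_p(self):
        table = np.array([[20, 20, 20], [20, 20, 20]])
        assert h.fisher_exact_p(table, n_mc=2000, seed=1) > 0.5
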