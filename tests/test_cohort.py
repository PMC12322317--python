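"""Inclusion filters, longitudinal feature derivation, preprocessing."""

import numpy as np
import pandas as pd
import pytest

from npscreen import CohortConfig, apply_inclusion_filters, generate_cohort
from npscreen.cohort import EmptyCohortWarning, FeaturePreprocessor, derive_longitudinal_features
from npscreen.synthetic import Cohort


def _toy_cohort():
    parts = pd.DataFrame(
        {
            "participant_id": ["P1", "P2", "P3", "P4", "P5"],
            "autopsy": [False, False, True, True, True],
            "age_at_death": [np.nan, np.nan, 64.0, 80.0, 82.0],
            "n_visits": [1, 1, 4, 4, 2],
            "cognitive_status_final": ["normal"] * 5,
        }
    )
    rows = []
    for pid, ages, ybds in [
        ("P1", [59.0], [np.nan]),          # under 60: excluded everywhere
        ("P2", [75.0], [np.nan]),
        ("P3", [60, 61, 62, 63], [4, 3, 2, 1]),   # autopsy at 64: too young
        ("P4", [76, 77, 78, 79], [4, 3, 2, 1]),
        ("P5", [80, 81], [2, 1]),                 # only 2 visits
    ]:
        for i, (a, y) in enumerate(zip(ages, ybds), start=1):
            rows.append(
                {"participant_id": pid, "visit_index": i, "age_at_visit": float(a),
                 "years_before_death": y, "cognitive_status": "normal"}
            )
    return Cohort(parts, pd.DataFrame(rows), pd.DataFrame({"participant_id": ["P3", "P4", "P5"]}))


class TestInclusionFilters:
    def test_under_60_excluded_from_both_sets(self):
        c = _toy_cohort()
        gen = apply_inclusion_filters(c, "generalized", seed=0)
        assert "P1" not in set(gen["participant_id"])
        t = apply_inclusion_filters(c, "t_minus", seed=0)
        assert "P1" not in set(t["participant_id"])

    def test_autopsy_before_65_excluded_from_t_minus(self):
        t = apply_inclusion_filters(_toy_cohort(), "t_minus", seed=0)
        assert "P3" not in set(t["participant_id"])
        assert "P4" in set(t["participant_id"])

    def test_fewer_than_three_visits_excluded_from_t_minus(self):
        t = apply_inclusion_filters(_toy_cohort(), "t_minus", seed=0)
        assert "P5" not in set(t["participant_id"])

    def test_generalized_selects_one_visit_per_participant(self, small_cohort):
        gen = apply_inclusion_filters(small_cohort, "generalized", seed=3)
        assert gen["participant_id"].is_unique
        assert (gen["age_at_visit"] >= 60).all()

    def test_filters_idempotent(self, small_cohort):
        gen1 = apply_inclusion_filters(small_cohort, "generalized", seed=3)
        gen2 = apply_inclusion_filters(
            Cohort(small_cohort.participants, gen1, small_cohort.neuropathology),
            "generalized",
            seed=3,
        )
        pd.testing.assert_frame_equal(
            gen1.sort_values("participant_id").reset_index(drop=True),
            gen2.sort_values("participant_id").reset_index(drop=True),
        )
        t1 = apply_inclusion_filters(small_cohort, "t_minus", seed=3)
        t2 = apply_inclusion_filters(
            Cohort(small_cohort.participants, t1, small_cohort.neuropathology),
            "t_minus",
            seed=3,
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_result_warns(self):
        c = _toy_cohort()
        with pytest.warns(EmptyCohortWarning):
            apply_inclusion_filters(c, "t_minus", seed=0, autopsy_age_threshold=120)

    def test_unknown_kind_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            apply_inclusion_filters(small_cohort, "everything")


def _toy_visits(values, ybd, feature="gds_total"):
    n = len(values)
    return pd.DataFrame(
        {
            "participant_id": ["P1"] * n,
            "visit_index": range(1, n + 1),
            "years_before_death": ybd,
            "age_at_visit": [80 - y for y in ybd],
            feature: values,
        }
    )


class TestLongitudinalDerivation:
    def test_constant_feature_zero_slope_zero_sd(self):
        d = derive_longitudinal_features(_toy_visits([2.0, 2.0, 2.0], [3, 2, 1]))
        assert d.loc["P1", "gds_total__slope"] == pytest.approx(0.0)
        assert d.loc["P1", "gds_total__sd"] == pytest.approx(0.0)

    def test_unit_slope_toward_death(self):
        # values 1,2,3 at 3,2,1 years before death rise by 1 per year
        d = derive_longitudinal_features(_toy_visits([1.0, 2.0, 3.0], [3, 2, 1]))
        assert d.loc["P1", "gds_total__slope"] == pytest.approx(1.0)
        assert d.loc["P1", "gds_total__baseline"] == 1.0
        assert d.loc["P1", "gds_total__recent"] == 3.0

    def test_five_point_slope_matches_normal_equations(self):
        t = np.array([5.0, 4.0, 2.5, 1.5, 1.0])
        x = np.array([0.3, 1.1, 0.9, 2.0, 2.2])
        d = derive_longitudinal_features(_toy_visits(list(x), list(t)))
        tt = -t
        beta = ((tt - tt.mean()) * (x - x.mean())).sum() / ((tt - tt.mean()) ** 2).sum()
        assert d.loc["P1", "gds_total__slope"] == pytest.approx(beta, abs=1e-12)
        assert d.loc["P1", "gds_total__sd"] == pytest.approx(np.std(x, ddof=1))

    def test_fewer_than_three_visits_dropped(self):
        d = derive_longitudinal_features(_toy_visits([1.0, 2.0], [2, 1]))
        assert d.empty

    def test_all_missing_feature_yields_missing_entries(self):
        d = derive_longitudinal_features(
            _toy_visits([np.nan, np.nan, np.nan], [3, 2, 1])
        )
        assert np.isnan(d.loc["P1", "gds_total__slope"])
        assert np.isnan(d.loc["P1", "gds_total__baseline"])

    def test_categorical_mode_and_change(self, small_cohort):
        t = small_cohort.visits[small_cohort.visits["years_before_death"].notna()]
        d = derive_longitudinal_features(t)
        assert "sex__mode" in d.columns and "sex__changed" in d.columns
        # sex is stable per participant, so no observed change
        assert (d["sex__changed"].dropna() == 0.0).all()


class TestPreprocessing:
    def test_excessive_missingness_dropped(self):
        df = pd.DataFrame(
            {"gds_total": [1.0] + [np.nan] * 9, "mmse_total": np.arange(10.0)}
        )
        pp = FeaturePreprocessor(tiers=frozenset({1}), missing_threshold=0.2).fit(df)
        dropped = [c for c, _ in pp.report["dropped"]]
        assert "gds_total" in dropped and "mmse_total" not in dropped

    def test_zero_variance_dropped_with_report(self):
        df = pd.DataFrame({"gds_total": [3.0] * 8, "mmse_total": np.arange(8.0)})
        pp = FeaturePreprocessor(tiers=frozenset({1})).fit(df)
        assert ("gds_total", "zero variance") in pp.report["dropped"]

    def test_training_columns_standardized(self, small_sets):
        """Observed training values have mean 0 / SD 1 after the transform
        (imputed entries sit at the scaled median, so they are excluded)."""
        gen, _ = small_sets
        pp = FeaturePreprocessor(tiers=frozenset({1, 2, 3})).fit(gen)
        X = pp.transform(gen)
        for j, col in enumerate(pp._numeric):
            observed = pd.to_numeric(gen[col], errors="coerce").notna().to_numpy()
            vals = X[observed, j]
            assert abs(vals.mean()) < 1e-9
            assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_tier1_excludes_battery_apoe_and_cdr(self, small_sets):
        gen, _ = small_sets
        pp = FeaturePreprocessor(tiers=frozenset({1})).fit(gen)
        names = " ".join(pp.feature_names_)
        for banned in ("trails", "boston", "apoe", "cdr", "logical_memory", "digit"):
            assert banned not in names

    def test_statistics_come_from_training_rows_only(self, small_sets):
        gen, _ = small_sets
        train, test = gen.iloc[:150], gen.iloc[150:].copy()
        pp = FeaturePreprocessor(tiers=frozenset({1})).fit(train)
        before = pp.transform(test)
        # corrupting other test rows must not change a fixed row's transform
        test2 = test.copy()
        num_cols = [c for c in pp._numeric]
        test2.loc[test2.index[1:], num_cols] = 999.0
        after = pp.transform(test2)
        np.testing.assert_array_equal(before[0], after[0])

    def test_empty_tier_selection_rejected(self):
        with pytest.raises(ValueError):
            FeaturePreprocessor(tiers=frozenset())
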