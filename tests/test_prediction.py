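"""Evaluation metrics, condition grid pairing, and RM-ANOVA arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from npscreen.prediction import (
    AnovaResult,
    evaluate_predictions,
    macro_ovr_auc,
    posthoc_tier_anova,
    rm_anova,
    run_condition_grid,
)


def brute_force_macro_auc(y, proba, classes):
    """Exhaustive positive/negative pair counting, one-vs-rest per class."""
    aucs = []
    for i, c in enumerate(classes):
        pos = np.flatnonzero(y == c)
        neg = np.flatnonzero(y != c)
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = 0.0
        for p, n in itertools.product(pos, neg):
            if proba[p, i] > proba[n, i]:
                wins += 1.0
            elif proba[p, i] == proba[n, i]:
                wins += 0.5
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestMacroAuc:
    def test_oracle_probabilities_reach_one(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        classes = np.array(["a", "b", "c"])
        proba = np.eye(3)[[0, 1, 2, 0, 1, 2]]
        assert macro_ovr_auc(y, proba, classes) == 1.0

    def test_uniform_probabilities_give_half(self):
        y = np.array(["a", "b", "c"] * 4)
        proba = np.full((12, 3), 1 / 3)
        assert macro_ovr_auc(y, proba, np.array(["a", "b", "c"])) == 0.5

    def test_matches_pairwise_counting_on_toy_table(self):
        rng = np.random.default_rng(0)
        classes = np.array(["lo", "mid", "hi"])
        y = np.array(["lo", "lo", "lo", "mid", "mid", "mid", "hi", "hi", "hi"])
        proba = rng.dirichlet(np.ones(3), size=9)
        got = macro_ovr_auc(y, proba, classes)
        assert got == pytest.approx(brute_force_macro_auc(y, proba, classes), abs=1e-12)

    def test_missing_class_skipped_with_warning(self):
        y = np.array(["a", "b", "a", "b"])
        proba = np.random.default_rng(1).dirichlet(np.ones(3), size=4)
        with pytest.warns(UserWarning, match="absent"):
            auc = macro_ovr_auc(y, proba, np.array(["a", "b", "c"]))
        assert 0.0 <= auc <= 1.0

    def test_metrics_consistent_with_confusion_matrix(self):
        rng = np.random.default_rng(2)
        classes = np.array(["a", "b", "c"])
        y = rng.choice(classes, size=60)
        proba = rng.dirichlet(np.ones(3), size=60)
        ev = evaluate_predictions(y, proba, classes)
        cm = ev["confusion"]
        for i, c in enumerate(classes):
            tp = cm[i, i]
            ppv = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
            rec = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
            assert ev["per_class"].loc[c, "precision"] == pytest.approx(ppv)
            assert ev["per_class"].loc[c, "recall"] == pytest.approx(rec)
            denom = ppv + rec
            f1 = 2 * ppv * rec / denom if denom else 0.0
            assert ev["per_class"].loc[c, "f1"] == pytest.approx(f1)


def _hand_table(values):
    """3 tiers x 2 visit modes x 5 folds cell table."""
    rows = []
    for (i, t), (j, m) in itertools.product(
        enumerate(["1", "12", "123"]), enumerate(["single", "longitudinal"])
    ):
        for f in range(5):
            rows.append(
                {"tiers": t, "visit_mode": m, "fold": f, "auc": values[i][j][f]}
            )
    return pd.DataFrame(rows)


def rm_anova_oracle(y):
    """Direct sum-of-squares arithmetic on y[subject, A, B] (rational style)."""
    n, a, b = y.shape
    gm = y.mean()
    A = y.mean(axis=(0, 2)); B = y.mean(axis=(0, 1)); S = y.mean(axis=(1, 2))
    AB = y.mean(axis=0); AS = y.mean(axis=2); BS = y.mean(axis=1)
    ss_a = n * b * ((A - gm) ** 2).sum()
    ss_b = n * a * ((B - gm) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + gm) ** 2).sum()
    ss_s = a * b * ((S - gm) ** 2).sum()
    ss_as = b * ((AS - S[:, None] - A[None, :] + gm) ** 2).sum()
    ss_bs = a * ((BS - S[:, None] - B[None, :] + gm) ** 2).sum()
    ss_abs = ((y - gm) ** 2).sum() - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs
    Fa = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    Fb = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    Fab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return Fa, Fb, Fab


class TestRmAnova:
    def _random_table(self, seed):
        rng = np.random.default_rng(seed)
        return [[list(rng.uniform(0.5, 0.9, 5)) for _ in range(2)] for _ in range(3)]

    def test_identical_cells_give_zero_F(self):
        vals = [[[0.7] * 5] * 2] * 3
        res = {r.effect: r for r in rm_anova(_hand_table(vals))}
        for e in ("tier", "visit", "interaction"):
            assert res[e].F == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_with_five_folds(self):
        res = {r.effect: r for r in rm_anova(_hand_table(self._random_table(0)))}
        assert (res["tier"].df1, res["tier"].df2) == (2, 8)
        assert (res["visit"].df1, res["visit"].df2) == (1, 4)
        assert (res["interaction"].df1, res["interaction"].df2) == (2, 8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_direct_sum_of_squares(self, seed):
        vals = self._random_table(seed)
        y = np.zeros((5, 3, 2))
        for i in range(3):
            for j in range(2):
                y[:, i, j] = vals[i][j]
        Fa, Fb, Fab = rm_anova_oracle(y)
        res = {r.effect: r for r in rm_anova(_hand_table(vals))}
        assert res["tier"].F == pytest.approx(Fa, abs=1e-10)
        assert res["visit"].F == pytest.approx(Fb, abs=1e-10)
        assert res["interaction"].F == pytest.approx(Fab, abs=1e-10)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_independent_reference_implementation(self, seed):
        pingouin = pytest.importorskip("pingouin")
        df = _hand_table(self._random_table(seed))
        df["subject"] = df["fold"]
        ref = pingouin.rm_anova(
            data=df, dv="auc", within=["tiers", "visit_mode"], subject="subject",
            detailed=True,
        )
        res = {r.effect: r for r in rm_anova(df)}
        ref_f = dict(zip(ref["Source"], ref["F"]))
        assert res["tier"].F == pytest.approx(ref_f["tiers"], rel=1e-6)
        assert res["visit"].F == pytest.approx(ref_f["visit_mode"], rel=1e-6)
        assert res["interaction"].F == pytest.approx(
            ref_f["tiers * visit_mode"], rel=1e-6
        )

    def test_unbalanced_grid_rejected(self):
        t = _hand_table(self._random_table(6)).drop(index=[0])
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(t)

    def test_posthoc_df_with_five_folds(self):
        ph = posthoc_tier_anova(_hand_table(self._random_table(7)))
        assert (ph["df1"] == 2).all() and (ph["df2"] == 12).all()
        assert set(ph["visit_mode"]) == {"single", "longitudinal"}


class TestBaselines:
    def test_separable_toy_data_near_perfect(self):
        from npscreen.prediction import fit_baselines

        rng = np.random.default_rng(0)
        X = rng.standard_normal((240, 4))
        y = np.where(X[:, 0] > 0.5, "a", np.where(X[:, 0] < -0.5, "c", "b"))
        models = fit_baselines(X[:160], y[:160], seed=0)
        for name, m in models.items():
            proba = m.predict_proba(X[160:])
            order = [list(m.classes_).index(c) for c in np.unique(y)]
            auc = macro_ovr_auc(y[160:], proba[:, order], np.unique(y))
            assert auc > 0.97, name

    def test_label_free_noise_is_chance_level(self):
        from npscreen.prediction import fit_baselines

        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 6))
        y = rng.choice(["a", "b", "c"], size=400)
        models = fit_baselines(X[:280], y[:280], seed=1)
        for name, m in models.items():
            proba = m.predict_proba(X[280:])
            order = [list(m.classes_).index(c) for c in np.unique(y)]
            auc = macro_ovr_auc(y[280:], proba[:, order], np.unique(y))
            assert abs(auc - 0.5) < 0.12, name


class TestConditionGrid:
    @pytest.fixture(scope="class")
    def grid(self, small_sets, small_labels, small_cohort):
        _, t_minus = small_sets
        auto = set(small_cohort.participants.loc[
            small_cohort.participants["autopsy"], "participant_id"])
        unl = small_cohort.visits[~small_cohort.visits["participant_id"].isin(auto)]
        return run_condition_grid(
            t_minus, small_labels, unl, nfolds=3, seed=5,
            model_name="logistic",
            targets=("total_load",),
        )

    def test_fold_pairing_shared_across_conditions(self, grid):
        counts = grid.cells.groupby(["tiers", "visit_mode"])["fold"].nunique()
        assert (counts == 3).all()
        assert len(grid.cells) == 3 * 2 * 3  # tiers x modes x folds

    def test_tier_sets_nest_feature_counts(self, small_sets, small_labels):
        from npscreen.cohort import FeaturePreprocessor

        _, t_minus = small_sets
        sv = t_minus.groupby("participant_id").sample(1, random_state=0)
        n1 = len(FeaturePreprocessor(tiers=frozenset({1})).fit(sv).feature_names_)
        n12 = len(FeaturePreprocessor(tiers=frozenset({1, 2})).fit(sv).feature_names_)
        n123 = len(FeaturePreprocessor(tiers=frozenset({1, 2, 3})).fit(sv).feature_names_)
        assert n1 < n12 < n123

    def test_grid_deterministic_under_seed(self, small_sets, small_labels, small_cohort):
        _, t_minus = small_sets
        g1 = run_condition_grid(
            t_minus, small_labels, None, nfolds=3, seed=9,
            model_name="logistic", targets=("amyloid_load",),
            tier_sets=(frozenset({1}),),
        )
        g2 = run_condition_grid(
            t_minus, small_labels, None, nfolds=3, seed=9,
            model_name="logistic", targets=("amyloid_load",),
            tier_sets=(frozenset({1}),),
        )
        pd.testing.assert_frame_equal(g1.cells, g2.cells)

    def test_evaluations_cover_all_cells(self, grid):
        assert len(grid.evaluations) == 6
        for ev in grid.evaluations:
            assert len(ev.fold_aucs) == 3
            assert ev.per_class.shape[0] == 3
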