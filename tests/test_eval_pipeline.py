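"""Validation engine: folds, standardization, models, metrics, SFFS,
bootstrap inference, screening and the model-comparison report."""

import itertools

import numpy as np
import pandas as pd
import pytest

from swayrisk.eval_pipeline import (
    MODEL_SPECS,
    aggregate_subject,
    bootstrap_auc,
    bootstrap_auc_diff_test,
    brier,
    calibration_bins,
    evaluate_models,
    heatmap_matrix,
    loso_predict,
    loso_splits,
    make_model,
    screen_conditions,
    select_features,
    sffs,
    standardize_apply,
    standardize_fit,
    subject_auc,
    train_predict,
    youden_threshold,
)

from conftest import make_toy_features


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_auc(y, p):
    num = n = 0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] == 1 and y[j] == 0:
                n += 1
                if p[i] > p[j]:
                    num += 1
                elif p[i] == p[j]:
                    num += 0.5
    return num / n


def oracle_youden(y, p):
    best = (-1.0, None)
    for thr in sorted({(a + b) / 2 for a, b in zip(sorted(set(p)), sorted(set(p))[1:])} or set(p)):
        pred = [v >= thr for v in p]
        sens = sum(1 for v, l in zip(pred, y) if v and l == 1) / sum(y)
        spec = sum(1 for v, l in zip(pred, y) if not v and l == 0) / (len(y) - sum(y))
        j = sens + spec - 1
        if j > best[0] + 1e-15:
            best = (j, thr)
    return best[1]


# ---------------------------------------------------------------------------
# folds and standardization
# ---------------------------------------------------------------------------

class TestLosoSplits:
    def test_one_split_per_subject_partition(self, toy_features):
        splits = loso_splits(toy_features)
        subjects = sorted(toy_features["subject_id"].unique())
        assert len(splits) == len(subjects)
        assert sorted(t for _, t in splits) == subjects
        for train, test in splits:
            assert test not in train
            assert sorted(train + [test]) == subjects

    def test_degenerate_cohorts_rejected(self):
        single_class = make_toy_features(seed=0, n_pos=0, n_neg=5)
        with pytest.raises(ValueError):
            loso_splits(single_class)
        lone_positive = make_toy_features(seed=0, n_pos=1, n_neg=5)
        with pytest.raises(ValueError):
            loso_splits(lone_positive)


class TestStandardize:
    def test_two_point_column(self):
        mean, sd = standardize_fit(np.array([[0.0], [2.0]]))
        assert mean[0] == 1.0 and sd[0] == pytest.approx(np.sqrt(2))
        z = standardize_apply((mean, sd), np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(z.ravel(), [-0.7071067811865475, 0.7071067811865475])

    def test_train_params_on_train_are_zscores(self):
        X = np.random.default_rng(0).normal(3.0, 2.0, size=(40, 5))
        params = standardize_fit(X)
        Z = standardize_apply(params, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_test_set_uses_train_params_not_its_own(self):
        rng = np.random.default_rng(1)
        train, test = rng.normal(0, 1, (30, 2)), rng.normal(5, 1, (10, 2))
        params = standardize_fit(train)
        z_train_params = standardize_apply(params, test)
        z_self = standardize_apply(standardize_fit(test), test)
        assert not np.allclose(z_train_params, z_self)

    def test_zero_sd_passes_through_centered(self):
        X = np.c_[np.ones(10), np.arange(10.0)]
        Z = standardize_apply(standardize_fit(X), X)
        np.testing.assert_allclose(Z[:, 0], 0.0)


class TestTrainPredict:
    @pytest.fixture(scope="class")
    def blobs(self):
        rng = np.random.default_rng(42)
        X0 = rng.normal(-2, 0.5, size=(60, 2))
        X1 = rng.normal(+2, 0.5, size=(60, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        Xt0 = rng.normal(-2, 0.5, size=(20, 2))
        Xt1 = rng.normal(+2, 0.5, size=(20, 2))
        return X, y, np.vstack([Xt0, Xt1]), np.r_[np.zeros(20, int), np.ones(20, int)]

    @pytest.mark.parametrize("model_id", list(MODEL_SPECS))
    def test_separable_blobs_classified(self, blobs, model_id):
        X, y, Xt, yt = blobs
        p = train_predict(MODEL_SPECS[model_id], X, y, Xt)
        assert np.all((p >= 0) & (p <= 1))
        correct = ((p >= 0.5).astype(int) == yt).mean()
        assert correct >= 0.95

    @pytest.mark.parametrize("model_id", list(MODEL_SPECS))
    def test_deterministic_given_seed(self, blobs, model_id):
        X, y, Xt, _ = blobs
        a = train_predict(MODEL_SPECS[model_id], X, y, Xt)
        b = train_predict(MODEL_SPECS[model_id], X, y, Xt)
        np.testing.assert_array_equal(a, b)

    def test_single_class_training_rejected(self, blobs):
        X, y, Xt, _ = blobs
        with pytest.raises(ValueError):
            train_predict(MODEL_SPECS["DT"], X, np.zeros_like(y), Xt)


# ---------------------------------------------------------------------------
# subject-level metrics
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_examples(self):
        assert aggregate_subject(np.array([0.2, 0.4, 0.6])) == pytest.approx(0.4)
        assert aggregate_subject(np.array([0.7])) == 0.7
        assert aggregate_subject(np.array([0.6, 0.2, 0.4])) == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject(np.array([]))


class TestSubjectAuc:
    def test_trivial_values(self):
        y = np.r_[np.ones(3, int), np.zeros(5, int)]
        assert subject_auc(y, np.r_[np.full(3, 0.9), np.full(5, 0.1)]) == 1.0
        assert subject_auc(y, np.full(8, 0.5)) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = np.round(rng.uniform(size=32), 2)  # rounding forces some ties
        assert subject_auc(y, p) == pytest.approx(oracle_auc(y, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            subject_auc(np.ones(5, int), np.linspace(0, 1, 5))


class TestYouden:
    def test_perfect_separation(self):
        y = np.r_[np.ones(4, int), np.zeros(6, int)]
        p = np.r_[np.full(4, 0.9), np.full(6, 0.1)]
        thr, sens, spec = youden_threshold(y, p)
        assert sens == spec == 1.0
        assert 0.1 < thr < 0.9

    def test_all_equal_probabilities(self):
        y = np.r_[np.ones(4, int), np.zeros(6, int)]
        thr, sens, spec = youden_threshold(y, np.full(10, 0.4))
        assert sens + spec - 1 == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(1000 + seed)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = np.round(rng.uniform(size=32), 2)
        thr, sens, spec = youden_threshold(y, p)
        assert thr == pytest.approx(oracle_youden(list(y), list(p)), abs=1e-12)


class TestCalibrationAndBrier:
    def test_perfect_and_constant_brier(self):
        y = np.r_[np.ones(4, int), np.zeros(6, int)]
        assert brier(y, y.astype(float)) == 0.0
        assert brier(y, np.full(10, 0.5)) == 0.25

    def test_32_subjects_bin_counts(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = rng.uniform(size=32)
        tab = calibration_bins(y, p)
        assert sorted(tab["count"]) == [10, 11, 11]
        assert tab["count"].sum() == 32
        assert tab["mean_predicted"].is_monotonic_increasing

    def test_observed_fractions_track_labels(self):
        y = np.r_[np.zeros(10, int), np.ones(5, int)]
        p = np.r_[np.linspace(0.0, 0.4, 10), np.linspace(0.6, 1.0, 5)]
        tab = calibration_bins(y, p)
        assert tab["observed_fraction"].iloc[0] == 0.0
        assert tab["observed_fraction"].iloc[-1] == 1.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrapAuc:
    def test_perfect_separation_degenerate_summary(self):
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = np.r_[np.full(8, 0.9), np.full(24, 0.1)]
        bs = bootstrap_auc(y, p, B=500, seed=0)
        assert bs.auc_mean == 1.0 and bs.auc_sd == 0.0
        assert (bs.ci_low, bs.ci_high) == (1.0, 1.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = rng.uniform(size=32)
        a = bootstrap_auc(y, p, B=300, seed=7)
        b = bootstrap_auc(y, p, B=300, seed=7)
        assert a == b

    def test_null_ci_covers_half_in_most_seeds(self):
        """Probabilities independent of labels: the 95% CI should cover 0.5
        in at least 90% of 50 seeded instances."""
        cover = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(8, int), np.zeros(24, int)]
            p = rng.uniform(size=32)
            bs = bootstrap_auc(y, p, B=400, seed=seed)
            cover += bs.ci_low <= 0.5 <= bs.ci_high
        assert cover >= 45

    def test_small_B_rejected(self):
        y = np.r_[np.ones(4, int), np.zeros(4, int)]
        with pytest.raises(ValueError):
            bootstrap_auc(y, np.linspace(0, 1, 8), B=50)


class TestBootstrapDiff:
    def test_model_against_itself_p_one(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        p = rng.uniform(size=32)
        assert bootstrap_auc_diff_test(y, p, p, B=400, seed=1) == 1.0

    def test_dominant_model_detected(self):
        """A model strictly better on every subject should reach p <= 0.05
        in at least 80% of 50 seeded instances."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            y = np.r_[np.ones(8, int), np.zeros(24, int)]
            good = np.clip(y * 0.8 + rng.normal(0, 0.08, 32) + 0.1, 0, 1)
            bad = rng.uniform(size=32)
            p = bootstrap_auc_diff_test(y, good, bad, B=400, seed=seed)
            hits += p <= 0.05
        assert hits >= 40

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(8, int), np.zeros(24, int)]
        a, b = rng.uniform(size=32), rng.uniform(size=32)
        assert bootstrap_auc_diff_test(y, a, b, B=300, seed=2) == bootstrap_auc_diff_test(
            y, a, b, B=300, seed=2
        )


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

class TestSffs:
    def test_duplicate_feature_never_selected_twice(self):
        df = make_toy_features(seed=3)
        df["f00_copy"] = df["f00"]
        sel = sffs(df, ["f00", "f00_copy", "f01", "f03"], MODEL_SPECS["LR"])
        assert not ("f00" in sel and "f00_copy" in sel)

    def test_chosen_pair_matches_exhaustive_two_subset_oracle(self):
        """On a small toy whose two informative features are complementary,
        greedy-with-floating must find a pair as good as the exhaustive best."""
        df = make_toy_features(seed=11, n_informative=2, n_noise=4, effect=2.0)
        cands = [f"f{j:02d}" for j in range(6)]
        spec = MODEL_SPECS["LR"]

        from swayrisk.eval_pipeline import inner_loso_objective

        sel = sffs(df, cands, spec, max_features=2)
        best_pair = max(
            (inner_loso_objective(df, list(pair), spec) for pair in itertools.combinations(cands, 2))
        )
        assert inner_loso_objective(df, sel, spec) >= best_pair - 1e-4

    def test_rf_objective_recovers_informative_smoke(self):
        df = make_toy_features(seed=0)
        sel = sffs(df, [f"f{j:02d}" for j in range(10)], MODEL_SPECS["RF"])
        assert set(sel) <= {"f00", "f01", "f02"}

    def test_select_features_modes(self):
        df = make_toy_features(seed=1, n_pos=4, n_neg=8)
        cands = [f"f{j:02d}" for j in range(10)]
        desc = select_features(df, cands, MODEL_SPECS["LR"], mode="descriptive")
        assert desc["per_fold"] is None and len(desc["subset"]) >= 1
        nested = select_features(df, cands, MODEL_SPECS["LR"], mode="nested")
        assert len(nested["per_fold"]) == 12
        assert isinstance(nested["subset"], list)
        for test_subject, subset in nested["per_fold"].items():
            assert subset  # every fold selected something


# ---------------------------------------------------------------------------
# screening and model comparison
# ---------------------------------------------------------------------------

def make_condition_toy(seed, informative_condition="rs_ec"):
    """Four-condition toy features where only one condition carries signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(12):
        at_risk = i < 4
        for cond in ("rs_eo", "rs_ec", "us_eo", "us_ec"):
            for t in range(3):
                shift = 2.0 if (at_risk and cond == informative_condition) else 0.0
                rows.append({
                    "subject_id": f"S{i:02d}", "condition": cond, "trial_index": t + 1,
                    "label": "fall_risk" if at_risk else "no_fall_risk",
                    **{f"f{j}": shift + rng.normal() for j in range(5)},
                })
    return pd.DataFrame(rows)


class TestScreenConditions:
    def test_five_rows_and_ordering(self):
        df = make_condition_toy(0)
        tab = screen_conditions(df, MODEL_SPECS["DT"], B=200, seed=0)
        assert len(tab) == 5
        assert set(tab["condition"]) == {"rs_eo", "rs_ec", "us_eo", "us_ec", "all"}
        assert tab["auc_mean"].is_monotonic_decreasing

    def test_informative_condition_ranks_first_in_most_seeds(self):
        wins = 0
        for seed in range(20):
            tab = screen_conditions(make_condition_toy(seed), MODEL_SPECS["DT"], B=150, seed=seed)
            wins += tab["condition"].iloc[0] == "rs_ec"
        assert wins >= 16

    def test_all_pools_trials_across_conditions(self):
        df = make_condition_toy(1)
        base = MODEL_SPECS["DT"]
        subj_all, _ = loso_predict(df, [f"f{j}" for j in range(5)], base)
        assert len(subj_all) == 12  # one aggregated probability per subject


class TestEvaluateModels:
    @pytest.fixture(scope="class")
    def results(self):
        df = make_toy_features(seed=5, n_pos=5, n_neg=10, effect=2.0)
        return evaluate_models(df, "rs_ec", ["f00", "f01", "f02"], B=300, seed=0)

    def test_all_models_reported(self, results):
        assert set(results) == {"DT", "RF", "XGB", "LR", "SVM"}
        assert results["RF"].auc_diff_p is None
        for mid, r in results.items():
            if mid != "RF":
                assert 0.0 < r.auc_diff_p <= 1.0
            assert 0.0 <= r.brier_score <= 1.0
            assert r.bootstrap.ci_low <= r.bootstrap.auc_mean <= r.bootstrap.ci_high

    def test_heatmap_final_is_row_mean_and_risk_first(self, results):
        hm = heatmap_matrix(results["RF"])
        trial_cols = [c for c in hm.columns if c.startswith("trial_")]
        np.testing.assert_allclose(hm["FINAL"], hm[trial_cols].mean(axis=1))
        labels = list(hm["label"])
        first_norisk = labels.index("no_fall_risk")
        assert all(l == "no_fall_risk" for l in labels[first_norisk:])

    def test_leakage_provenance_audited(self, results):
        for r in results.values():
            for fold in r.folds:
                fold.assert_no_leakage()
                assert fold.test_subject not in fold.standardization_source

    def test_empty_subset_rejected(self):
        df = make_toy_features(seed=6)
        with pytest.raises(ValueError):
            evaluate_models(df, "rs_ec", [], B=300, seed=0)
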