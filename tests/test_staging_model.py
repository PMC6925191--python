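"""Balanced bagging, cross-validation protocols, and the actigraphy baseline."""

import numpy as np
import pandas as pd
import pytest

from somnostage.features import FeatureMatrix
from somnostage.io_model import ValidationError
from somnostage.staging_model import (
    BaggingConfig,
    actigraphy_baseline,
    learning_curve,
    loso_evaluate,
    personal_evaluate,
    predict_labels,
    predict_scores,
    train_balanced_bagging,
)


def make_fm(X, labels, subjects):
    X = pd.DataFrame(np.asarray(X, float))
    X.columns = [f"f{j}" for j in range(X.shape[1])]
    return FeatureMatrix(
        df=X,
        labels=pd.Series(list(labels), name="stage"),
        subjects=pd.Series(list(subjects), name="subject"),
        clip_starts=pd.Series(np.arange(len(X), dtype=float), name="clip_start_s"),
    )


def separable_fm(n_subjects=4, per_class=30, noise=0.05, seed=0):
    """Well-separated clusters per stage; subjects share the geometry."""
    rng = np.random.default_rng(seed)
    centers = {"W": [0, 0], "N2": [4, 0], "SWS": [0, 4], "REM": [4, 4]}
    rows, labels, subjects = [], [], []
    for s in range(n_subjects):
        for stage, c in centers.items():
            pts = rng.normal(c, noise, (per_class, 2))
            rows.append(pts)
            labels += [stage] * per_class
            subjects += [f"S{s}"] * per_class
    return make_fm(np.vstack(rows), labels, subjects)


def noise_fm(n_subjects=4, n_rows=60, imbalance=None, seed=0):
    """Pure-noise features; labels carry no signal."""
    rng = np.random.default_rng(seed)
    rows, labels, subjects = [], [], []
    for s in range(n_subjects):
        X = rng.standard_normal((n_rows, 3))
        if imbalance:
            majority = int(n_rows * imbalance / (imbalance + 1))
            labs = ["N2"] * majority + ["REM"] * (n_rows - majority)
        else:
            labs = list(rng.choice(["W", "N2", "REM"], n_rows))
        rows.append(X)
        labels += labs
        subjects += [f"S{s}"] * n_rows
    return make_fm(np.vstack(rows), labels, subjects)


class TestTraining:
    def test_per_tree_class_counts_equal_minority(self):
        fm = noise_fm(1, 100, imbalance=9, seed=1)
        model = train_balanced_bagging(
            fm, fm.labels, BaggingConfig(n_trees=10, seed=1), resolution=None
        )
        minority = min(np.sum(fm.labels == c) for c in model.classes)
        for counts in model.per_tree_class_counts:
            assert all(v == minority for v in counts.values())

    def test_default_ensemble_size_is_130(self):
        fm = separable_fm(1, per_class=10)
        model = train_balanced_bagging(fm, fm.labels, BaggingConfig())
        assert len(model.trees) == 130

    def test_separable_training_recall(self):
        fm = separable_fm(1, per_class=20, seed=2)
        two_class = fm.labels.isin(["W", "N2"]).to_numpy()
        fm2 = make_fm(fm.df[two_class].to_numpy(), fm.labels[two_class], fm.subjects[two_class])
        model = train_balanced_bagging(fm2, fm2.labels, BaggingConfig(n_trees=30, seed=3))
        pred = predict_labels(model, fm2)
        for c in model.classes:
            rows = fm2.labels.to_numpy() == c
            assert np.mean(pred[rows] == c) >= 0.99

    def test_single_class_rejected(self):
        fm = make_fm(np.random.default_rng(0).standard_normal((20, 2)), ["N2"] * 20, ["S"] * 20)
        with pytest.raises(ValidationError):
            train_balanced_bagging(fm, fm.labels, BaggingConfig(n_trees=5))

    def test_deterministic_under_seed(self):
        fm = noise_fm(2, 40, seed=4)
        cfg = BaggingConfig(n_trees=15, seed=9)
        m1 = train_balanced_bagging(fm, fm.labels, cfg)
        m2 = train_balanced_bagging(fm, fm.labels, cfg)
        s1 = predict_scores(m1, fm).to_numpy()
        s2 = predict_scores(m2, fm).to_numpy()
        np.testing.assert_array_equal(s1, s2)


class TestScores:
    def test_scores_sum_to_one(self):
        fm = noise_fm(2, 40, seed=5)
        model = train_balanced_bagging(fm, fm.labels, BaggingConfig(n_trees=20, seed=5))
        s = predict_scores(model, fm).to_numpy()
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
        assert (s >= 0).all() and (s <= 1).all()

    def test_deep_interior_point_scores_high(self):
        fm = separable_fm(1, per_class=25, seed=6)
        model = train_balanced_bagging(fm, fm.labels, BaggingConfig(n_trees=30, seed=6))
        probe = pd.DataFrame([[4.0, 4.0]], columns=fm.df.columns)
        s = predict_scores(model, probe)
        assert s["REM"].iloc[0] > 0.9

    def test_column_permutation_is_schema_keyed(self):
        fm = separable_fm(1, per_class=15, seed=7)
        model = train_balanced_bagging(fm, fm.labels, BaggingConfig(n_trees=10, seed=7))
        permuted = fm.df[list(fm.df.columns)[::-1]]
        np.testing.assert_array_equal(
            predict_labels(model, fm.df), predict_labels(model, permuted)
        )

    def test_schema_mismatch_rejected(self):
        fm = separable_fm(1, per_class=15, seed=8)
        model = train_balanced_bagging(fm, fm.labels, BaggingConfig(n_trees=5, seed=8))
        bad = fm.df.rename(columns={"f0": "junk"})
        with pytest.raises(ValidationError):
            predict_scores(model, bad)


class TestLoso:
    def test_one_fold_per_subject_and_no_leakage(self):
        fm = separable_fm(5, per_class=10, seed=9)
        rep = loso_evaluate(fm, 3, BaggingConfig(n_trees=10, seed=9))
        assert len(rep.folds) == 5
        held = {f.held_out for f in rep.folds}
        assert held == set(fm.subjects)

    def test_separable_data_high_wake_auroc(self):
        fm = separable_fm(5, per_class=12, seed=10)
        rep = loso_evaluate(fm, 3, BaggingConfig(n_trees=20, seed=10))
        assert rep.auroc_mean["Wake"] >= 0.95

    def test_pooled_confusion_rows_normalized(self):
        fm = separable_fm(4, per_class=10, seed=11)
        rep = loso_evaluate(fm, 3, BaggingConfig(n_trees=10, seed=11))
        sums = rep.pooled_confusion.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums[np.isfinite(sums)], 1.0, atol=1e-9)

    def test_single_subject_directed_to_personal(self):
        fm = separable_fm(1, per_class=10)
        with pytest.raises(ValidationError, match="personal"):
            loso_evaluate(fm, 3)

    def test_auroc_invariant_under_monotone_score_transform(self):
        """AUROC depends only on the score ordering."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        a1 = roc_auc_score(y, s)
        a2 = roc_auc_score(y, np.exp(5 * s))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPersonal:
    def test_default_20_folds_partition_rows(self):
        fm = separable_fm(1, per_class=30, seed=13)
        rep = personal_evaluate(fm, 4, k=20, config=BaggingConfig(n_trees=10, seed=13))
        assert len(rep.folds) == 20
        total = sum(f.confusion.to_numpy().sum() for f in rep.folds)
        assert total == fm.n_clips

    def test_separable_subject_high_recall(self):
        fm = separable_fm(1, per_class=30, noise=0.05, seed=14)
        rep = personal_evaluate(fm, 4, k=10, config=BaggingConfig(n_trees=20, seed=14))
        for c in rep.classes:
            assert rep.recall_mean[c] >= 0.8

    def test_too_few_rows_rejected(self):
        fm = separable_fm(1, per_class=4)
        with pytest.raises(ValidationError):
            personal_evaluate(fm, 2, k=20)


class TestImbalance:
    def test_undersampling_shrinks_recall_gap(self):
        """9:1 pure-noise imbalance: under-sampling narrows the majority-vs-
        minority recall gap, paired over 10 seeds."""
        gaps_on, gaps_off = [], []
        for seed in range(10):
            fm = noise_fm(4, 80, imbalance=9, seed=100 + seed)
            rep_on = loso_evaluate(fm, 3, BaggingConfig(n_trees=15, undersample=True, seed=seed))
            rep_off = loso_evaluate(fm, 3, BaggingConfig(n_trees=15, undersample=False, seed=seed))
            gaps_on.append(abs(rep_on.recall_mean["NREM"] - rep_on.recall_mean["REM"]))
            gaps_off.append(abs(rep_off.recall_mean["NREM"] - rep_off.recall_mean["REM"]))
        assert np.mean(gaps_on) < np.mean(gaps_off)

    def test_without_undersampling_majority_wins_on_noise(self):
        fm = noise_fm(4, 80, imbalance=9, seed=200)
        rep = loso_evaluate(fm, 3, BaggingConfig(n_trees=15, undersample=False, seed=0))
        assert rep.recall_mean["NREM"] > rep.recall_mean["REM"]


class TestLearningCurve:
    def test_one_row_per_training_size(self):
        fm = separable_fm(5, per_class=8, seed=15)
        lc = learning_curve(fm, 3, repeats=3, config=BaggingConfig(n_trees=8, seed=15))
        assert list(lc["n_subjects"]) == [2, 3, 4]

    def test_flat_near_half_on_pure_noise(self):
        fm = noise_fm(5, 60, seed=16)
        lc = learning_curve(fm, 3, repeats=4, config=BaggingConfig(n_trees=10, seed=16))
        aurocs = lc[[c for c in lc.columns if c.startswith("auroc_") and "sd" not in c]]
        vals = aurocs.to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        assert np.abs(vals - 0.5).max() < 0.15


class TestActigraphyBaseline:
    def test_all_zero_counts_scored_sleep(self):
        labels = actigraphy_baseline(np.zeros(10))
        assert set(labels) == {"Sleep"}

    def test_weighted_spillover_hand_example(self):
        """[0,0,1000,0,0]: weighted scores are 40,200,1000,200,40, and the
        strict > rule leaves the s=40 edges asleep."""
        labels = actigraphy_baseline(np.array([0.0, 0.0, 1000.0, 0.0, 0.0]), threshold=40.0)
        assert list(labels) == ["Sleep", "Wake", "Wake", "Wake", "Sleep"]

    def test_isolated_moderate_count(self):
        labels = actigraphy_baseline(np.array([0.0, 50.0, 0.0]), threshold=40.0)
        assert list(labels) == ["Sleep", "Wake", "Sleep"]


class TestAblation:
    def test_ablation_rows_and_determinism(self):
        """One row per subset, deterministic under the same seed."""
        from somnostage.features import SensorSubset, process_recording
        from somnostage.staging_model import subset_ablation
        from somnostage.synthetic_data import SimConfig, generate_cohort

        cfg = SimConfig(duration=1.0, ecg_rate=250.0, seed=67)
        processed = [process_recording(r) for r in generate_cohort(cfg, 3)]
        subsets = {
            "accnd_ecg_handnd": SensorSubset(("wrist_nd",), True, "single:hand_nd"),
            "accnd": SensorSubset(("wrist_nd",), False, "none"),
            "accnd_dup": SensorSubset(("wrist_nd",), False, "none"),
        }
        tab = subset_ablation(processed, subsets, 2, BaggingConfig(n_trees=15, seed=3))
        assert list(tab["subset"]) == list(subsets)
        assert list(tab["n_features"]) == [51, 33, 33]
        # duplicate subset definitions produce identical metric rows
        a = tab.iloc[1].drop("subset")
        b = tab.iloc[2].drop("subset")
        assert (a == b).all()


class TestBaselineAsymmetry:
    def test_sleep_recall_exceeds_wake_recall_on_simulated_nights(self):
        """The count-threshold scorer detects sleep far better than quiet
        wake on the default simulator, mirroring wrist-device behaviour."""
        from somnostage.io_model import map_stage_resolution
        from somnostage.synthetic_data import SimConfig, generate_cohort

        cfg = SimConfig(duration=2.0, ecg_rate=250.0, seed=71)
        wake_r, sleep_r = [], []
        for rec in generate_cohort(cfg, 3):
            truth = np.array(
                [map_stage_resolution(s, 2) for s in rec.hypnogram.epoch_labels],
                dtype=object,
            )
            pred = actigraphy_baseline(rec.channel("actigraph", "counts"))
            n = min(len(pred), len(truth))
            wake_rows = truth[:n] == "Wake"
            sleep_rows = truth[:n] == "Sleep"
            wake_r.append(np.mean(pred[:n][wake_rows] == "Wake"))
            sleep_r.append(np.mean(pred[:n][sleep_rows] == "Sleep"))
        assert np.mean(sleep_r) > np.mean(wake_r)
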