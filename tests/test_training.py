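import numpy as np
import pandas as pd
import pytest

from translokit.training import (
    Stump,
    StumpEnsemble,
    TrainingConfig,
    TrainingError,
    cross_validate,
    f1_threshold_scan,
    fit_stump_ensemble,
    fit_xgboost,
    high_confidence_cutoff,
    select_features,
)


def _cohort_with_perfect_feature(n=60, n_noise=5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    data = {"signal": y.astype(float)}
    for j in range(n_noise):
        data[f"noise{j}"] = rng.integers(0, 2, size=n).astype(float)
    data["label"] = y
    return pd.DataFrame(data)


def _ensemble_from_importances(importances: dict[str, float]) -> StumpEnsemble:
    trees = [
        Stump(feature=f, threshold=0.5, left_leaf=-w / 2, right_leaf=w / 2)
        for f, w in importances.items()
    ]
    return StumpEnsemble(
        trees=trees,
        feature_names=list(importances),
        base_margin=0.0,
        learning_rate=0.3,
    )


class TestFitStumpEnsemble:
    def test_perfect_feature_dominates_importance(self):
        ensemble = fit_stump_ensemble(_cohort_with_perfect_feature())
        imp = ensemble.importances()
        assert imp.abs().idxmax() == "signal"
        assert imp["signal"] > 0

    def test_same_config_is_deterministic(self, cohort0):
        config = TrainingConfig(seed=3)
        one = fit_stump_ensemble(cohort0, config)
        two = fit_stump_ensemble(cohort0, config)
        assert one.trees == two.trees

    def test_all_trees_are_stumps_with_known_features(self, cohort0):
        ensemble = fit_stump_ensemble(cohort0, TrainingConfig(n_rounds=20))
        assert all(isinstance(t, Stump) for t in ensemble.trees)
        assert {t.feature for t in ensemble.trees} <= set(ensemble.feature_names)

    def test_single_class_cohort_rejected(self):
        cohort = pd.DataFrame({"f": [0.0, 1.0, 0.5], "label": [1, 1, 1]})
        with pytest.raises(TrainingError, match="both classes"):
            fit_stump_ensemble(cohort)

    def test_noise_cohort_with_shuffled_labels_yields_no_importance(self):
        """On pure-noise features no importance should clear the 0.02 cutoff."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.integers(0, 2, size=(300, 30)).astype(float),
                columns=[f"f{j}" for j in range(30)],
            )
            X["label"] = rng.permutation([1] * 150 + [0] * 150)
            ensemble = fit_stump_ensemble(X, TrainingConfig(seed=seed))
            hits += int((ensemble.importances().abs() <= 0.02).all())
        assert hits >= 19  # >= 95% of seeds

    def test_xgboost_adapter_parity_on_separable_data(self):
        cohort = _cohort_with_perfect_feature()
        model = fit_xgboost(cohort, TrainingConfig(n_rounds=20))
        proba = model.predict_proba(cohort.drop(columns="label"))[:, 1]
        reference = fit_stump_ensemble(cohort, TrainingConfig(n_rounds=20))
        ref_scores = reference.decision_function(cohort.drop(columns="label"))
        y = cohort["label"].to_numpy()
        assert (proba[y == 1].min() > proba[y == 0].max())
        assert (ref_scores[y == 1].min() > ref_scores[y == 0].max())


class TestSelectFeatures:
    def test_strict_cutoff_filter(self):
        ensemble = _ensemble_from_importances({"a": 0.5, "b": 0.01, "c": 0.03})
        assert select_features(ensemble) == {"a", "c"}

    def test_exactly_cutoff_excluded(self):
        ensemble = _ensemble_from_importances({"edge": 0.02})
        assert select_features(ensemble) == set()

    def test_negative_importance_selected_by_magnitude(self):
        ensemble = _ensemble_from_importances({"neg": -0.4, "tiny": -0.001})
        assert select_features(ensemble) == {"neg"}

    def test_empty_ensemble_selects_nothing(self):
        ensemble = _ensemble_from_importances({})
        assert select_features(ensemble) == set()

    def test_nonpositive_cutoff_rejected(self):
        ensemble = _ensemble_from_importances({"a": 0.5})
        with pytest.raises(TrainingError):
            select_features(ensemble, cutoff=0.0)


class TestCrossValidate:
    def test_separable_cohort_gives_perfect_auc(self):
        cohort = _cohort_with_perfect_feature()
        report = cross_validate(cohort, TrainingConfig(repeats=5), keep_curves=False)
        assert report.aucs == [1.0] * 5

    def test_report_contains_one_auc_per_repeat(self, cohort0):
        report = cross_validate(cohort0, TrainingConfig(repeats=3), keep_curves=True)
        assert len(report.aucs) == 3
        assert len(report.pr_curves) == 3
        assert len(report.mcc_curves) == 3
        assert all(0.0 <= a <= 1.0 for a in report.aucs)

    def test_per_fold_auc_mode(self):
        cohort = _cohort_with_perfect_feature()
        report = cross_validate(
            cohort,
            TrainingConfig(repeats=2, auc_mode="per_fold"),
            keep_curves=False,
        )
        assert report.aucs == [1.0, 1.0]

    def test_class_too_small_to_stratify_rejected(self):
        cohort = pd.DataFrame(
            {"f": np.arange(10.0), "label": [1] * 2 + [0] * 8}
        )
        with pytest.raises(TrainingError, match="stratify"):
            cross_validate(cohort, TrainingConfig(folds=5, repeats=1))


class TestF1ThresholdScan:
    def test_three_candidate_example(self):
        scan = f1_threshold_scan([0.9, 0.8, 0.1], [1, 1, 0])
        assert scan.threshold == 0.8
        assert scan.f1 == 1.0

    def test_separated_scores_reach_f1_one(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0]
        assert f1_threshold_scan(scores, labels).f1 == 1.0

    def test_curves_cover_all_candidates(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        scan = f1_threshold_scan(scores, labels)
        assert set(scan.curves.columns) == {
            "threshold",
            "recall",
            "precision",
            "fallout",
            "f1",
        }
        assert len(scan.curves) == len(np.unique(scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        base = f1_threshold_scan(scores, labels)
        warped = f1_threshold_scan(np.exp(scores), labels)
        assert warped.f1 == pytest.approx(base.f1)
        assert warped.threshold == pytest.approx(np.exp(base.threshold))

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            f1_threshold_scan([0.1, 0.2], [1, 1])


class TestHighConfidenceCutoff:
    def test_is_maximum_negative_score(self):
        assert high_confidence_cutoff([0.1, 0.3, 0.6167]) == 0.6167

    def test_single_negative(self):
        assert high_confidence_cutoff([0.2]) == 0.2

    def test_empty_rejected(self):
        with pytest.raises(TrainingError):
            high_confidence_cutoff([])
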