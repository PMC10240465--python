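"""kNN cross-validation, metrics arithmetic, and the GLM confound analysis."""

import numpy as np
import pandas as pd
import pytest

from edsleep.classify_confound import (
    CONFOUND_VARS,
    confound_analysis,
    cross_validate,
    evaluate,
    glm_logistic,
    grid_search,
    knn_fit_predict,
    pseudo_r2,
    stratified_kfold,
)
from edsleep.io_preprocess import ConfigurationError, DataError


def _labels(n_high, n_low):
    return pd.Series(
        ["high"] * n_high + ["low"] * n_low,
        index=[f"S{i:03d}" for i in range(n_high + n_low)],
    )


class TestStratifiedKFold:
    def test_31_41_partition(self):
        plan = stratified_kfold(_labels(31, 41), k=5, seed=0)
        labels = _labels(31, 41)
        for fold in range(5):
            te = plan.test_index(fold)
            counts = labels.loc[te].value_counts()
            # integer-partition oracle: 31 = 6*4 + 7, 41 = 8*4 + 9
            assert counts["high"] in (6, 7)
            assert counts["low"] in (8, 9)
        assert sorted(plan.fold_of.unique()) == [0, 1, 2, 3, 4]

    def test_balanced_10_10(self):
        plan = stratified_kfold(_labels(10, 10), k=5, seed=1)
        labels = _labels(10, 10)
        for fold in range(5):
            counts = labels.loc[plan.test_index(fold)].value_counts()
            assert counts["high"] == 2 and counts["low"] == 2

    def test_k_one_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_kfold(_labels(10, 10), k=1)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_kfold(_labels(3, 40), k=5)

    def test_deterministic_given_seed(self):
        a = stratified_kfold(_labels(31, 41), k=5, seed=7)
        b = stratified_kfold(_labels(31, 41), k=5, seed=7)
        assert (a.fold_of == b.fold_of).all()


# 5-point training fixture used by the brute-force kNN oracle test
KNN_TRAIN = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [3.0, 3.0], [4.0, 3.0]])
KNN_LABELS = np.array(["high", "high", "low", "low", "high"])
KNN_TEST = np.array([[0.5, 0.5], [3.5, 3.0], [2.0, 1.5]])


class TestKnn:
    def test_one_nn_on_coincident_point(self):
        scores, labels = knn_fit_predict(
            KNN_TRAIN, KNN_LABELS, KNN_TRAIN[:1], {"k_neighbors": 1}
        )
        assert labels[0] == "high" and scores[0] == 1.0

    def test_matches_exhaustive_neighbour_search(self):
        scores, labels = knn_fit_predict(
            KNN_TRAIN, KNN_LABELS, KNN_TEST,
            {"k_neighbors": 3, "metric": "euclidean", "weighting": "uniform"},
        )
        for x, s, lab in zip(KNN_TEST, scores, labels):
            d = np.linalg.norm(KNN_TRAIN - x, axis=1)
            nearest = np.argsort(d, kind="stable")[:3]
            frac = np.mean(KNN_LABELS[nearest] == "high")
            assert s == pytest.approx(frac)
            assert lab == ("high" if frac >= 0.5 else "low")

    def test_separable_clusters_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array(["high"] * 20 + ["low"] * 20)
        scores, labels = knn_fit_predict(X, y, X, {"k_neighbors": 5})
        assert (labels == y).all()

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ConfigurationError):
            knn_fit_predict(KNN_TRAIN, KNN_LABELS, KNN_TEST, {"k_neighbors": 9})


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["high", "low"] * 15)
        hp = grid_search(X, y, {"k_neighbors": (3,), "metric": ("euclidean",),
                                "weighting": ("uniform",)}, seed=0)
        assert hp["k_neighbors"] == 3 and hp["metric"] == "euclidean"

    def test_separable_data_reaches_inner_accuracy_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(8, 0.1, (15, 2))])
        y = np.array(["high"] * 15 + ["low"] * 15)
        hp = grid_search(X, y, seed=0)
        assert hp["inner_accuracy"] == 1.0

    def test_logged_score_reproducible_by_reevaluation(self, rng):
        from sklearn.model_selection import StratifiedKFold

        from edsleep.classify_confound import _fold_transform

        X = rng.standard_normal((24, 3))
        y = np.array(["high", "low"] * 12)
        hp = grid_search(X, y, seed=3)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=3)
        accs = []
        for tr, te in skf.split(X, y):
            transform = _fold_transform(X[tr])
            _, labels = knn_fit_predict(
                transform(X[tr]), y[tr], transform(X[te]), hp
            )
            accs.append(np.mean(labels == y[te]))
        assert np.mean(accs) == pytest.approx(hp["inner_accuracy"])


class TestEvaluate:
    def _report(self, tp, fn, tn, fp, rng):
        n = tp + fn + tn + fp
        idx = [f"S{i:03d}" for i in range(n)]
        truth = pd.Series(["high"] * (tp + fn) + ["low"] * (tn + fp), index=idx)
        predicted = pd.Series(
            ["high"] * tp + ["low"] * fn + ["low"] * tn + ["high"] * fp, index=idx
        )
        scores = pd.Series(
            np.where(predicted == "high", 0.8, 0.2) + rng.normal(0, 0.01, n),
            index=idx,
        )
        fold = pd.Series(np.arange(n) % 5, index=idx)
        return evaluate(truth, scores, predicted, fold)

    def test_confusion_arithmetic_near_reported_operating_point(self, rng):
        # constructed confusion matrix: TP=23 FN=8 TN=35 FP=6 over 72 subjects
        rep = self._report(23, 8, 35, 6, rng)
        assert rep.metrics["accuracy"] == pytest.approx(58 / 72)
        assert rep.metrics["recall"] == pytest.approx(23 / 31)
        assert rep.metrics["specificity"] == pytest.approx(35 / 41)
        assert rep.metrics["precision"] == pytest.approx(23 / 29)

    def test_all_correct_gives_ones(self, rng):
        rep = self._report(10, 0, 10, 0, rng)
        assert all(v == pytest.approx(1.0) for v in rep.metrics.values())

    def test_constant_scores_auc_half(self):
        idx = [f"S{i}" for i in range(10)]
        truth = pd.Series(["high"] * 4 + ["low"] * 6, index=idx)
        predicted = pd.Series(["high"] * 10, index=idx)
        scores = pd.Series(0.5, index=idx)
        rep = evaluate(truth, scores, predicted, pd.Series(0, index=idx))
        assert rep.metrics["auc_roc"] == pytest.approx(0.5)

    def test_missing_prediction_rejected(self):
        idx = ["a", "b", "c", "d"]
        truth = pd.Series(["high", "high", "low", "low"], index=idx)
        scores = pd.Series([0.9, np.nan, 0.1, 0.2], index=idx)
        predicted = pd.Series(["high", "high", "low", "low"], index=idx)
        with pytest.raises(DataError):
            evaluate(truth, scores, predicted, pd.Series(0, index=idx))


class TestCrossValidate:
    def test_out_of_fold_discipline(self, rng, monkeypatch):
        """No training call may contain the subjects it scores."""
        import edsleep.classify_confound as cc

        seen = []
        real = cc.knn_fit_predict

        def spy(X_train, y_train, X_test, hp):
            seen.append((len(X_train), len(X_test)))
            return real(X_train, y_train, X_test, hp)

        monkeypatch.setattr(cc, "knn_fit_predict", spy)
        X = pd.DataFrame(rng.standard_normal((20, 3)),
                         index=[f"S{i}" for i in range(20)])
        labels = pd.Series(["high", "low"] * 10, index=X.index)
        rep = cc.cross_validate(
            X, labels, k=5, seed=0,
            grid={"k_neighbors": (3,), "metric": ("euclidean",),
                  "weighting": ("uniform",)},
        )
        outer = [s for s in seen if s[0] == 16]
        assert len(outer) == 5  # one fit per fold on the 16-subject train split
        assert not rep.scores.isna().any()

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((24, 3)),
                         index=[f"S{i}" for i in range(24)])
        labels = pd.Series(["high", "low"] * 12, index=X.index)
        a = cross_validate(X, labels, seed=5)
        b = cross_validate(X, labels, seed=5)
        assert (a.scores == b.scores).all()
        assert a.metrics == b.metrics

    def test_missing_values_imputed_from_training_fold(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)),
                         index=[f"S{i}" for i in range(30)])
        X.iloc[::7, 1] = np.nan
        labels = pd.Series(["high", "low"] * 15, index=X.index)
        rep = cross_validate(X, labels, seed=1)
        assert not rep.scores.isna().any()


# 12-subject worked fixture (ML score, age, BMI, gender) with a finite,
# well-conditioned maximum-likelihood solution
GLM_Y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1], dtype=float)
GLM_X = np.array(
    [
        [0.64, 49.8, 39.4, 0.0],
        [0.32, 70.1, 37.6, 1.0],
        [0.62, 61.4, 40.3, 1.0],
        [0.72, 48.0, 49.9, 0.0],
        [0.28, 44.9, 20.5, 1.0],
        [0.57, 55.3, 32.3, 1.0],
        [0.26, 42.8, 41.7, 1.0],
        [0.64, 48.3, 24.3, 1.0],
        [0.25, 58.1, 48.8, 1.0],
        [0.76, 66.6, 39.9, 0.0],
        [0.28, 61.1, 43.8, 1.0],
        [0.78, 32.1, 32.4, 0.0],
    ]
)


class TestGlm:
    def test_deviance_matches_statsmodels(self):
        import statsmodels.api as sm

        fit = glm_logistic(GLM_X, GLM_Y, ridge=1e-6)
        ref = sm.GLM(GLM_Y, sm.add_constant(GLM_X), family=sm.families.Binomial()).fit()
        assert fit["deviance"] == pytest.approx(ref.deviance, abs=1e-8)
        np.testing.assert_allclose(fit["beta"], ref.params, rtol=1e-3, atol=1e-4)

    def test_null_model_pseudo_r2_zero(self):
        null = glm_logistic(np.empty((12, 0)), GLM_Y)
        assert pseudo_r2(null["deviance"], null["deviance"]) == 0.0

    def test_separated_fold_flagged_not_crashed(self):
        X = np.linspace(-1, 1, 10)[:, None]
        y = (X[:, 0] > 0).astype(float)
        fit = glm_logistic(X, y)
        assert fit["ridge_escalated"]
        assert np.isfinite(fit["deviance"])


def _cv_report_for_confounds(rng, n=40, informative=True):
    idx = [f"S{i:03d}" for i in range(n)]
    truth = pd.Series(["high", "low"] * (n // 2), index=idx)
    base = np.where(truth == "high", 0.7, 0.3) if informative else 0.5
    scores = pd.Series(np.clip(base + rng.normal(0, 0.15, n), 0, 1), index=idx)
    predicted = pd.Series(np.where(scores >= 0.5, "high", "low"), index=idx)
    fold = pd.Series(np.arange(n) % 5, index=idx)
    report = evaluate(truth, scores, predicted, fold)
    covariates = pd.DataFrame(
        {
            "age": rng.normal(55, 12, n),
            "bmi": rng.normal(37, 8, n),
            "gender": rng.integers(0, 2, n).astype(float),
        },
        index=idx,
    )
    return report, covariates


class TestConfoundAnalysis:
    def test_nested_model_dominates_in_every_fold(self, rng):
        report, cov = _cv_report_for_confounds(rng)
        res = confound_analysis(report, cov)
        for fold in res.per_fold:
            both = fold["ml_plus_confounds"]["deviance"]
            assert both <= fold["ml_only"]["deviance"] + 1e-6
            assert both <= fold["confounds_only"]["deviance"] + 1e-6
            assert fold["ml_plus_confounds"]["pseudo_r2"] >= max(
                fold["ml_only"]["pseudo_r2"], fold["confounds_only"]["pseudo_r2"]
            ) - 1e-9

    def test_informative_scores_beat_uninformative_confounds(self, rng):
        report, cov = _cv_report_for_confounds(rng)
        res = confound_analysis(report, cov)
        assert res.pseudo_r2["ml_only"] > res.pseudo_r2["confounds_only"]
        assert set(res.p_values["confounds_only"]) == set(CONFOUND_VARS)

    def test_single_class_fold_excluded(self, rng):
        report, cov = _cv_report_for_confounds(rng, n=40)
        # make fold 0 single-class
        fold0 = report.fold_of[report.fold_of == 0].index
        report.truth.loc[fold0] = "high"
        res = confound_analysis(report, cov)
        assert res.excluded_folds == [0]
        assert len(res.per_fold) == 4

    def test_leakage_increases_confound_fit(self):
        from dataclasses import replace as dc_replace

        from edsleep.synth_cohort import CovariateParams, GeneratorConfig, sample_covariates

        r2 = []
        for lam in (0.0, 0.5, 1.0):
            cfg = GeneratorConfig(
                n_high=60, n_low=60, seed=17,
                covariate_params=CovariateParams(leakage=lam),
            )
            recs = sample_covariates(cfg)
            X = np.array(
                [[r.age, r.bmi, 1.0 if r.sex == "female" else 0.0] for r in recs]
            )
            y = np.array([1.0 if r.group == "high" else 0.0 for r in recs])
            fit = glm_logistic(X, y)
            null = glm_logistic(np.empty((len(y), 0)), y)
            r2.append(pseudo_r2(fit["deviance"], null["deviance"]))
        assert r2[0] < r2[1] < r2[2]
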