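"""Linear discriminant, LOOCV, ROC/AUC, DA suite and the two-step model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from cfpanel import (
    DiscriminantAnalysis,
    TwoStepClassifier,
    loocv_evaluate,
    roc_auc,
    run_da_suite,
    standard_feature_sets,
)
from cfpanel.discriminant import DegenerateModelError, da_table


def _toy(seed=0, n=24, p=3, delta=2.5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, p)), rng.normal(delta, 1, (n // 2, p))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


class TestFitLda:
    def test_1d_boundary_at_midpoint(self):
        # two tight 1-D classes around 0 and 4: threshold ~ 2
        rng = np.random.default_rng(3)
        x0 = rng.normal(0, 1, 500)[:, None]
        x1 = rng.normal(4, 1, 500)[:, None]
        res = DiscriminantAnalysis(np.vstack([x0, x1]),
                                   np.r_[np.zeros(500, int), np.ones(500, int)]).fit()
        boundary = -res.const / res.weights[0]
        assert boundary == pytest.approx(2.0, abs=0.15)

    def test_separable_toy_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0], [5.1, 4.9]])
        y = np.array([0, 0, 1, 1])
        res = DiscriminantAnalysis(X, y).fit()
        assert (res.predict(X) == y).all()

    def test_duplicated_feature_column_same_predictions(self):
        X, y = _toy(seed=1)
        Xdup = np.hstack([X, X[:, [0]]])
        p1 = DiscriminantAnalysis(X, y).fit().predict(X)
        p2 = DiscriminantAnalysis(Xdup, y).fit().predict(Xdup)
        assert (p1 == p2).all()

    def test_affine_rescaling_invariance(self):
        X, y = _toy(seed=2)
        Xs = X.copy()
        Xs[:, 0] = 100.0 * Xs[:, 0] - 7.0
        p1 = DiscriminantAnalysis(X, y).fit().predict(X)
        p2 = DiscriminantAnalysis(Xs, y).fit().predict(Xs)
        assert (p1 == p2).all()

    def test_matches_sklearn_on_nonsingular_data(self):
        X, y = _toy(seed=4, n=40, p=4, delta=1.0)
        ours = DiscriminantAnalysis(X, y).fit().predict(X)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
        assert (ours == sk).all()

    def test_all_constant_features_degenerate(self):
        X = np.ones((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(DegenerateModelError):
            DiscriminantAnalysis(X, y).fit()

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            DiscriminantAnalysis(np.ones((4, 1)), np.zeros(4, int))


class TestLoocv:
    def test_separable_data_perfect(self):
        X, y = _toy(seed=5, delta=8.0)
        res = loocv_evaluate(X, y)
        assert res.accuracy == 100.0 and res.auc == 1.0

    def test_metric_identities(self):
        X, y = _toy(seed=6, delta=0.8)
        r = loocv_evaluate(X, y)
        total = r.tp + r.fp + r.tn + r.fn
        assert total == len(y)
        assert r.accuracy == pytest.approx(100.0 * (r.tp + r.tn) / total)
        assert r.sensitivity == pytest.approx(100.0 * r.tp / (r.tp + r.fn))
        assert r.specificity == pytest.approx(100.0 * r.tn / (r.tn + r.fp))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_per_fold_sklearn_refit(self, seed):
        # independent oracle: sklearn LDA refit from scratch on every fold
        X, y = _toy(seed=seed, n=24, p=2, delta=1.2)
        ours = loocv_evaluate(X, y)
        oracle = np.empty(len(y), dtype=int)
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X[mask], y[mask])
            oracle[i] = clf.predict(X[i : i + 1])[0]
        assert (ours.predictions == oracle).all()

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(11)
        accs = []
        for seed in range(5):
            X = rng.normal(size=(200, 5))
            y = rng.permutation(np.r_[np.zeros(100, int), np.ones(100, int)])
            accs.append(loocv_evaluate(X, y).accuracy)
        assert 40.0 < np.mean(accs) < 60.0

    def test_depleted_fold_predicts_majority(self):
        # one lone negative: its fold loses class 0 entirely
        X = np.r_[np.zeros((1, 1)), np.ones((9, 1)) + np.arange(9)[:, None] * 0.1]
        y = np.r_[0, np.ones(9, int)]
        res = loocv_evaluate(X, y)
        assert res.predictions[0] == 1
        assert any("depleted" in w for w in res.fold_warnings)


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.9, 1.1], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_mann_whitney_construction(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60) + np.r_[np.zeros(30), np.full(30, 0.5)]
        scores = np.round(scores, 1)  # force ties
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert roc_auc(scores, labels) == pytest.approx(u / (30 * 30), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDaSuite:
    def test_five_sets_reported_with_counts(self, cohort, preprocessed):
        dataset, _ = cohort
        fm = preprocessed["feature_matrix"]
        labels = (dataset.samples.set_index("sample_id")["group"]
                  .reindex(fm.values.index) != "healthy").astype(int)
        sets = standard_feature_sets(fm, ["MLH1", "miR-17-5p"], "COSM238555")
        assert all("COSM238555" not in feats for feats in sets.values())
        results, skipped = run_da_suite(fm.values, labels, sets)
        assert [r.label for r in results] == ["DA1", "DA2", "DA3", "DA4", "DA5"]
        for r in results:
            assert r.n_features == len(sets[r.label])
        table = da_table(results)
        assert list(table["n_biomarkers"]) == [len(sets[k]) for k in sets]

    def test_empty_set_skipped_with_log(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = [0, 0, 0, 1, 1, 1]
        results, skipped = run_da_suite(X, y, {"DA1": ["a"], "DA9": ["missing"]})
        assert len(results) == 1 and "DA9" in skipped[0]


class TestTwoStep:
    @staticmethod
    def _fm(n=30, seed=0, ar_rate=0.4):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 3, int), np.ones(n - n // 3, int)]
        ar = np.where(y == 1, rng.random(n) < ar_rate, 0).astype(float)
        cont = rng.normal(0, 1, n) + 1.5 * y
        fm = pd.DataFrame({"AR": ar, "f": cont},
                          index=[f"S{i}" for i in range(n)])
        return fm, y

    def test_ar_positive_always_predicted_tumor(self):
        fm, y = self._fm()
        fm.iloc[0, fm.columns.get_loc("AR")] = 1.0  # healthy-like profile, AR+
        res = TwoStepClassifier(fm, y, "AR", ["f"]).fit()
        assert res.predictions[0] == 1

    def test_no_ar_positives_reduces_to_downstream(self):
        fm, y = self._fm()
        fm["AR"] = 0.0
        two = TwoStepClassifier(fm, y, "AR", ["f"]).fit()
        solo = loocv_evaluate(fm[["f"]], y)
        assert (two.predictions == solo.predictions).all()

    def test_split_only_adds_positive_predictions(self, cohort, preprocessed):
        dataset, _ = cohort
        fm = preprocessed["feature_matrix"]
        labels = (dataset.samples.set_index("sample_id")["group"]
                  .reindex(fm.values.index) != "healthy").astype(int).to_numpy()
        res = TwoStepClassifier(fm, labels, "COSM238555", ["MLH1", "miR-17-5p"]).fit()
        assert res.sensitivity >= res.downstream.sensitivity

    def test_missing_split_feature_raises(self):
        fm, y = self._fm()
        with pytest.raises(KeyError):
            TwoStepClassifier(fm, y, "nope", ["f"])
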