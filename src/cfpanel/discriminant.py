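"""Linear discriminant classification with leave-one-out cross-validation.

The core model is a two-class Fisher linear discriminant built from class
means and the pooled within-class covariance.  The pooled covariance is
inverted by Moore-Penrose pseudo-inverse, so feature sets larger than the
sample count (or with duplicated columns) are handled deterministically.
Class priors default to equal; a proportional mode is available.

Model/Results layout:

* ``DiscriminantAnalysis(X, y).fit()`` -> ``DiscriminantResults`` with the
  weight vector, threshold, per-class classification functions, prediction
  and scoring methods, and a ``summary()`` table.
* ``loocv_evaluate`` refits the model on each leave-one-out fold and collects
  the held-out predictions into a ``DAResult`` (confusion counts, accuracy /
  sensitivity / specificity in percent with tumor as the positive class, and
  ROC AUC from the held-out signed discriminant scores).
* ``TwoStepClassifier`` first routes every sample positive for a designated
  binary split feature (the AR mutation call) straight to the tumor class,
  then classifies the split-negative remainder with a LOOCV discriminant on a
  downstream feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

POSITIVE = 1  # tumor
NEGATIVE = 0  # healthy


class DegenerateModelError(ValueError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


class DiscriminantAnalysis:
    """Two-class linear discriminant model.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Feature values; binary features coded 0/1.
    y : (n,) array-like
        Class labels coded 0 (healthy / negative) and 1 (tumor / positive).
    priors : {"equal", "proportional"} or (pi0, pi1)
        Class prior probabilities used in the classification functions.
    """

    def __init__(self, X, y, priors: str | tuple[float, float] = "equal"):
        self.X, self.feature_names = _as_matrix(X)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have different lengths")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")
        if np.bincount(self.y).min() < 2:
            raise ValueError("each class needs at least 2 samples")
        if priors == "equal":
            self.priors = np.array([0.5, 0.5])
        elif priors == "proportional":
            self.priors = np.bincount(self.y) / len(self.y)
        else:
            self.priors = np.asarray(priors, dtype=float)
            if self.priors.shape != (2,) or not np.isclose(self.priors.sum(), 1.0):
                raise ValueError("priors must be two probabilities summing to 1")

    def fit(self) -> "DiscriminantResults":
        X, y = self.X, self.y
        if np.all(np.ptp(X, axis=0) == 0):
            raise DegenerateModelError("all features are constant")
        mu0 = X[y == 0].mean(axis=0)
        mu1 = X[y == 1].mean(axis=0)
        n0, n1 = (y == 0).sum(), (y == 1).sum()
        S0 = np.cov(X[y == 0], rowvar=False, ddof=1)
        S1 = np.cov(X[y == 1], rowvar=False, ddof=1)
        pooled = ((n0 - 1) * np.atleast_2d(S0) + (n1 - 1) * np.atleast_2d(S1)) / (n0 + n1 - 2)
        # pseudo-inverse with a tiny relative ridge: keeps directions with
        # zero within-class variance but separated means (e.g. a perfectly
        # separating binary feature) instead of annihilating them
        p = pooled.shape[0]
        scale = float(np.trace(pooled)) / p
        if scale <= 0.0:
            scale = 1.0
        prec = np.linalg.pinv(pooled + 1e-8 * scale * np.eye(p))
        # signed discriminant: score(x) = g1(x) - g0(x) with
        # gk(x) = x' P mu_k - mu_k' P mu_k / 2 + log pi_k
        w = prec @ (mu1 - mu0)
        const = (
            -0.5 * (mu1 @ prec @ mu1 - mu0 @ prec @ mu0)
            + np.log(self.priors[1])
            - np.log(self.priors[0])
        )
        return DiscriminantResults(model=self, weights=w, const=float(const),
                                   class_means=np.vstack([mu0, mu1]), pooled_cov=pooled)


@dataclass
class DiscriminantResults:
    """Fitted discriminant function; predicts tumor when the score is >= 0."""

    model: DiscriminantAnalysis
    weights: np.ndarray
    const: float
    class_means: np.ndarray
    pooled_cov: np.ndarray

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.weights, index=self.model.feature_names, name="weight")
        s.loc["const"] = self.const
        return s

    def decision_scores(self, X) -> np.ndarray:
        arr, _ = _as_matrix(X) if not isinstance(X, np.ndarray) else (np.asarray(X, float), None)
        return arr @ self.weights + self.const

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0).astype(int)

    def summary(self) -> str:
        lines = ["Linear discriminant (tumor vs healthy)", "=" * 42]
        lines.append(f"n obs: {len(self.model.y)}   features: {len(self.weights)}")
        lines.append(f"priors (healthy, tumor): {tuple(np.round(self.model.priors, 3))}")
        lines.append("-" * 42)
        for name, w in zip(self.model.feature_names, self.weights):
            lines.append(f"{name:>24s}  {w:+.4f}")
        lines.append(f"{'const':>24s}  {self.const:+.4f}")
        return "\n".join(lines)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals the Mann-Whitney probability of
    correct ranking (ties counted half)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    """Threshold / TPR / FPR table for ROC plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})


@dataclass
class DAResult:
    """One discriminant-model evaluation on leave-one-out predictions."""

    label: str
    features: list[str]
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    scores: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    sample_ids: list[str] = field(default_factory=list, repr=False)
    fold_warnings: list[str] = field(default_factory=list, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / max(self.tp + self.fp + self.tn + self.fn, 1)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / max(self.tp + self.fn, 1)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / max(self.tn + self.fp, 1)

    def as_row(self) -> dict:
        return {
            "model": self.label,
            "accuracy_pct": round(self.accuracy, 1),
            "sensitivity_pct": round(self.sensitivity, 1),
            "specificity_pct": round(self.specificity, 1),
            "roc_auc": round(self.auc, 3),
            "n_biomarkers": self.n_features,
        }

    def summary(self) -> str:
        return (
            f"{self.label}: acc {self.accuracy:.1f}%  sens {self.sensitivity:.1f}%  "
            f"spec {self.specificity:.1f}%  AUC {self.auc:.3f}  "
            f"(TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}, "
            f"{self.n_features} biomarkers)"
        )

    def plot_roc(self, ax=None):
        """Plot the ROC curve of the held-out scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = roc_points(self.scores, self.labels)
        ax.plot(pts["fpr"], pts["tpr"], label=f"{self.label} (AUC {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def loocv_evaluate(
    X, y, *, priors: str | tuple[float, float] = "equal", label: str = "DA",
    sample_ids: list[str] | None = None,
) -> DAResult:
    """Leave-one-out evaluation: refit on n-1 samples, predict the held-out one.

    A fold whose training set loses an entire class predicts the larger
    remaining class (logged).  Held-out signed discriminant scores feed the
    ROC; tumor (1) is the positive class.
    """
    Xarr, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    warnings: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        counts = np.bincount(ytr, minlength=2)
        if counts.min() < 2:
            majority = int(np.argmax(counts))
            preds[i] = majority
            scores[i] = 1e12 if majority == 1 else -1e12  # extreme finite score
            warnings.append(f"fold {i}: class {int(np.argmin(counts))} depleted; predicted majority")
            continue
        res = DiscriminantAnalysis(Xarr[mask], ytr, priors=priors).fit()
        scores[i] = res.decision_scores(Xarr[i : i + 1])[0]
        preds[i] = int(scores[i] >= 0)
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    return DAResult(
        label=label, features=names, tp=tp, fp=fp, tn=tn, fn=fn,
        auc=roc_auc(scores, y), scores=scores, predictions=preds, labels=y,
        sample_ids=sample_ids or [], fold_warnings=warnings,
    )


def standard_feature_sets(feature_matrix, selected: list[str], ar_feature: str) -> dict[str, list[str]]:
    """The five canonical biomarker sets, all excluding the split feature.

    DA1 all features, DA2 mutations only, DA3 methylation only, DA4 miRNAs
    only, DA5 the selected biomarkers.
    """
    from .preprocess import METHYLATION, MIRNA, MUTATION

    drop = {ar_feature}
    return {
        "DA1": [f for f in feature_matrix.feature_ids if f not in drop],
        "DA2": [f for f in feature_matrix.features_of_class(MUTATION) if f not in drop],
        "DA3": [f for f in feature_matrix.features_of_class(METHYLATION) if f not in drop],
        "DA4": [f for f in feature_matrix.features_of_class(MIRNA) if f not in drop],
        "DA5": [f for f in selected if f not in drop],
    }


def run_da_suite(
    feature_matrix, labels, feature_sets: dict[str, list[str]],
    *, priors: str | tuple[float, float] = "equal",
) -> tuple[list[DAResult], list[str]]:
    """Evaluate one LOOCV discriminant per named feature set.

    Sets whose features are all unavailable in the matrix are skipped with a
    log entry.  Returns (results, skip log).
    """
    values = feature_matrix if isinstance(feature_matrix, pd.DataFrame) else feature_matrix.values
    y = np.asarray(labels, dtype=int)
    results: list[DAResult] = []
    skipped: list[str] = []
    for name, feats in feature_sets.items():
        avail = [f for f in feats if f in values.columns]
        if not avail:
            skipped.append(f"{name}: no available features")
            continue
        if len(avail) < len(feats):
            skipped.append(f"{name}: {len(feats) - len(avail)} feature(s) unavailable, using {len(avail)}")
        results.append(
            loocv_evaluate(values[avail], y, priors=priors, label=name,
                           sample_ids=list(values.index))
        )
    return results, skipped


def da_table(results: list[DAResult]) -> pd.DataFrame:
    """Stack DAResults into the canonical report layout."""
    return pd.DataFrame([r.as_row() for r in results])


class TwoStepClassifier:
    """Split-then-discriminate model.

    Samples positive for ``split_feature`` (an AR mutation call) are predicted
    tumor outright; split-negative samples are classified by a LOOCV linear
    discriminant on ``downstream_features``.
    """

    def __init__(self, feature_matrix, labels, split_feature: str,
                 downstream_features: list[str],
                 priors: str | tuple[float, float] = "equal"):
        values = feature_matrix if isinstance(feature_matrix, pd.DataFrame) else feature_matrix.values
        if split_feature not in values.columns:
            raise KeyError(f"split feature '{split_feature}' not in the feature matrix")
        self.values = values
        self.labels = np.asarray(labels, dtype=int)
        self.split_feature = split_feature
        self.downstream_features = [f for f in downstream_features if f != split_feature]
        self.priors = priors

    def fit(self) -> "TwoStepResults":
        split_pos = self.values[self.split_feature].to_numpy() == 1
        y = self.labels
        preds = np.empty(len(y), dtype=int)
        preds[split_pos] = POSITIVE
        downstream = None
        if (~split_pos).any():
            sub = self.values.loc[~split_pos, self.downstream_features]
            ysub = y[~split_pos]
            if len(set(ysub)) == 2:
                downstream = loocv_evaluate(
                    sub, ysub, priors=self.priors, label="downstream",
                    sample_ids=list(sub.index),
                )
                preds[~split_pos] = downstream.predictions
            else:
                preds[~split_pos] = int(ysub[0]) if len(ysub) else NEGATIVE
        return TwoStepResults(model=self, predictions=preds, split_positive=split_pos,
                              downstream=downstream)


@dataclass
class TwoStepResults:
    """Combined predictions of the split step plus the downstream discriminant."""

    model: TwoStepClassifier
    predictions: np.ndarray
    split_positive: np.ndarray
    downstream: DAResult | None

    def confusion(self) -> dict[str, int]:
        y, p = self.model.labels, self.predictions
        return {
            "tp": int(((p == 1) & (y == 1)).sum()),
            "fp": int(((p == 1) & (y == 0)).sum()),
            "tn": int(((p == 0) & (y == 0)).sum()),
            "fn": int(((p == 0) & (y == 1)).sum()),
        }

    @property
    def accuracy(self) -> float:
        c = self.confusion()
        return 100.0 * (c["tp"] + c["tn"]) / len(self.predictions)

    @property
    def sensitivity(self) -> float:
        c = self.confusion()
        return 100.0 * c["tp"] / max(c["tp"] + c["fn"], 1)

    @property
    def specificity(self) -> float:
        c = self.confusion()
        return 100.0 * c["tn"] / max(c["tn"] + c["fp"], 1)

    def summary(self) -> str:
        c = self.confusion()
        lines = [
            "Two-step classifier (split + linear discriminant)",
            "=" * 50,
            f"split feature: {self.model.split_feature}  "
            f"(split-positive n={int(self.split_positive.sum())}, all predicted tumor)",
            f"downstream features: {len(self.model.downstream_features)}",
            f"combined: acc {self.accuracy:.1f}%  sens {self.sensitivity:.1f}%  "
            f"spec {self.specificity:.1f}%  "
            f"(TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']})",
        ]
        if self.downstream is not None:
            lines.append("downstream " + self.downstream.summary())
        return "\n".join(lines)
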