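"""Candidate-biomarker identification.

For each cancer type (contrasted against the healthy controls):

1. continuous features (methylation %, miRNA z-scores) are dichotomized at
   the midpoint threshold maximizing |phi| against the class indicator;
2. every (now binary) feature is correlated with the type-vs-healthy
   indicator (phi coefficient) and features are ranked by |r|, keeping the
   top k (default 4);
3. every non-empty subset of the top k is scored by leave-one-out
   discriminant classification with the cost S = 2*FN + FP (false negatives
   doubly discouraged; tumor is the positive class), and the minimum-S subset
   wins (ties: smaller subset, then lexicographic feature order);
4. features carrying redundant information are eliminated: while any pair in
   the winning subset correlates above a ceiling (default |r| > 0.9), the
   member with the weaker outcome correlation is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import ANALYSIS_GROUPS
from .discriminant import loocv_evaluate
from .preprocess import FeatureMatrix


class DegenerateFeatureError(ValueError):
    pass


class CombinatorialGuardError(ValueError):
    pass


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two (possibly binary) vectors; NaN if constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class DichotomizedFeature:
    feature_id: str
    threshold: float
    binary: pd.Series = field(repr=False)
    phi: float


def dichotomize(values: pd.Series, class_labels, feature_id: str = "") -> DichotomizedFeature:
    """Binarize a continuous feature at the |phi|-maximizing midpoint threshold.

    Candidate thresholds are the midpoints between consecutive sorted distinct
    values; binary value is 1 iff value > threshold.  Ties in |phi| break
    toward the smallest threshold.
    """
    v = values.to_numpy(dtype=float)
    y = np.asarray(class_labels, dtype=float)
    distinct = np.unique(v)
    if distinct.size < 2:
        raise DegenerateFeatureError(f"feature '{feature_id or values.name}' is constant")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_phi = None, -1.0
    for t in candidates:
        b = (v > t).astype(float)
        phi = _phi(b, y)
        if np.isnan(phi):
            continue
        if abs(phi) > best_phi + 1e-12:
            best_t, best_phi = t, abs(phi)
    if best_t is None:  # labels constant: fall back to the first midpoint
        best_t, best_phi = candidates[0], 0.0
    b = pd.Series((v > best_t).astype(int), index=values.index, name=values.name)
    return DichotomizedFeature(
        feature_id=feature_id or str(values.name), threshold=float(best_t),
        binary=b, phi=float(best_phi),
    )


def dichotomize_matrix(
    fm: FeatureMatrix, class_labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dichotomize every continuous column of a feature matrix.

    Binary (mutation) columns pass through unchanged.  Returns the binary
    matrix and a per-feature table of thresholds.
    """
    from .preprocess import MUTATION

    cols = {}
    rows = []
    for fid in fm.feature_ids:
        col = fm.values[fid]
        if fm.classes[fid] == MUTATION:
            cols[fid] = col.astype(int)
            rows.append((fid, np.nan))
        else:
            d = dichotomize(col, class_labels, feature_id=fid)
            cols[fid] = d.binary
            rows.append((fid, d.threshold))
    binary = pd.DataFrame(cols, index=fm.values.index)
    thresholds = pd.DataFrame(rows, columns=["feature_id", "threshold"])
    return binary, thresholds


@dataclass(frozen=True)
class BiomarkerRanking:
    cancer_type: str
    ranking: tuple[tuple[str, float], ...]  # (feature_id, r) sorted by |r| desc

    def top(self, k: int) -> list[str]:
        return [f for f, _ in self.ranking[:k]]


def rank_biomarkers(
    binary_features: pd.DataFrame, indicator, cancer_type: str, *, k: int | None = None
) -> BiomarkerRanking:
    """Rank binary features by |phi| against the type-vs-healthy indicator.

    Constant features are excluded.  Ties in |r| break lexicographically on
    feature id for determinism.
    """
    y = np.asarray(indicator, dtype=float)
    if y.sum() == 0:
        raise ValueError(f"no samples for cancer type '{cancer_type}'")
    pairs = []
    for fid in binary_features.columns:
        r = _phi(binary_features[fid].to_numpy(dtype=float), y)
        if not np.isnan(r):
            pairs.append((fid, r))
    pairs.sort(key=lambda p: (-abs(p[1]), p[0]))
    if k is not None:
        pairs = pairs[:k]
    return BiomarkerRanking(cancer_type=cancer_type, ranking=tuple(pairs))


@dataclass(frozen=True)
class SubsetScore:
    features: tuple[str, ...]
    fn: int
    fp: int

    @property
    def score(self) -> int:
        """S = 2*FN + FP (false negatives doubly discouraged)."""
        return 2 * self.fn + self.fp


def score_subset(
    binary_features: pd.DataFrame, indicator, feature_subset,
    *, mode: str = "loocv",
) -> SubsetScore:
    """Score a feature subset by discriminant classification of type vs healthy.

    ``mode='loocv'`` (default) takes FN/FP from leave-one-out predictions;
    ``mode='resubstitution'`` from refitting and predicting the training set.
    """
    subset = tuple(feature_subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    X = binary_features[list(subset)]
    y = np.asarray(indicator, dtype=int)
    if mode == "loocv":
        res = loocv_evaluate(X, y)
        return SubsetScore(features=subset, fn=res.fn, fp=res.fp)
    if mode == "resubstitution":
        from .discriminant import DiscriminantAnalysis

        fit = DiscriminantAnalysis(X, y).fit()
        preds = fit.predict(X)
        fn = int(((preds == 0) & (y == 1)).sum())
        fp = int(((preds == 1) & (y == 0)).sum())
        return SubsetScore(features=subset, fn=fn, fp=fp)
    raise ValueError(f"unknown scoring mode '{mode}'")


def search_best_subsets(
    binary_features: pd.DataFrame, indicator, candidates: list[str],
    *, max_subset_size: int | None = None, mode: str = "loocv",
) -> tuple[SubsetScore, list[SubsetScore]]:
    """Exhaustively score every non-empty subset of the candidates.

    Returns (best, all scores).  The minimum-S subset wins; ties break toward
    the smaller subset, then lexicographic feature order.  Guarded against
    combinatorial blow-up at k > 20.
    """
    if len(candidates) > 20:
        raise CombinatorialGuardError(f"refusing exhaustive search over {len(candidates)} candidates")
    max_size = max_subset_size or len(candidates)
    scored: list[SubsetScore] = []
    for size in range(1, max_size + 1):
        for combo in combinations(sorted(candidates), size):
            scored.append(score_subset(binary_features, indicator, combo, mode=mode))
    best = min(scored, key=lambda s: (s.score, len(s.features), s.features))
    return best, scored


def eliminate_redundant(
    subset, binary_features: pd.DataFrame, indicator,
    *, correlation_ceiling: float = 0.9,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop redundant subset members until no pair correlates above the ceiling.

    At each step the most-correlated offending pair is considered and the
    member with the weaker |phi| against the outcome is dropped (ties:
    lexicographically later id).  Returns (reduced subset, drop log of
    (dropped, kept_partner) pairs).
    """
    if not 0 < correlation_ceiling <= 1:
        raise ValueError("correlation ceiling must be in (0, 1]")
    y = np.asarray(indicator, dtype=float)
    keep = sorted(subset)
    log: list[tuple[str, str]] = []
    while len(keep) > 1:
        worst = None  # (|corr|, a, b)
        for a, b in combinations(keep, 2):
            r = _phi(binary_features[a].to_numpy(float), binary_features[b].to_numpy(float))
            if np.isnan(r) or abs(r) <= correlation_ceiling:
                continue
            if worst is None or abs(r) > worst[0]:
                worst = (abs(r), a, b)
        if worst is None:
            break
        _, a, b = worst
        ra = abs(_phi(binary_features[a].to_numpy(float), y))
        rb = abs(_phi(binary_features[b].to_numpy(float), y))
        ra = 0.0 if np.isnan(ra) else ra
        rb = 0.0 if np.isnan(rb) else rb
        drop, kept = (b, a) if (ra > rb or (ra == rb)) else (a, b)
        keep.remove(drop)
        log.append((drop, kept))
    return keep, log


@dataclass
class TypeSelection:
    """Selection outcome for one cancer type."""

    cancer_type: str
    ranking: BiomarkerRanking
    best: SubsetScore
    all_scores: list[SubsetScore]
    selected: list[str]
    redundancy_log: list[tuple[str, str]]


def select_biomarkers(
    fm: FeatureMatrix, samples: pd.DataFrame,
    *, k: int = 4, correlation_ceiling: float = 0.9, mode: str = "loocv",
    cancer_types: list[str] | None = None,
) -> dict[str, TypeSelection]:
    """Run the full per-type selection against the healthy controls."""
    groups = samples.set_index("sample_id")["group"].reindex(fm.values.index)
    types = cancer_types or [g for g in ANALYSIS_GROUPS if g != "healthy"]
    out: dict[str, TypeSelection] = {}
    for ctype in types:
        contrast = groups.isin([ctype, "healthy"])
        sub = fm.values.loc[contrast.to_numpy()]
        sub_fm = FeatureMatrix(values=sub, classes=fm.classes)
        indicator = (groups[contrast] == ctype).astype(int).to_numpy()
        if indicator.sum() == 0:
            raise ValueError(f"no samples for cancer type '{ctype}'")
        binary, _ = dichotomize_matrix(sub_fm, indicator)
        binary = binary.loc[:, binary.nunique() > 1]
        ranking = rank_biomarkers(binary, indicator, ctype)
        candidates = ranking.top(k)
        best, scored = search_best_subsets(binary, indicator, candidates, mode=mode)
        selected, rlog = eliminate_redundant(
            best.features, binary, indicator, correlation_ceiling=correlation_ceiling
        )
        out[ctype] = TypeSelection(
            cancer_type=ctype,
            ranking=BiomarkerRanking(ctype, ranking.ranking[:k]),
            best=best, all_scores=scored, selected=selected, redundancy_log=rlog,
        )
    return out


def build_selection_table(
    per_type_selections: dict[str, list[str]],
    feature_classes: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate per-type selections grouped by analyte class.

    Returns the table (one row per cancer type, one column per analyte class)
    and the sorted union of all selected features.
    """
    from .preprocess import METHYLATION, MIRNA, MUTATION

    rows = []
    union: set[str] = set()
    for ctype, feats in per_type_selections.items():
        union |= set(feats)
        if feature_classes is not None:
            by_class = {MUTATION: [], METHYLATION: [], MIRNA: []}
            for f in feats:
                by_class.setdefault(feature_classes.get(f, "other"), []).append(f)
            rows.append(
                {
                    "cancer_type": ctype,
                    "mutations": ", ".join(sorted(by_class[MUTATION])) or "-",
                    "methylation": ", ".join(sorted(by_class[METHYLATION])) or "-",
                    "mirnas": ", ".join(sorted(by_class[MIRNA])) or "-",
                }
            )
        else:
            rows.append({"cancer_type": ctype, "biomarkers": ", ".join(sorted(feats)) or "-"})
    table = pd.DataFrame(rows)
    return table, sorted(union)
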