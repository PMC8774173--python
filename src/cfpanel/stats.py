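"""Descriptive and inferential statistics for the cohort comparisons.

Wraps the classical tests used to characterize the cohort — Pearson chi-square
on 2x2 tables (no continuity correction), pooled two-sample t, Spearman rank
correlation, one-way ANOVA — plus the single documented chi-square split of
the samples on a binary feature (the first split of a CHAID-style tree; no
recursion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateTableError(ValueError):
    pass


class DegenerateSplitError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome with its effect summary."""

    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact one-line report
        core = f"statistic={self.statistic:.4f}, p={self.p_value:.4g}, df={self.df}"
        if self.effect:
            core += ", " + ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}" for k, v in self.effect.items())
        return f"TestResult({core})"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = feature (+/-), columns = class (e.g. healthy/tumor)."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("positive", "negative")
    col_labels: tuple[str, str] = ("healthy", "tumor")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise DegenerateTableError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def pearson_chi2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), df=float(dof))


def split_on_feature(
    samples: pd.DataFrame, feature: pd.Series, *, status_col: str = "group"
) -> tuple[dict[str, list[str]], TestResult]:
    """Partition samples on a binary feature and test it against tumor status.

    Returns ({'positive': ids, 'negative': ids}, chi-square result of the
    feature x (healthy vs tumor) table).  Only this single split is computed.
    """
    f = feature.reindex(samples["sample_id"]).astype(float)
    vals = set(f.dropna().unique())
    if not vals <= {0.0, 1.0}:
        raise ValueError("split feature must be binary 0/1")
    if len(vals) < 2:
        raise DegenerateSplitError("split feature is constant")
    tumor = (samples.set_index("sample_id")[status_col] != "healthy").astype(int)
    pos = f == 1.0
    table = ContingencyTable2x2(
        a=int(((pos) & (tumor == 0)).sum()),
        b=int(((pos) & (tumor == 1)).sum()),
        c=int(((~pos) & (tumor == 0)).sum()),
        d=int(((~pos) & (tumor == 1)).sum()),
        row_labels=("feature+", "feature-"),
        col_labels=("healthy", "tumor"),
    )
    groups = {
        "positive": list(f.index[pos]),
        "negative": list(f.index[~pos]),
    }
    return groups, pearson_chi2(table)


def burden_t_test(burdens_a, burdens_b) -> TestResult:
    """Pooled-variance two-sample t-test with mean difference, SE and 95% CI."""
    x = np.asarray(burdens_a, dtype=float)
    y = np.asarray(burdens_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    n1, n2 = len(x), len(y)
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dof
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    diff = float(x.mean() - y.mean())
    tcrit = float(sps.t.ppf(0.975, dof)) if se > 0 else 0.0
    return TestResult(
        statistic=float(t),
        p_value=float(p),
        df=float(dof),
        effect={
            "mean_difference": diff,
            "std_error": se,
            "ci95_low": diff - tcrit * se,
            "ci95_high": diff + tcrit * se,
        },
    )


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired observations with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), df=float(len(x) - 2), effect={"n": len(x)})


def one_way_anova(*groups) -> TestResult:
    """One-way ANOVA F-test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return TestResult(statistic=float(f), p_value=float(p), df=(float(k - 1), float(n - k)))


def pairwise_group_tests(
    values: pd.Series, groups: pd.Series, *, alpha: float = 0.05, adjust: str | None = None
) -> pd.DataFrame:
    """Per-pair pooled t-tests behind the letter-coded group contrasts.

    Returns a tidy frame (group_a, group_b, t, p, significant).  ``adjust``
    may be None (default; no correction) or 'bonferroni'.
    """
    labels = [g for g in pd.unique(groups) if pd.notna(g)]
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            va = values[groups == ga].dropna()
            vb = values[groups == gb].dropna()
            if len(va) < 2 or len(vb) < 2:
                continue
            res = burden_t_test(va, vb)
            rows.append((ga, gb, res.statistic, res.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    if adjust == "bonferroni" and len(out):
        out["p"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust not in (None, "bonferroni"):
        raise ValueError(f"unknown adjustment '{adjust}'")
    out["significant"] = out["p"] < alpha
    return out


def cohort_characteristics_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort summary (n, age, sex, stage counts, BMI)."""
    rows = []
    for group, sub in samples.groupby("group", sort=False):
        n = len(sub)
        rows.append(
            {
                "group": group,
                "n": n,
                "age_mean": sub["age"].mean(),
                "female_n": int((sub["sex"] == "female").sum()),
                "male_n": int((sub["sex"] == "male").sum()),
                "stage1_n": int((sub["stage"] == 1).sum()),
                "stage2_n": int((sub["stage"] == 2).sum()),
                "stage3_n": int((sub["stage"] == 3).sum()),
                "bmi_mean": sub["bmi"].mean(),
                "cfdna_mean": sub["cfdna_conc"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    order = {"healthy": 0}
    out = out.sort_values("group", key=lambda s: s.map(lambda g: (order.get(g, 1), g)))
    return out.reset_index(drop=True)
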