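"""Ct-level preprocessing: mutation calls, methylation percent, miRNA z-scores.

Three analyte blocks are derived from the raw Ct tables:

* mutations — dCt = Ct(mutation assay) - Ct(reference assay); a sample is
  called positive when dCt is defined and at or below the assay-specific
  cutoff.  Non-amplification (undetermined Ct) is non-detection.
* methylation — m% = 100 / (1 + 2**(CtMe - CtUnMe)), the two-fraction
  abundance estimator at 100% PCR efficiency; equal Cts give 50%, and
  m%(a, b) + m%(b, a) = 100.
* miRNA — per-sample global-mean normalization (rel_expr = mean detected Ct
  minus the miRNA's Ct, so higher = more abundant) followed by per-miRNA
  z-scoring over samples (n-1 standard deviation).

The blocks are assembled into a single samples x features matrix with an
analyte-class tag per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, ConfigurationError, PanelConfig

MUTATION = "mutation"
METHYLATION = "methylation"
MIRNA = "mirna"


class InputDomainError(ValueError):
    pass


class DegeneratePanelError(ValueError):
    pass


def compute_delta_ct(ct_mutation, ct_reference):
    """dCt = Ct(mutation) - Ct(reference); NaN if either Ct is undetermined.

    Accepts scalars or arrays.  Determined Cts must be positive.
    """
    m = np.asarray(ct_mutation, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if np.any((~np.isnan(m)) & (m <= 0)) or np.any((~np.isnan(r)) & (r <= 0)):
        raise InputDomainError("Ct values must be positive")
    out = m - r
    return float(out) if out.ndim == 0 else out


def call_mutation(delta_ct, assay_cutoff: float):
    """Positive iff dCt is defined and dCt <= cutoff; undefined dCt is negative."""
    if assay_cutoff is None or not np.isfinite(assay_cutoff):
        raise ConfigurationError("assay cutoff must be a finite real")
    d = np.asarray(delta_ct, dtype=float)
    out = (~np.isnan(d)) & (d <= assay_cutoff)
    return bool(out) if out.ndim == 0 else out


def mutation_call_table(mutation_cts: pd.DataFrame, panel: PanelConfig) -> pd.DataFrame:
    """Per-row mutation calls: columns sample_id, assay_id, delta_ct, positive."""
    missing = set(mutation_cts["assay_id"]) - set(panel.mutation_cutoffs)
    if missing:
        raise ConfigurationError(f"no cutoff configured for assay(s): {sorted(missing)}")
    out = mutation_cts[["sample_id", "assay_id"]].copy()
    out["delta_ct"] = compute_delta_ct(
        mutation_cts["ct_mutation"].to_numpy(), mutation_cts["ct_reference"].to_numpy()
    )
    cutoffs = mutation_cts["assay_id"].map(panel.mutation_cutoffs).to_numpy(dtype=float)
    d = out["delta_ct"].to_numpy()
    out["positive"] = (~np.isnan(d)) & (d <= cutoffs)
    return out


def mutation_calls_wide(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot the call table to samples x assays of 0/1 integers."""
    wide = calls.pivot(index="sample_id", columns="assay_id", values="positive")
    return wide.astype(float).fillna(0.0).astype(int)


def mutation_burden(calls: pd.DataFrame) -> pd.Series:
    """Number of positive mutation calls per sample."""
    return calls.groupby("sample_id")["positive"].sum().astype(int)


def methylation_percent(ct_me, ct_unme):
    """m% = 100 / (1 + 2**(CtMe - CtUnMe)); NaN propagates from either Ct."""
    me = np.asarray(ct_me, dtype=float)
    un = np.asarray(ct_unme, dtype=float)
    if np.any((~np.isnan(me)) & (me <= 0)) or np.any((~np.isnan(un)) & (un <= 0)):
        raise InputDomainError("Ct values must be positive")
    out = 100.0 / (1.0 + np.exp2(me - un))
    return float(out) if out.ndim == 0 else out


def methylation_values(methylation_cts: pd.DataFrame) -> pd.DataFrame:
    """Samples x regions table of methylation percentages (NaN if undetermined)."""
    df = methylation_cts.copy()
    df["m_percent"] = methylation_percent(df["ct_me"].to_numpy(), df["ct_unme"].to_numpy())
    return df.pivot(index="sample_id", columns="region", values="m_percent")


@dataclass(frozen=True)
class DetectionPolicy:
    """Rule for dropping miRNAs that failed to amplify.

    ``mode='reference'`` drops a miRNA when its Ct is undetermined in the
    named reference sample; ``mode='fraction'`` (default) drops it when it is
    undetermined in at least ``max_undetected_fraction`` of samples.
    """

    mode: str = "fraction"
    reference_sample: str | None = None
    max_undetected_fraction: float = 0.5


def drop_undetected_mirnas(
    mirna_cts: pd.DataFrame, policy: DetectionPolicy = DetectionPolicy()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove candidate miRNAs that fail the detection policy.

    The spike-in is never a candidate and is always retained in the table.
    Returns (reduced table, exclusion log with columns mirna_id/reason).
    """
    candidates = mirna_cts[~mirna_cts["is_spike_in"]]
    wide = candidates.pivot(index="sample_id", columns="mirna_id", values="ct")

    if policy.mode == "reference":
        if policy.reference_sample is None or policy.reference_sample not in wide.index:
            raise ConfigurationError("reference policy requires a reference sample present in the table")
        flagged = wide.columns[wide.loc[policy.reference_sample].isna()]
        reason = f"undetermined in reference sample {policy.reference_sample}"
    elif policy.mode == "fraction":
        frac = wide.isna().mean(axis=0)
        flagged = frac.index[frac >= policy.max_undetected_fraction]
        reason = f"undetermined in >= {policy.max_undetected_fraction:.0%} of samples"
    else:
        raise ConfigurationError(f"unknown detection policy mode '{policy.mode}'")

    if len(flagged) == len(wide.columns):
        raise DegeneratePanelError("all candidate miRNAs excluded by the detection policy")

    log = pd.DataFrame({"mirna_id": list(flagged), "reason": reason})
    keep = mirna_cts[mirna_cts["is_spike_in"] | ~mirna_cts["mirna_id"].isin(set(flagged))]
    return keep.reset_index(drop=True), log


def global_mean_normalize(mirna_cts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample global-mean normalization of miRNA Cts.

    rel_expr(sample, m) = mean over the sample's detected candidate miRNAs of
    Ct, minus Ct(sample, m) — a -dCt scale where higher means more abundant.
    The spike-in is excluded from the mean.  Samples with fewer than two
    detected miRNAs cannot be normalized and are returned in the flag list.
    """
    candidates = mirna_cts[~mirna_cts["is_spike_in"]]
    wide = candidates.pivot(index="sample_id", columns="mirna_id", values="ct")
    detected = wide.notna().sum(axis=1)
    flagged = list(wide.index[detected < 2])
    ok = wide.drop(index=flagged)
    rel = ok.mean(axis=1, skipna=True).to_numpy()[:, None] - ok.to_numpy()
    return pd.DataFrame(rel, index=ok.index, columns=ok.columns), flagged


def standardize_zscores(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-column z-scores over non-missing samples (n-1 sd).

    Constant columns (zero variance) get no z-scores and are reported in the
    flag list; missing cells stay missing.
    """
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    constant = list(values.columns[(sd == 0) | sd.isna()])
    z = (values - mean) / sd
    z = z.drop(columns=constant)
    return z, constant


@dataclass
class FeatureMatrix:
    """Samples x features with an analyte-class tag and drop log.

    ``values`` is a float DataFrame (mutation calls coded 0/1, methylation in
    percent, miRNAs as z-scores); ``classes`` maps each column to its analyte
    class; ``drop_log`` records columns removed during assembly.
    """

    values: pd.DataFrame
    classes: pd.Series
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature_id", "reason"])
    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def features_of_class(self, analyte: str) -> list[str]:
        return list(self.classes.index[self.classes == analyte])

    def to_csv(self, path) -> None:
        self.values.rename_axis("sample_id").to_csv(path, float_format="%.17g")


def assemble_feature_matrix(
    mutation_calls: pd.DataFrame,
    methylation: pd.DataFrame,
    mirna_z: pd.DataFrame,
    *,
    strict_complete: bool = True,
    drop_constant: bool = True,
) -> FeatureMatrix:
    """Join the three analyte blocks on their common samples.

    Under the default strict-complete policy, any column with a missing value
    is dropped (and logged); constant columns are likewise dropped since they
    cannot contribute to any contrast.
    """
    blocks = {MUTATION: mutation_calls.astype(float), METHYLATION: methylation, MIRNA: mirna_z}
    seen: dict[str, str] = {}
    for analyte, block in blocks.items():
        for col in block.columns:
            if col in seen:
                raise ValueError(f"feature id '{col}' appears in both {seen[col]} and {analyte}")
            seen[col] = analyte

    common = blocks[MUTATION].index
    for block in (methylation, mirna_z):
        common = common.intersection(block.index)
    joined = pd.concat([b.loc[common] for b in blocks.values()], axis=1)
    classes = pd.Series(seen)[joined.columns]

    log: list[tuple[str, str]] = []
    if strict_complete:
        incomplete = joined.columns[joined.isna().any(axis=0)]
        log += [(c, "missing values") for c in incomplete]
        joined = joined.drop(columns=incomplete)
    if drop_constant:
        constant = joined.columns[joined.nunique(dropna=True) <= 1]
        log += [(c, "constant") for c in constant]
        joined = joined.drop(columns=constant)

    return FeatureMatrix(
        values=joined,
        classes=classes[joined.columns],
        drop_log=pd.DataFrame(log, columns=["feature_id", "reason"]),
    )


def preprocess_cohort(
    dataset: CohortDataset,
    *,
    detection_policy: DetectionPolicy = DetectionPolicy(),
) -> dict:
    """Run the full Ct -> feature-matrix pipeline on a cohort.

    Returns a dict with the call table, burden series, methylation table,
    miRNA rel_expr/z-score tables, the assembled FeatureMatrix and the
    intermediate logs.
    """
    calls = mutation_call_table(dataset.mutation_cts, dataset.panel)
    burden = mutation_burden(calls)
    meth = methylation_values(dataset.methylation_cts)
    mirna_kept, mirna_log = drop_undetected_mirnas(dataset.mirna_cts, detection_policy)
    rel_expr, flagged_samples = global_mean_normalize(mirna_kept)
    zscores, constant_mirnas = standardize_zscores(rel_expr)
    fm = assemble_feature_matrix(mutation_calls_wide(calls), meth, zscores)
    return {
        "calls": calls,
        "burden": burden,
        "methylation": meth,
        "mirna_rel_expr": rel_expr,
        "mirna_zscores": zscores,
        "mirna_exclusion_log": mirna_log,
        "flagged_samples": flagged_samples,
        "constant_mirnas": constant_mirnas,
        "feature_matrix": fm,
    }
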