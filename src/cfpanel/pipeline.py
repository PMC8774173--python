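"""End-to-end orchestration: read -> exclude -> preprocess -> stats ->
select -> classify, with a paper-style report bundle on disk.

Every run writes a manifest (seed, config hash, package version) so any
bundle can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import ExclusionRules, apply_exclusions, read_cohort
from .discriminant import (
    TwoStepClassifier, da_table, roc_points, run_da_suite, standard_feature_sets,
)
from .preprocess import DetectionPolicy, preprocess_cohort
from .selection import build_selection_table, select_biomarkers
from .simulate import AR_ASSAY, GeneratorConfig, generate_cohort, write_ground_truth
from .stats import (
    burden_t_test, cohort_characteristics_table, spearman_correlation, split_on_feature,
)


@dataclass
class PipelineConfig:
    """Run configuration: either an input directory with the four CSV tables
    + panel.yaml, or a generator seed for a synthetic cohort."""

    outdir: str | Path
    input_dir: str | Path | None = None
    seed: int | None = None
    generator: GeneratorConfig | None = None
    exclusions: ExclusionRules = field(default_factory=ExclusionRules)
    selection_k: int = 4
    correlation_ceiling: float = 0.9
    score_mode: str = "loocv"
    priors: str = "equal"
    ar_feature: str = AR_ASSAY
    detection_policy: DetectionPolicy = field(default_factory=DetectionPolicy)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle to outdir.

    Returns the bundle as a dict (also serialized to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- load / synthesize -------------------------------------------------
    truth = None
    if config.input_dir is not None:
        d = Path(config.input_dir)
        try:
            dataset = read_cohort(d / "samples.csv", d / "mutations.csv",
                                  d / "methylation.csv", d / "mirna.csv", d / "panel.yaml")
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
    else:
        if config.seed is None and config.generator is None:
            raise PipelineError("load", "either input_dir or a generator seed is required")
        gen = config.generator or GeneratorConfig(seed=config.seed)
        dataset, truth = generate_cohort(gen)
        write_ground_truth(truth, outdir / "ground_truth.json")

    # --- exclusions --------------------------------------------------------
    try:
        dataset, exclusion_log = apply_exclusions(dataset, config.exclusions)
    except Exception as exc:
        raise PipelineError("exclude", str(exc)) from exc
    exclusion_log.to_csv(outdir / "exclusion_log.csv", index=False)

    # --- preprocessing -----------------------------------------------------
    try:
        pre = preprocess_cohort(dataset, detection_policy=config.detection_policy)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    fm = pre["feature_matrix"]
    fm.to_csv(outdir / "features.csv")
    meta = pd.DataFrame({"feature_id": fm.feature_ids,
                         "analyte_class": [fm.classes[f] for f in fm.feature_ids]})
    meta.to_csv(outdir / "features_meta.csv", index=False)
    fm.drop_log.to_csv(outdir / "features_dropped.csv", index=False)

    samples = dataset.samples[dataset.samples["sample_id"].isin(fm.sample_ids)]
    groups = samples.set_index("sample_id")["group"].reindex(fm.values.index)
    tumor = (groups != "healthy").astype(int).to_numpy()

    # --- cohort statistics -------------------------------------------------
    try:
        stats_report: dict = {}
        burden = pre["burden"].reindex(fm.values.index)
        t = burden_t_test(burden[tumor == 1], burden[tumor == 0])
        stats_report["mutation_burden"] = {
            "tumor_mean": float(burden[tumor == 1].mean()),
            "healthy_mean": float(burden[tumor == 0].mean()),
            "t": t.statistic, "p": t.p_value, **t.effect,
        }
        conc = samples.set_index("sample_id")["cfdna_conc"].reindex(fm.values.index)
        stage = samples.set_index("sample_id")["stage"].reindex(fm.values.index)
        ok = conc.notna()
        rho = spearman_correlation(stage[ok], conc[ok])
        stats_report["cfdna_stage_spearman"] = {"rho": rho.statistic, "p": rho.p_value,
                                                "n": int(ok.sum())}
        ar_split = None
        if config.ar_feature in fm.values.columns:
            groups_split, chi2 = split_on_feature(samples, fm.values[config.ar_feature])
            ar_split = {
                "feature": config.ar_feature,
                "n_positive": len(groups_split["positive"]),
                "n_negative": len(groups_split["negative"]),
                "healthy_in_positive": int(
                    (groups.loc[groups_split["positive"]] == "healthy").sum()),
                "chi2": chi2.statistic, "p": chi2.p_value,
            }
        stats_report["ar_split"] = ar_split
        table1 = cohort_characteristics_table(samples)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    table1.to_csv(outdir / "table1.csv", index=False, float_format="%.2f")
    (outdir / "stats_report.json").write_text(
        json.dumps(stats_report, indent=2, default=_json_default))

    # --- biomarker selection ----------------------------------------------
    try:
        selections = select_biomarkers(
            fm, samples, k=config.selection_k,
            correlation_ceiling=config.correlation_ceiling, mode=config.score_mode)
        per_type = {t: sorted(set(s.selected) - {config.ar_feature})
                    for t, s in selections.items()}
        table2, union = build_selection_table(
            {t: s.selected for t, s in selections.items()}, fm.classes)
        selection_report = {
            t: {
                "ranking": [[f, r] for f, r in s.ranking.ranking],
                "best_subset": list(s.best.features),
                "best_score": s.best.score,
                "fn": s.best.fn, "fp": s.best.fp,
                "selected": s.selected,
                "redundancy_dropped": s.redundancy_log,
            }
            for t, s in selections.items()
        }
        selection_report["_union"] = union
        selection_report["_union_size"] = len(union)
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    table2.to_csv(outdir / "table2.csv", index=False)
    (outdir / "selection_report.json").write_text(
        json.dumps(selection_report, indent=2, default=_json_default))

    # --- classification ----------------------------------------------------
    try:
        downstream = sorted({f for feats in per_type.values() for f in feats})
        if config.ar_feature in fm.values.columns:
            ar_mask = fm.values[config.ar_feature].to_numpy() == 1
            neg = fm.values.index[~ar_mask]
            sets = standard_feature_sets(fm, downstream, config.ar_feature)
            neg_fm_values = fm.values.loc[neg]
            da_results, skipped = run_da_suite(neg_fm_values, tumor[~ar_mask], sets,
                                               priors=config.priors)
            two_step = TwoStepClassifier(fm, tumor, config.ar_feature, downstream,
                                         priors=config.priors).fit()
        else:
            sets = standard_feature_sets(fm, downstream, config.ar_feature)
            da_results, skipped = run_da_suite(fm.values, tumor, sets, priors=config.priors)
            two_step = None
        table3 = da_table(da_results)
        roc_rows = []
        for r in da_results:
            pts = roc_points(r.scores[np.isfinite(r.scores)], r.labels[np.isfinite(r.scores)])
            pts.insert(0, "model", r.label)
            roc_rows.append(pts)
        metrics = {
            r.label: {
                "features": r.features, "n_features": r.n_features,
                "confusion": {"tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn},
                "accuracy_pct": r.accuracy, "sensitivity_pct": r.sensitivity,
                "specificity_pct": r.specificity, "auc": r.auc,
                "fold_warnings": r.fold_warnings,
            }
            for r in da_results
        }
        metrics["_skipped"] = skipped
        if two_step is not None:
            metrics["two_step"] = {
                "split_feature": config.ar_feature,
                "confusion": two_step.confusion(),
                "accuracy_pct": two_step.accuracy,
                "sensitivity_pct": two_step.sensitivity,
                "specificity_pct": two_step.specificity,
            }
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    table3.to_csv(outdir / "table3.csv", index=False)
    if roc_rows:
        pd.concat(roc_rows).to_csv(outdir / "roc_points.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    (outdir / "model_metrics.json").write_text(
        json.dumps(metrics, indent=2, default=_json_default))

    # --- manifest ----------------------------------------------------------
    cfg_repr = {
        "seed": config.seed, "input_dir": str(config.input_dir) if config.input_dir else None,
        "selection_k": config.selection_k, "correlation_ceiling": config.correlation_ceiling,
        "score_mode": config.score_mode, "priors": config.priors,
        "ar_feature": config.ar_feature,
        "exclusions": dataclasses.asdict(config.exclusions),
    }
    manifest = {
        "package_version": __version__,
        "config": cfg_repr,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_repr, sort_keys=True).encode()).hexdigest()[:16],
        "n_samples": int(len(samples)),
        "n_features": len(fm.feature_ids),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "dataset": dataset, "truth": truth, "preprocessed": pre,
        "stats_report": stats_report, "table1": table1,
        "selections": selections, "table2": table2, "union": union,
        "da_results": da_results, "table3": table3,
        "two_step": two_step, "manifest": manifest,
    }


def summarize(outdir: str | Path) -> str:
    """One-page text summary of a report bundle directory."""
    outdir = Path(outdir)
    lines: list[str] = ["cfpanel run summary", "=" * 40]
    warnings: list[str] = []

    def load(name):
        p = outdir / name
        if not p.exists():
            warnings.append(f"missing {name}")
            return None
        return json.loads(p.read_text()) if name.endswith(".json") else pd.read_csv(p)

    table1 = load("table1.csv")
    if table1 is not None:
        lines.append(f"cohort: {int(table1['n'].sum())} samples in {len(table1)} groups")
        lines.append("  " + ", ".join(f"{g} {n}" for g, n in zip(table1["group"], table1["n"])))
    stats = load("stats_report.json")
    if stats is not None:
        mb = stats.get("mutation_burden", {})
        lines.append(
            f"mutation burden: tumor {mb.get('tumor_mean', float('nan')):.2f} vs "
            f"healthy {mb.get('healthy_mean', float('nan')):.2f} "
            f"(diff {mb.get('mean_difference', float('nan')):.2f}, p={mb.get('p', float('nan')):.2g})")
        ar = stats.get("ar_split")
        if ar:
            lines.append(
                f"AR split: {ar['n_positive']} positive ({ar['healthy_in_positive']} healthy) / "
                f"{ar['n_negative']} negative, chi2 {ar['chi2']:.3f} (p={ar['p']:.2g})")
        rho = stats.get("cfdna_stage_spearman")
        if rho:
            lines.append(f"cfDNA vs stage: Spearman rho {rho['rho']:.3f} (p={rho['p']:.2g})")
    sel = load("selection_report.json")
    if sel is not None:
        lines.append(f"selected biomarker union: {sel.get('_union_size')} features")
        for t, entry in sel.items():
            if not t.startswith("_"):
                lines.append(f"  {t}: {', '.join(entry['selected'])}")
    table3 = load("table3.csv")
    if table3 is not None:
        lines.append("discriminant models:")
        for _, row in table3.iterrows():
            lines.append(
                f"  {row['model']}: acc {row['accuracy_pct']}%  sens {row['sensitivity_pct']}%  "
                f"spec {row['specificity_pct']}%  AUC {row['roc_auc']}  "
                f"({row['n_biomarkers']} biomarkers)")
    metrics = load("model_metrics.json")
    if metrics is not None and "two_step" in metrics:
        ts = metrics["two_step"]
        lines.append(
            f"two-step (split on {ts['split_feature']}): acc {ts['accuracy_pct']:.1f}%  "
            f"sens {ts['sensitivity_pct']:.1f}%  spec {ts['specificity_pct']:.1f}%")
    if warnings:
        lines.append("warnings: " + "; ".join(warnings))
    return "\n".join(lines)
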