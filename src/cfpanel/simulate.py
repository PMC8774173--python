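"""Synthetic Ct-level cohort generator.

Emits the four input tables (sample sheet + three Ct tables) with the
statistical structure the downstream analysis assumes, so that every pipeline
stage is testable without patient data:

* fixed per-group sample counts (default: the study layout — 15 healthy and
  197 tumor samples over 9 solid-cancer types) with deterministic per-group
  stage counts;
* an androgen-receptor (AR) point-mutation call planted with per-group
  prevalences (absent in healthy controls by default);
* total mutation burden drawn as AR + Poisson, with a higher mean for AR+
  tumors than AR- tumors and a low healthy background;
* stage-dependent plasma cfDNA concentration (lognormal around stage means);
* per-cancer-type planted effects on methylation (a shift of the
  CtMe - CtUnMe gap) and on miRNA abundance (a Ct shift), mimicking the
  group-specific deregulation the analysis is meant to recover;
* additive Gaussian Ct measurement noise and a per-sample "plate/yield"
  shift on the miRNA block (removed by global-mean normalization).

The default mutation-assay and miRNA panels are synthetic stand-ins: the
handful of assay identifiers reported in the literature are kept verbatim and
the remainder of the 75-assay / 47-miRNA panels is filled with synthetic
placeholder entries (``SYN*`` assays, common circulating miRNA names).

A fixed seed makes the output byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CohortDataset, ConfigurationError, ExclusionRules, PanelConfig

# ---------------------------------------------------------------------------
# default panels

_NAMED_ASSAYS = {
    "COSM238555": "AR",
    "COSM6224": "EGFR",
    "COSM10758": "TP53",
    "COSM718": "FGFR3",
    "COSM1716559": "TERT",
    "COSM18561": "APC",
    "COSM5663": "CTNNB1",
    "COSM517": "KRAS",
    "COSM760": "PIK3CA",
    "COSM10662": "TP53",
    "COSM6549": "TP53",
    "COSM10690": "TP53",
    "COSM10863": "TP53",
    "COSM5677": "CTNNB1",
    "COSM6223": "EGFR",
    "COSM22932": "FBXW7",
    "COSM483": "HRAS",
    "COSM499": "HRAS",
    "COSM518": "KRAS",
    "COSM10779": "TP53",
}

#: assays that never amplify in any sample (their columns are constant and
#: get dropped during feature assembly)
DEFAULT_NEVER_DETECTED = (
    "COSM5677", "COSM6223", "COSM22932", "COSM483", "COSM499", "COSM518", "COSM10779",
)

_FILLER_GENES = (
    "AKT1", "BRAF", "CTNNB1", "EGFR", "ERBB2", "ESR1", "FBXW7", "FGFR3", "GNAS",
    "HRAS", "IDH1", "KRAS", "MED12", "NRAS", "PIK3CA", "SMAD4", "TERT", "TP53", "VHL",
)

METHYLATION_REGIONS = (
    "SEPT9", "MLH1", "MGMT", "GATA5", "GSTP1", "SFN",
    "MDR1", "VIM", "SHOX2", "ALKBH3", "APC", "RASSF1A",
)

_NAMED_MIRNAS = (
    "miR-17-5p", "miR-20a-5p", "miR-21-5p", "miR-26a-5p", "miR-27a-3p",
    "miR-29c-3p", "miR-92a-3p", "miR-101-3p", "miR-133a-3p", "miR-148b-3p",
    "miR-155-5p", "miR-195-5p", "miR-30a-5p", "miR-218-5p", "miR-1225-3p",
    "miR-203a-3p", "miR-148a-3p", "miR-34a-5p", "miR-31-5p", "miR-23a-3p",
    "miR-25-3p", "miR-210-3p",
)

_FILLER_MIRNAS = (
    "miR-16-5p", "miR-15a-5p", "miR-19a-3p", "miR-19b-3p", "miR-22-3p",
    "miR-24-3p", "miR-26b-5p", "miR-27b-3p", "miR-28-3p", "miR-29a-3p",
    "miR-30c-5p", "miR-93-5p", "miR-103a-3p", "miR-106a-5p", "miR-107",
    "miR-122-5p", "miR-126-3p", "miR-130a-3p", "miR-143-3p", "miR-145-5p",
    "miR-150-5p", "miR-181a-5p", "miR-191-5p", "miR-221-3p", "let-7a-5p",
)

SPIKE_IN = "cel-miR-39-3p"

#: miRNAs planted below the detection limit (dropped by the detection policy)
DEFAULT_UNDETECTED_MIRNAS = ("miR-30a-5p", "miR-218-5p", "miR-1225-3p", "miR-203a-3p")


def default_panel(*, n_mutation_assays: int = 75, delta_ct_cutoff: float = 8.0,
                  ct_ceiling: float = 40.0) -> PanelConfig:
    """The default (partly synthetic) assay panel: 75 mutation assays across
    the canonical gene list, 12 methylation regions, 47 miRNAs + spike-in."""
    cutoffs = {a: delta_ct_cutoff for a in _NAMED_ASSAYS}
    genes = dict(_NAMED_ASSAYS)
    i = 0
    while len(cutoffs) < n_mutation_assays:
        aid = f"SYN{i:03d}"
        cutoffs[aid] = delta_ct_cutoff
        genes[aid] = _FILLER_GENES[i % len(_FILLER_GENES)]
        i += 1
    return PanelConfig(
        mutation_cutoffs=cutoffs,
        mutation_genes=genes,
        methylation_regions=METHYLATION_REGIONS,
        mirna_panel=_NAMED_MIRNAS + _FILLER_MIRNAS,
        spike_in=SPIKE_IN,
        ct_ceiling=ct_ceiling,
    )


# ---------------------------------------------------------------------------
# study-shaped cohort parameters

DEFAULT_GROUP_SIZES = {
    "healthy": 15, "bladder": 20, "brain": 9, "breast": 30, "colorectal": 28,
    "lung": 29, "ovarian": 19, "prostate": 27, "stomach": 23, "pancreas": 12,
}

#: per-group (stage I, II, III) counts; they sum to 39 / 81 / 77
DEFAULT_STAGE_COUNTS = {
    "bladder": (9, 6, 5), "brain": (2, 4, 3), "breast": (8, 16, 6),
    "colorectal": (3, 19, 6), "lung": (1, 12, 16), "ovarian": (0, 4, 15),
    "prostate": (16, 7, 4), "stomach": (0, 8, 15), "pancreas": (0, 5, 7),
}

DEFAULT_AR_PREVALENCE = {
    "healthy": 0.0, "colorectal": 0.8571, "bladder": 0.80, "prostate": 0.6667,
    "breast": 0.60, "lung": 0.4828, "stomach": 0.2609, "ovarian": 0.20,
    "brain": 0.1111, "pancreas": 0.0833,
}

_DEMOGRAPHICS = {  # group -> (age mean, female fraction, bmi mean)
    "healthy": (54.60, 8 / 15, 25.47), "bladder": (70.75, 3 / 20, 26.26),
    "brain": (63.22, 3 / 9, 25.22), "breast": (63.67, 29 / 30, 25.50),
    "colorectal": (66.57, 14 / 28, 24.65), "lung": (62.62, 4 / 29, 25.77),
    "ovarian": (60.95, 1.0, 28.19), "prostate": (66.70, 0.0, 26.08),
    "stomach": (69.35, 15 / 23, 22.98), "pancreas": (67.08, 6 / 12, 24.41),
    "liver": (63.0, 0.4, 25.0),
}

AR_ASSAY = "COSM238555"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted group-specific marker effect.

    ``analyte`` is 'methylation' (effect = reduction of the CtMe - CtUnMe gap
    in cycles; positive means more methylated), 'mirna' (effect = Ct
    reduction in cycles; positive means up-regulated) or 'mutation' (effect =
    multiplicative weight on the assay when allocating the sample's positive
    calls).
    """

    feature_id: str
    analyte: str
    effect: float


def default_planted_markers() -> dict[str, list[PlantedEffect]]:
    """Per-cancer-type planted effects mirroring the marker sets the
    selection stage should recover."""
    m, mi, mu = "methylation", "mirna", "mutation"
    return {
        "bladder": [PlantedEffect("COSM10758", mu, 15.0), PlantedEffect("miR-17-5p", mi, 2.0)],
        "brain": [PlantedEffect("MLH1", m, 1.5), PlantedEffect("GATA5", m, 1.5),
                  PlantedEffect("miR-133a-3p", mi, 2.0)],
        "breast": [PlantedEffect("COSM10758", mu, 15.0), PlantedEffect("MDR1", m, 1.5),
                   PlantedEffect("miR-17-5p", mi, 2.0)],
        "colorectal": [PlantedEffect("COSM10758", mu, 15.0), PlantedEffect("miR-17-5p", mi, 2.0)],
        "lung": [PlantedEffect("COSM10758", mu, 15.0), PlantedEffect("miR-17-5p", mi, 2.0),
                 PlantedEffect("miR-92a-3p", mi, 2.0), PlantedEffect("miR-155-5p", mi, 2.0)],
        "ovarian": [PlantedEffect("miR-29c-3p", mi, 2.0), PlantedEffect("miR-92a-3p", mi, 2.0),
                    PlantedEffect("miR-101-3p", mi, 2.0), PlantedEffect("miR-148b-3p", mi, 2.0)],
        "pancreas": [PlantedEffect("SFN", m, 1.5), PlantedEffect("miR-27a-3p", mi, 2.0),
                     PlantedEffect("miR-29c-3p", mi, 2.0), PlantedEffect("miR-148b-3p", mi, 2.0)],
        "prostate": [PlantedEffect("miR-17-5p", mi, 2.0), PlantedEffect("miR-26a-5p", mi, 2.0)],
        "stomach": [PlantedEffect("COSM18561", mu, 15.0), PlantedEffect("miR-20a-5p", mi, 2.0),
                    PlantedEffect("miR-21-5p", mi, 2.0)],
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    stage_counts: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    ar_prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AR_PREVALENCE))
    burden_mean_healthy: float = 1.33
    burden_mean_tumor_ar_pos: float = 7.5   # AR call included in the count
    burden_mean_tumor_ar_neg: float = 4.8
    cfdna_stage_means: tuple[float, float, float] = (0.435, 1.091, 2.506)  # ng/uL
    cfdna_healthy_mean: float = 0.557
    cfdna_log_sd: float = 0.5
    ct_noise_sd: float = 0.25               # qPCR measurement noise, cycles
    subject_sd_methylation: float = 0.8     # biological sd of CtMe-CtUnMe, cycles
    subject_sd_mirna: float = 1.0           # biological sd of miRNA Ct, cycles
    methylation_baseline_gap: float = 1.5   # baseline CtMe-CtUnMe (m% ~ 26)
    planted_markers: dict[str, list[PlantedEffect]] = field(
        default_factory=default_planted_markers)
    undetected_mirnas: tuple[str, ...] = DEFAULT_UNDETECTED_MIRNAS
    panel: PanelConfig = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        for g, p in self.ar_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"AR prevalence for {g} out of [0,1]: {p}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be positive")
        valid = set(self.panel.mutation_cutoffs) | set(self.panel.methylation_regions) | set(
            self.panel.mirna_panel)
        for ctype, effects in self.planted_markers.items():
            for e in effects:
                if e.feature_id not in valid:
                    raise ConfigurationError(
                        f"planted feature '{e.feature_id}' for {ctype} is not in the panel")


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Zero every group effect: identical feature distributions in all groups."""
    return replace(
        config,
        ar_prevalence={g: 0.0 for g in config.ar_prevalence},
        burden_mean_tumor_ar_pos=config.burden_mean_healthy,
        burden_mean_tumor_ar_neg=config.burden_mean_healthy,
        cfdna_stage_means=(config.cfdna_healthy_mean,) * 3,
        planted_markers={},
    )


def _lognormal(rng: np.random.Generator, mean: float, log_sd: float, size: int) -> np.ndarray:
    mu = np.log(mean) - log_sd**2 / 2.0
    return rng.lognormal(mu, log_sd, size)


def _sample_sheet(cfg: GeneratorConfig, rng: np.random.Generator,
                  extra_groups: dict[str, int]) -> pd.DataFrame:
    rows = []
    idx = 0
    groups = dict(cfg.group_sizes)
    for g, n in extra_groups.items():
        groups[g] = groups.get(g, 0) + n
    for group in sorted(groups):
        n = groups[group]
        if group == "healthy":
            stages = [0] * n
        else:
            counts = cfg.stage_counts.get(group)
            if counts is None:
                # groups without an exact layout (e.g. liver): spread stages
                # 1..3 as evenly as possible
                base = [1, 2, 3] * (n // 3 + 1)
                stages = sorted(base[:n])
            else:
                stages = [1] * counts[0] + [2] * counts[1] + [3] * counts[2]
                stages = stages[:n]
                stages += [2] * (n - len(stages))  # resized groups: mid-stage padding
        age_mean, female_frac, bmi_mean = _DEMOGRAPHICS.get(group, (64.0, 0.5, 25.0))
        for stage in stages:
            rows.append(
                {
                    "sample_id": f"S{idx:03d}",
                    "group": group,
                    "stage": stage,
                    "age": float(np.clip(rng.normal(age_mean, 10.0), 26.0, 95.0).round(1)),
                    "sex": "female" if rng.random() < female_frac else "male",
                    "bmi": float(np.clip(rng.normal(bmi_mean, 3.0), 15.0, 45.0).round(1)),
                    "cfdna_conc": np.nan,  # filled below, stage-dependent
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    conc = np.empty(len(df))
    for i, (group, stage) in enumerate(zip(df["group"], df["stage"])):
        mean = cfg.cfdna_healthy_mean if stage == 0 else cfg.cfdna_stage_means[stage - 1]
        conc[i] = _lognormal(rng, mean, cfg.cfdna_log_sd, 1)[0]
    df["cfdna_conc"] = np.round(conc, 4)
    return df


def _mutation_table(cfg: GeneratorConfig, rng: np.random.Generator,
                    samples: pd.DataFrame, truth: dict) -> pd.DataFrame:
    panel = cfg.panel
    assays = panel.mutation_assays
    detected = [a for a in assays if a not in DEFAULT_NEVER_DETECTED and a != AR_ASSAY]
    rows = []
    for _, s in samples.iterrows():
        group = s["group"]
        prev = cfg.ar_prevalence.get(group, 0.3)
        ar_pos = bool(rng.random() < prev)
        if group == "healthy":
            mean_other = cfg.burden_mean_healthy
        elif ar_pos:
            mean_other = max(cfg.burden_mean_tumor_ar_pos - 1.0, 0.0)
        else:
            mean_other = cfg.burden_mean_tumor_ar_neg
        n_other = int(min(rng.poisson(mean_other), len(detected)))
        weights = np.ones(len(detected))
        for eff in cfg.planted_markers.get(group, []):
            if eff.analyte == "mutation" and eff.feature_id in detected:
                weights[detected.index(eff.feature_id)] = eff.effect
        p = weights / weights.sum()
        positive = set(rng.choice(detected, size=n_other, replace=False, p=p)) if n_other else set()
        if ar_pos:
            positive.add(AR_ASSAY)
        truth["samples"][s["sample_id"]].update(
            {"ar_positive": ar_pos, "burden": len(positive)})
        for assay in assays:
            ct_ref = rng.normal(27.0, cfg.ct_noise_sd)
            cutoff = panel.mutation_cutoffs[assay]
            if assay in positive:
                delta = cutoff - rng.uniform(0.5, 4.0)
                ct_mut = ct_ref + delta
            elif rng.random() < 0.7 or assay in DEFAULT_NEVER_DETECTED:
                ct_mut = np.nan  # no amplification
            else:
                ct_mut = min(ct_ref + cutoff + rng.uniform(1.0, 6.0), panel.ct_ceiling + 1)
                if ct_mut >= panel.ct_ceiling:
                    ct_mut = np.nan
            rows.append((s["sample_id"], assay, panel.mutation_genes[assay],
                         round(ct_mut, 4) if np.isfinite(ct_mut) else np.nan,
                         round(ct_ref, 4)))
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "gene", "ct_mutation", "ct_reference"])


def _methylation_table(cfg: GeneratorConfig, rng: np.random.Generator,
                       samples: pd.DataFrame) -> pd.DataFrame:
    regions = cfg.panel.methylation_regions
    offsets = np.linspace(-0.5, 0.5, len(regions))
    rows = []
    for _, s in samples.iterrows():
        shifts = {
            e.feature_id: e.effect
            for e in cfg.planted_markers.get(s["group"], [])
            if e.analyte == "methylation"
        }
        for region, off in zip(regions, offsets):
            gap = (cfg.methylation_baseline_gap + off
                   + rng.normal(0.0, cfg.subject_sd_methylation)
                   - shifts.get(region, 0.0))
            ct_unme = rng.normal(26.0, cfg.ct_noise_sd)
            ct_me = ct_unme + gap + rng.normal(0.0, cfg.ct_noise_sd)
            rows.append((s["sample_id"], region, round(ct_me, 4), round(ct_unme, 4)))
    return pd.DataFrame(rows, columns=["sample_id", "region", "ct_me", "ct_unme"])


def _mirna_table(cfg: GeneratorConfig, rng: np.random.Generator,
                 samples: pd.DataFrame) -> pd.DataFrame:
    panel = cfg.panel.mirna_panel
    baseline = dict(zip(panel, np.linspace(24.0, 32.0, len(panel))))
    rows = []
    for _, s in samples.iterrows():
        yield_shift = rng.normal(0.0, 0.7)  # per-sample RNA yield / plate shift
        shifts = {
            e.feature_id: e.effect
            for e in cfg.planted_markers.get(s["group"], [])
            if e.analyte == "mirna"
        }
        for mirna in panel:
            if mirna in cfg.undetected_mirnas:
                ct = np.nan
            else:
                ct = (baseline[mirna] + yield_shift - shifts.get(mirna, 0.0)
                      + rng.normal(0.0, cfg.subject_sd_mirna)
                      + rng.normal(0.0, cfg.ct_noise_sd))
            rows.append((s["sample_id"], mirna,
                         round(ct, 4) if np.isfinite(ct) else np.nan, False))
        rows.append((s["sample_id"], cfg.panel.spike_in,
                     round(22.0 + rng.normal(0.0, cfg.ct_noise_sd), 4), True))
    return pd.DataFrame(rows, columns=["sample_id", "mirna_id", "ct", "is_spike_in"])


def generate_cohort(
    config: GeneratorConfig, *, extra_groups: dict[str, int] | None = None
) -> tuple[CohortDataset, dict]:
    """Generate a full synthetic cohort plus its ground-truth ledger.

    The ledger records per-sample true status, AR call and realized burden,
    and every planted effect.  The same config (seed included) reproduces the
    output exactly.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config, rng, extra_groups or {})
    truth: dict = {
        "seed": config.seed,
        "planted_markers": {
            g: [(e.feature_id, e.analyte, e.effect) for e in effs]
            for g, effs in config.planted_markers.items()
        },
        "samples": {
            sid: {"group": grp, "tumor": grp != "healthy"}
            for sid, grp in zip(samples["sample_id"], samples["group"])
        },
    }
    mutation_cts = _mutation_table(config, rng, samples, truth)
    methylation_cts = _methylation_table(config, rng, samples)
    mirna_cts = _mirna_table(config, rng, samples)
    dataset = CohortDataset(samples, mutation_cts, methylation_cts, mirna_cts, config.panel)
    return dataset, truth


def generate_null_cohort(config: GeneratorConfig) -> tuple[CohortDataset, dict]:
    """Cohort with every group effect zeroed (type-I-error calibration)."""
    return generate_cohort(null_config(config))


def generate_study_cohort(
    seed: int, config: GeneratorConfig | None = None
) -> tuple[CohortDataset, ExclusionRules, dict]:
    """Raw study-shaped cohort: the analysis groups plus a 7-member liver
    group and one listed-for-exclusion ovarian sample, with the matching
    exclusion rules (drop the listed sample; minimum group size 8)."""
    cfg = replace(config, seed=seed) if config else GeneratorConfig(seed=seed)
    sizes = dict(cfg.group_sizes)
    sizes["ovarian"] = sizes.get("ovarian", 0) + 1  # the later-excluded sample
    cfg = replace(cfg, group_sizes=sizes)
    dataset, truth = generate_cohort(cfg, extra_groups={"liver": 7})
    ovarian_ids = dataset.samples.loc[dataset.samples["group"] == "ovarian", "sample_id"]
    excluded = ovarian_ids.iloc[-1]
    rules = ExclusionRules(
        drop_samples={excluded: "post-collection stage-4 diagnosis"},
        min_group_size=8,
    )
    truth["listed_exclusion"] = excluded
    return dataset, rules, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
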