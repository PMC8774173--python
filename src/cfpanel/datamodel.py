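"""Data model and delimited-text IO for multi-analyte liquid-biopsy cohorts.

A cohort bundles a sample sheet (group, stage, demographics, plasma cfDNA
concentration) with three long-format qPCR cycle-threshold (Ct) tables:

* mutation assays   — Ct of the mutation assay and of its reference assay,
* methylation assays — Ct of the methylated and of the unmethylated cfDNA
  fraction for each genomic region (MBD two-fraction capture),
* miRNA assays      — one Ct per circulating miRNA plus a spike-in control.

Undetermined Ct values (non-amplification) are an explicit state: on input,
empty cells, the string ``Undetermined`` and any Ct at or above the configured
ceiling (instrument cycle cap, default 40) all map to ``NaN``, which is the
in-memory sentinel throughout the package.

All tables are comma-delimited UTF-8 with a single header row and ``.`` as
decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Group labels used in the analysis (healthy + 9 solid-tumor types).
ANALYSIS_GROUPS = (
    "healthy",
    "bladder",
    "brain",
    "breast",
    "colorectal",
    "lung",
    "ovarian",
    "prostate",
    "stomach",
    "pancreas",
)

#: Labels accepted on input.  "liver" may appear in a raw cohort but is
#: expected to be removed by the exclusion rules before analysis.
INPUT_GROUPS = ANALYSIS_GROUPS + ("liver",)

UNDETERMINED_STRINGS = {"", "undetermined", "na", "nan"}

SAMPLE_COLUMNS = ["sample_id", "group", "stage", "age", "sex", "bmi", "cfdna_conc"]
MUTATION_COLUMNS = ["sample_id", "assay_id", "gene", "ct_mutation", "ct_reference"]
METHYLATION_COLUMNS = ["sample_id", "region", "ct_me", "ct_unme"]
MIRNA_COLUMNS = ["sample_id", "mirna_id", "ct", "is_spike_in"]


class SchemaError(ValueError):
    """A table is missing a required column or has an invalid value."""


class ReferentialIntegrityError(ValueError):
    """A Ct row references a sample_id absent from the sample sheet."""


class DuplicationError(ValueError):
    """Duplicate (sample_id, assay) pair in a Ct table."""


class ConfigurationError(ValueError):
    """Invalid panel or exclusion configuration."""


@dataclass(frozen=True)
class PanelConfig:
    """Assay metadata: mutation cutoffs, region list, miRNA panel, Ct ceiling.

    ``mutation_cutoffs`` maps assay_id -> dCt cutoff (a sample is called
    positive when dCt = Ct(mutation) - Ct(reference) is at or below the
    cutoff).  ``spike_in`` names the one exogenous control miRNA; it is never
    part of the analyzed miRNA panel.
    """

    mutation_cutoffs: dict[str, float]
    mutation_genes: dict[str, str]
    methylation_regions: tuple[str, ...]
    mirna_panel: tuple[str, ...]
    spike_in: str
    ct_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if self.spike_in in self.mirna_panel:
            raise ConfigurationError("spike-in must not be listed in the miRNA panel")
        if self.ct_ceiling <= 0:
            raise ConfigurationError("ct_ceiling must be positive")
        missing = set(self.mutation_cutoffs) ^ set(self.mutation_genes)
        if missing:
            raise ConfigurationError(f"cutoff/gene metadata mismatch for assays: {sorted(missing)}")

    @property
    def mutation_assays(self) -> tuple[str, ...]:
        return tuple(sorted(self.mutation_cutoffs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        raw = yaml.safe_load(Path(path).read_text())
        assays = raw.get("mutation_assays", {})
        return cls(
            mutation_cutoffs={a: float(m["delta_ct_cutoff"]) for a, m in assays.items()},
            mutation_genes={a: str(m["gene"]) for a, m in assays.items()},
            methylation_regions=tuple(raw.get("methylation_regions", ())),
            mirna_panel=tuple(raw.get("mirna_panel", ())),
            spike_in=str(raw["spike_in"]),
            ct_ceiling=float(raw.get("ct_ceiling", 40.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "mutation_assays": {
                a: {"gene": self.mutation_genes[a], "delta_ct_cutoff": self.mutation_cutoffs[a]}
                for a in self.mutation_assays
            },
            "methylation_regions": list(self.methylation_regions),
            "mirna_panel": list(self.mirna_panel),
            "spike_in": self.spike_in,
            "ct_ceiling": self.ct_ceiling,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass(frozen=True)
class ExclusionRules:
    """Declarative sample-exclusion rules applied before analysis."""

    drop_samples: dict[str, str] = field(default_factory=dict)  # sample_id -> reason
    drop_groups: tuple[str, ...] = ()
    min_group_size: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExclusionRules":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            drop_samples=dict(raw.get("drop_samples", {})),
            drop_groups=tuple(raw.get("drop_groups", ())),
            min_group_size=raw.get("min_group_size"),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "drop_samples": dict(self.drop_samples),
            "drop_groups": list(self.drop_groups),
            "min_group_size": self.min_group_size,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class CohortDataset:
    """A validated cohort: sample sheet + the three Ct tables + panel config."""

    samples: pd.DataFrame
    mutation_cts: pd.DataFrame
    methylation_cts: pd.DataFrame
    mirna_cts: pd.DataFrame
    panel: PanelConfig

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        for df, cols, name in (
            (self.samples, SAMPLE_COLUMNS, "samples"),
            (self.mutation_cts, MUTATION_COLUMNS, "mutations"),
            (self.methylation_cts, METHYLATION_COLUMNS, "methylation"),
            (self.mirna_cts, MIRNA_COLUMNS, "mirna"),
        ):
            for col in cols:
                if col not in df.columns:
                    raise SchemaError(f"{name} table is missing required column '{col}'")

        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DuplicationError(f"duplicate sample_id '{dup}' in sample sheet")
        bad = set(self.samples["group"]) - set(INPUT_GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels: {sorted(bad)}")
        healthy = self.samples["group"] == "healthy"
        if (self.samples.loc[healthy, "stage"] != 0).any():
            raise SchemaError("healthy samples must have stage 0")
        if (self.samples.loc[~healthy, "stage"] == 0).any():
            raise SchemaError("tumor samples must have stage >= 1")

        known = set(ids)
        for df, key, name in (
            (self.mutation_cts, "assay_id", "mutations"),
            (self.methylation_cts, "region", "methylation"),
            (self.mirna_cts, "mirna_id", "mirna"),
        ):
            orphans = set(df["sample_id"]) - known
            if orphans:
                raise ReferentialIntegrityError(
                    f"{name} table references unknown sample_id(s): {sorted(orphans)}"
                )
            pair = df[["sample_id", key]]
            if pair.duplicated().any():
                s, a = pair[pair.duplicated()].iloc[0]
                raise DuplicationError(f"duplicate ({s}, {a}) in {name} table")

    def subset(self, sample_ids: list[str]) -> "CohortDataset":
        """Restrict the cohort to the given samples (order preserved)."""
        keep = set(sample_ids)
        return CohortDataset(
            samples=self.samples[self.samples["sample_id"].isin(keep)].reset_index(drop=True),
            mutation_cts=self.mutation_cts[self.mutation_cts["sample_id"].isin(keep)].reset_index(drop=True),
            methylation_cts=self.methylation_cts[
                self.methylation_cts["sample_id"].isin(keep)
            ].reset_index(drop=True),
            mirna_cts=self.mirna_cts[self.mirna_cts["sample_id"].isin(keep)].reset_index(drop=True),
            panel=self.panel,
        )

    def write(self, outdir: str | Path) -> None:
        """Write the four CSV tables and panel.yaml (full float precision)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "samples.csv", index=False, float_format="%.17g")
        self.mutation_cts.to_csv(outdir / "mutations.csv", index=False, float_format="%.17g")
        self.methylation_cts.to_csv(outdir / "methylation.csv", index=False, float_format="%.17g")
        self.mirna_cts.to_csv(outdir / "mirna.csv", index=False, float_format="%.17g")
        self.panel.to_yaml(outdir / "panel.yaml")


def _parse_ct(series: pd.Series, ceiling: float) -> pd.Series:
    """Coerce a raw Ct column to float with NaN as the undetermined sentinel."""
    def one(v: object) -> float:
        if isinstance(v, str) and v.strip().lower() in UNDETERMINED_STRINGS:
            return np.nan
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        x = float(v)
        if x <= 0:
            raise SchemaError(f"Ct value must be positive, got {x}")
        return np.nan if x >= ceiling else x

    return series.map(one).astype(float)


def read_cohort(
    sample_sheet_path: str | Path,
    mutation_path: str | Path,
    methylation_path: str | Path,
    mirna_path: str | Path,
    panel_config_path: str | Path,
) -> CohortDataset:
    """Read and validate the four cohort tables against a panel config."""
    panel = PanelConfig.from_yaml(panel_config_path)
    samples = pd.read_csv(sample_sheet_path, dtype={"sample_id": str})
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise SchemaError(f"sample sheet is missing required column '{col}'")
    samples["stage"] = samples["stage"].astype(int)

    mut = pd.read_csv(mutation_path, dtype={"sample_id": str}, keep_default_na=False)
    for col in ("ct_mutation", "ct_reference"):
        if col not in mut.columns:
            raise SchemaError(f"mutation table is missing required column '{col}'")
        mut[col] = _parse_ct(mut[col], panel.ct_ceiling)

    meth = pd.read_csv(methylation_path, dtype={"sample_id": str}, keep_default_na=False)
    for col in ("ct_me", "ct_unme"):
        if col not in meth.columns:
            raise SchemaError(f"methylation table is missing required column '{col}'")
        meth[col] = _parse_ct(meth[col], panel.ct_ceiling)
    bad_regions = set(meth.get("region", pd.Series(dtype=str))) - set(panel.methylation_regions)
    if bad_regions:
        raise SchemaError(f"methylation regions not in panel: {sorted(bad_regions)}")

    mirna = pd.read_csv(mirna_path, dtype={"sample_id": str}, keep_default_na=False)
    if "ct" not in mirna.columns:
        raise SchemaError("mirna table is missing required column 'ct'")
    mirna["ct"] = _parse_ct(mirna["ct"], panel.ct_ceiling)
    if "is_spike_in" in mirna.columns:
        mirna["is_spike_in"] = mirna["is_spike_in"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )

    return CohortDataset(samples, mut, meth, mirna, panel)


def apply_exclusions(
    dataset: CohortDataset, rules: ExclusionRules
) -> tuple[CohortDataset, pd.DataFrame]:
    """Apply declarative exclusion rules; return filtered cohort + log.

    The log has columns (sample_id, reason); the retained samples plus the
    logged samples partition the input exactly.
    """
    samples = dataset.samples
    unknown = set(rules.drop_groups) - set(INPUT_GROUPS)
    if unknown:
        raise ConfigurationError(f"exclusion rule references unknown group(s): {sorted(unknown)}")

    log: list[tuple[str, str]] = []
    dropped: set[str] = set()

    for sid, reason in rules.drop_samples.items():
        if sid in set(samples["sample_id"]) and sid not in dropped:
            log.append((sid, reason))
            dropped.add(sid)

    remaining = samples[~samples["sample_id"].isin(dropped)]
    sizes = remaining.groupby("group")["sample_id"].count()
    for group in rules.drop_groups:
        for sid in remaining.loc[remaining["group"] == group, "sample_id"]:
            log.append((sid, f"group '{group}' excluded by rule"))
            dropped.add(sid)
    if rules.min_group_size is not None:
        for group, n in sizes.items():
            if n < rules.min_group_size and group not in rules.drop_groups:
                for sid in remaining.loc[remaining["group"] == group, "sample_id"]:
                    log.append((sid, f"group '{group}' below minimum size {rules.min_group_size} (n={n})"))
                    dropped.add(sid)

    keep = [s for s in samples["sample_id"] if s not in dropped]
    log_df = pd.DataFrame(log, columns=["sample_id", "reason"])
    return dataset.subset(keep), log_df
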