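import numpy as np
import pandas as pd
import pytest

from cfpanel import GeneratorConfig, generate_cohort, preprocess_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (study-shaped, seed 1) plus ground truth."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed(cohort):
    dataset, _ = cohort
    return preprocess_cohort(dataset)


@pytest.fixture(scope="session")
def feature_matrix(preprocessed):
    return preprocessed["feature_matrix"]


@pytest.fixture()
def tiny_cohort_dir(tmp_path):
    """Three-sample cohort written as the on-disk CSV/YAML schema."""
    samples = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "group": ["healthy", "breast", "lung"],
            "stage": [0, 2, 3],
            "age": [50.0, 61.5, 70.0],
            "sex": ["female", "female", "male"],
            "bmi": [24.0, 27.1, 22.3],
            "cfdna_conc": [0.5, 1.2, 2.4],
        }
    )
    mutations = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S1", "S2", "S3"],
            "assay_id": ["A1", "A1", "A1", "A2", "A2", "A2"],
            "gene": ["TP53"] * 3 + ["KRAS"] * 3,
            "ct_mutation": [np.nan, 30.0, 33.0, 35.0, np.nan, 29.0],
            "ct_reference": [27.0, 26.5, 27.2, 27.0, 26.5, 27.2],
        }
    )
    methylation = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "region": ["MLH1"] * 3,
            "ct_me": [26.0, 25.0, 24.5],
            "ct_unme": [25.0, 25.0, 26.0],
        }
    )
    mirna = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S1", "S2", "S2", "S2", "S3", "S3", "S3"],
            "mirna_id": ["miR-a", "miR-b", "spike"] * 3,
            "ct": [29.0, 31.0, 22.0, 28.0, 30.0, 22.1, 27.5, 33.0, 21.9],
            "is_spike_in": [False, False, True] * 3,
        }
    )
    panel = "\n".join(
        [
            "mutation_assays:",
            "  A1: {gene: TP53, delta_ct_cutoff: 8.0}",
            "  A2: {gene: KRAS, delta_ct_cutoff: 8.0}",
            "methylation_regions: [MLH1]",
            "mirna_panel: [miR-a, miR-b]",
            "spike_in: spike",
            "ct_ceiling: 40.0",
        ]
    )
    samples.to_csv(tmp_path / "samples.csv", index=False)
    mutations.to_csv(tmp_path / "mutations.csv", index=False)
    methylation.to_csv(tmp_path / "methylation.csv", index=False)
    mirna.to_csv(tmp_path / "mirna.csv", index=False)
    (tmp_path / "panel.yaml").write_text(panel)
    return tmp_path
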