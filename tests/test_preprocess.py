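"""Ct preprocessing: dCt, mutation calls, methylation %, miRNA normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfpanel import (
    DetectionPolicy,
    assemble_feature_matrix,
    call_mutation,
    compute_delta_ct,
    drop_undetected_mirnas,
    global_mean_normalize,
    methylation_percent,
    mutation_burden,
    standardize_zscores,
)
from cfpanel.preprocess import (
    DegeneratePanelError,
    InputDomainError,
    mutation_call_table,
    mutation_calls_wide,
)

cts = st.floats(min_value=1.0, max_value=39.0, allow_nan=False)


class TestDeltaCt:
    @pytest.mark.parametrize(
        "ct_mut,ct_ref,expected",
        [(30.0, 25.0, 5.0), (25.0, 25.0, 0.0), (24.0, 30.0, -6.0)],
    )
    def test_subtraction(self, ct_mut, ct_ref, expected):
        assert compute_delta_ct(ct_mut, ct_ref) == pytest.approx(expected)

    def test_undetermined_propagates(self):
        assert np.isnan(compute_delta_ct(np.nan, 25.0))
        assert np.isnan(compute_delta_ct(30.0, np.nan))

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(InputDomainError):
            compute_delta_ct(-1.0, 25.0)


class TestMutationCall:
    @pytest.mark.parametrize(
        "delta,cutoff,expected",
        [(5.0, 8.0, True), (9.5, 8.0, False), (8.0, 8.0, True), (np.nan, 8.0, False)],
    )
    def test_cutoff_rule(self, delta, cutoff, expected):
        assert call_mutation(delta, cutoff) is expected

    @given(delta=st.floats(-10, 10, allow_nan=False), shift=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_delta_ct(self, delta, shift):
        # lowering dCt never flips a positive call to negative
        if call_mutation(delta, 8.0):
            assert call_mutation(delta - shift, 8.0)

    def test_burden_counts_positives(self):
        calls = pd.DataFrame(
            {"sample_id": ["S1"] * 3 + ["S2"] * 3,
             "assay_id": ["A", "B", "C"] * 2,
             "positive": [True, False, True, False, False, False]}
        )
        burden = mutation_burden(calls)
        assert burden["S1"] == 2 and burden["S2"] == 0


class TestMethylationPercent:
    @pytest.mark.parametrize(
        "ct_me,ct_unme,expected",
        [
            (25.0, 25.0, 50.0),
            (24.0, 25.0, 100.0 / (1.0 + 0.5)),  # 66.666..., one cycle less = 2x more
            (30.0, 25.0, 100.0 / (1.0 + 32.0)),  # 3.0303...
        ],
    )
    def test_closed_form(self, ct_me, ct_unme, expected):
        assert methylation_percent(ct_me, ct_unme) == pytest.approx(expected, rel=1e-12)

    def test_undetermined_gives_absent_not_zero(self):
        assert np.isnan(methylation_percent(np.nan, 25.0))

    @given(a=cts, b=cts)
    @settings(max_examples=100, deadline=None)
    def test_complement_symmetry_and_bounds(self, a, b):
        m1, m2 = methylation_percent(a, b), methylation_percent(b, a)
        assert 0.0 < m1 < 100.0
        assert m1 + m2 == pytest.approx(100.0, abs=1e-9)

    @given(a=cts, b=cts, eps=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_strict_monotonicity(self, a, b, eps):
        assert methylation_percent(a + eps, b) < methylation_percent(a, b)
        assert methylation_percent(a, b + eps) > methylation_percent(a, b)


def _mirna_table(ct_by_sample: dict[str, list[float]], mirnas=None):
    rows = []
    for sid, cts_ in ct_by_sample.items():
        names = mirnas or [f"m{i}" for i in range(len(cts_))]
        for m, ct in zip(names, cts_):
            rows.append((sid, m, ct, False))
        rows.append((sid, "spike", 22.0, True))
    return pd.DataFrame(rows, columns=["sample_id", "mirna_id", "ct", "is_spike_in"])


class TestMiRnaNormalization:
    def test_equal_cts_give_zero(self):
        rel, flagged = global_mean_normalize(_mirna_table({"S1": [30.0, 30.0, 30.0]}))
        assert np.allclose(rel.loc["S1"], 0.0) and not flagged

    def test_signed_deviation_from_mean(self):
        rel, _ = global_mean_normalize(_mirna_table({"S1": [29.0, 31.0]}))
        assert rel.loc["S1"].tolist() == pytest.approx([1.0, -1.0])

    @given(st.lists(cts, min_size=3, max_size=10), st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_per_sample_mean_zero_and_plate_shift_invariance(self, values, shift):
        rel, _ = global_mean_normalize(_mirna_table({"S1": values}))
        assert rel.loc["S1"].mean() == pytest.approx(0.0, abs=1e-9)
        shifted, _ = global_mean_normalize(_mirna_table({"S1": [v + shift for v in values]}))
        assert np.allclose(rel.loc["S1"], shifted.loc["S1"], atol=1e-9)

    def test_sample_with_one_detected_mirna_flagged(self):
        rel, flagged = global_mean_normalize(
            _mirna_table({"S1": [30.0, np.nan, np.nan], "S2": [29.0, 30.0, 31.0]})
        )
        assert flagged == ["S1"] and list(rel.index) == ["S2"]


class TestDetectionFilter:
    def test_47_candidates_4_flagged_43_retained(self, cohort):
        dataset, _ = cohort
        kept, log = drop_undetected_mirnas(dataset.mirna_cts)
        retained = kept[~kept["is_spike_in"]]["mirna_id"].nunique()
        assert retained == 43 and len(log) == 4

    def test_no_flags_identity(self):
        table = _mirna_table({"S1": [28.0, 29.0], "S2": [30.0, 31.0]})
        kept, log = drop_undetected_mirnas(table)
        assert len(log) == 0 and kept.equals(table.reset_index(drop=True))

    def test_spike_in_never_a_candidate(self):
        table = _mirna_table({"S1": [np.nan, 29.0], "S2": [np.nan, 31.0]})
        kept, log = drop_undetected_mirnas(table)
        assert set(log["mirna_id"]) == {"m0"}
        assert kept["is_spike_in"].any()  # spike-in retained

    def test_all_excluded_raises(self):
        table = _mirna_table({"S1": [np.nan, np.nan], "S2": [np.nan, np.nan]})
        with pytest.raises(DegeneratePanelError):
            drop_undetected_mirnas(table)

    def test_reference_sample_policy(self):
        table = _mirna_table({"REF": [np.nan, 29.0], "S2": [28.0, 31.0]})
        kept, log = drop_undetected_mirnas(
            table, DetectionPolicy(mode="reference", reference_sample="REF")
        )
        assert set(log["mirna_id"]) == {"m0"}


class TestZScores:
    def test_hand_check_n_minus_1(self):
        z, flagged = standardize_zscores(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        assert z["f"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert not flagged

    def test_constant_feature_flagged(self):
        z, flagged = standardize_zscores(pd.DataFrame({"f": [2.0, 2.0, 2.0], "g": [1.0, 2.0, 4.0]}))
        assert flagged == ["f"] and list(z.columns) == ["g"]

    def test_normalization_identity(self, preprocessed):
        z = preprocessed["mirna_zscores"]
        assert np.allclose(z.mean(axis=0, skipna=True), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)


class TestAssembly:
    def test_complete_blocks_assemble(self):
        idx = ["S1", "S2", "S3"]
        fm = assemble_feature_matrix(
            pd.DataFrame({"A": [1, 0, 1], "B": [0, 0, 1]}, index=idx),
            pd.DataFrame({"MLH1": [40.0, 55.0, 60.0]}, index=idx),
            pd.DataFrame({"m1": [-1.0, 0.0, 1.0], "m2": [1.0, 0.0, -1.0]}, index=idx),
        )
        assert fm.values.shape == (3, 5)
        assert fm.classes["A"] == "mutation" and fm.classes["m1"] == "mirna"

    def test_missing_cell_drops_column_with_log(self):
        idx = ["S1", "S2", "S3"]
        fm = assemble_feature_matrix(
            pd.DataFrame({"A": [1, 0, 1]}, index=idx),
            pd.DataFrame({"MLH1": [40.0, np.nan, 60.0]}, index=idx),
            pd.DataFrame({"m1": [-1.0, 0.0, 1.0]}, index=idx),
        )
        assert "MLH1" not in fm.values.columns
        assert ("MLH1" == fm.drop_log["feature_id"]).any()

    def test_duplicate_feature_id_raises(self):
        idx = ["S1", "S2"]
        with pytest.raises(ValueError, match="X"):
            assemble_feature_matrix(
                pd.DataFrame({"X": [1, 0]}, index=idx),
                pd.DataFrame({"X": [40.0, 50.0]}, index=idx),
                pd.DataFrame({"m": [1.0, -1.0]}, index=idx),
            )

    def test_column_accounting_on_full_cohort(self, cohort, preprocessed):
        dataset, _ = cohort
        fm = preprocessed["feature_matrix"]
        calls = mutation_calls_wide(mutation_call_table(dataset.mutation_cts, dataset.panel))
        n_input = calls.shape[1] + preprocessed["methylation"].shape[1] + \
            preprocessed["mirna_zscores"].shape[1]
        assert fm.values.shape[1] == n_input - len(fm.drop_log)
        # 75 assays minus 7 never-amplifying = 68 mutation columns survive
        assert len(fm.features_of_class("mutation")) == 68
        assert len(fm.features_of_class("methylation")) == 12
        assert len(fm.features_of_class("mirna")) == 43
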