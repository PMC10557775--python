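"""Gene categorization rules, subset export, and the three-round heatmap
normalization."""

import numpy as np
import pandas as pd
import pytest

from circadiff import ExpressionTimeCourse, SimConfig, categorize, export_subsets, heatmap_normalize, simulate_expression
from circadiff.report import LOG2_10, SUBSET_NAMES, subset_membership


def _mini_tables():
    """Small hand-built diff/weights tables covering every category."""
    genes = ["loss", "gain", "delay", "advance", "up", "down", "quiet", "none"]
    diff = pd.DataFrame(
        {
            "mesor_diff":   [0.0, 0.0, 0.0, 0.0, 0.4, -0.4, 0.0, 0.3],
            "q_mesor_diff": [0.01, 0.5, 0.5, 0.5, 0.01, 0.01, 0.5, 0.5],
            "amp_diff":     [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.2],
            "q_amp_diff":   [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            "phase_diff":   [0.0, 0.0, 1.2, -1.2, 0.0, 0.0, 0.0, 2.0],
            "q_phase_diff": [0.5, 0.5, 0.01, 0.01, 0.5, 0.5, 0.5, 0.5],
            "amp_young":    [0.5, 0.0, 0.5, 0.5, 0.5, 0.5, 0.0, 0.5],
            "amp_old":      [0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0, 0.5],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    weights = pd.DataFrame(
        {
            "assigned_class": [
                "YOUNG_ONLY", "OLD_ONLY", "BOTH", "BOTH", "BOTH", "BOTH",
                "NEITHER", "BOTH",
            ]
        },
        index=diff.index.copy(),
    )
    return diff, weights


class TestCategorize:
    def test_weight_classes_drive_loss_and_gain(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        members = subset_membership(rec)
        assert members["loss_of_rhythmicity"] == ["loss"]
        assert members["gain_of_rhythmicity"] == ["gain"]
        assert set(members["rhythmic_in_both"]) == {"delay", "advance", "up", "down", "none"}

    def test_phase_sign_convention(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        assert rec.loc["delay", "phase_change"] == "DELAY"
        assert rec.loc["advance", "phase_change"] == "ADVANCE"

    def test_mesor_direction_and_log2fc(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        assert rec.loc["up", "mesor_change"] == "UP"
        assert rec.loc["down", "mesor_change"] == "DOWN"
        assert rec.loc["up", "mesor_log2fc"] == pytest.approx(0.4 * LOG2_10)
        assert rec.loc["up", "passes_mesor_fc_filter"]  # 1.33 > 0.25

    def test_nonsignificant_both_gene_has_no_change_calls(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        assert rec.loc["none", ["mesor_change", "amp_change", "phase_change"]].tolist() == ["NONE"] * 3

    def test_change_fields_none_unless_rhythmic_in_both(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        # 'loss' has q_mesor < cutoff but is not BOTH-class
        assert rec.loc["loss", "mesor_change"] == "NONE"

    def test_category_partition_exclusive_and_exhaustive(self):
        diff, weights = _mini_tables()
        rec = categorize(diff, weights)
        classes = {"BOTH", "YOUNG_ONLY", "OLD_ONLY", "NEITHER", "UNCLASSIFIED"}
        assert set(rec["rhythm_class"]).issubset(classes)
        counts = rec["rhythm_class"].value_counts()
        assert counts.sum() == len(rec)

    def test_raising_q_cut_never_shrinks_change_sets(self):
        etc, _ = simulate_expression(SimConfig(n_genes=300, mesor_shift_sd=0.2, seed=15))
        from circadiff import classify_matrix, diff_rhythm_table

        diff = diff_rhythm_table(etc)
        weights = classify_matrix(etc)
        tight = subset_membership(categorize(diff, weights, q_cut=0.01))
        loose = subset_membership(categorize(diff, weights, q_cut=0.20))
        for name in ("decreased_mesor", "increased_mesor", "phase_advance", "phase_delay"):
            assert set(tight[name]).issubset(set(loose[name]))

    def test_mismatched_gene_universe_rejected(self):
        diff, weights = _mini_tables()
        with pytest.raises(ValueError, match="gene universe"):
            categorize(diff, weights.iloc[:3])


class TestExportSubsets:
    def test_empty_records_give_seven_empty_files(self, tmp_path):
        diff, weights = _mini_tables()
        rec = categorize(diff.iloc[:0], weights.iloc[:0])
        members = export_subsets(rec, tmp_path)
        assert set(members) == set(SUBSET_NAMES)
        for name in SUBSET_NAMES:
            assert (tmp_path / f"{name}.txt").read_text() == ""

    def test_files_match_independent_refilter(self, tmp_path):
        etc, _ = simulate_expression(SimConfig(n_genes=400, mesor_shift_sd=0.3, seed=23))
        from circadiff import classify_matrix, diff_rhythm_table

        diff = diff_rhythm_table(etc)
        weights = classify_matrix(etc)
        rec = categorize(diff, weights)
        export_subsets(rec, tmp_path)
        # independent second-pass filter straight from the two tables
        both = weights["assigned_class"] == "BOTH"
        expected = {
            "loss_of_rhythmicity": set(weights.index[weights["assigned_class"] == "YOUNG_ONLY"]),
            "gain_of_rhythmicity": set(weights.index[weights["assigned_class"] == "OLD_ONLY"]),
            "rhythmic_in_both": set(weights.index[both]),
            "decreased_mesor": set(diff.index[both & (diff["q_mesor_diff"] < 0.05) & (diff["mesor_diff"] < 0)]),
            "increased_mesor": set(diff.index[both & (diff["q_mesor_diff"] < 0.05) & (diff["mesor_diff"] > 0)]),
            "phase_advance": set(diff.index[both & (diff["q_phase_diff"] < 0.05) & (diff["phase_diff"] < 0)]),
            "phase_delay": set(diff.index[both & (diff["q_phase_diff"] < 0.05) & (diff["phase_diff"] > 0)]),
        }
        for name in SUBSET_NAMES:
            lines = (tmp_path / f"{name}.txt").read_text().splitlines()
            assert len(lines) == len(set(lines)), f"duplicates in {name}"
            assert set(lines) == expected[name], name


def _one_group_etc(values_by_subject, timepoints=(1.0, 2.0, 3.0), group="young"):
    cols, data, rows = [], [], []
    samples = {"group": [], "subject": [], "time_h": []}
    for subj, _ in values_by_subject.items():
        for t in timepoints:
            cols.append(f"{group}_{subj}_{t:g}")
            samples["group"].append(group)
            samples["subject"].append(subj)
            samples["time_h"].append(t)
    mat = np.hstack([np.asarray(v, float) for v in values_by_subject.values()])
    values = pd.DataFrame(np.atleast_2d(mat), columns=cols)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    sheet = pd.DataFrame(samples, index=pd.Index(cols, name="sample_id"))
    return ExpressionTimeCourse(values=values, samples=sheet)


class TestHeatmapNormalize:
    def test_hand_computed_fixture(self):
        """2 genes x 2 subjects x 3 timepoints, worked by hand:

        gene g0: s1 = (1,2,3), s2 = (2,4,6)
          round 1 -> both (0.5, 1, 1.5); round 2 -> (0.5, 1, 1.5);
          round 3 (sd ddof=1 = 0.5) -> (-1, 0, 1)
        gene g1: s1 = (3,3,3) -> (1,1,1); s2 = (1,3,2) -> (0.5, 1.5, 1)
          round 2 -> (0.75, 1.25, 1); round 3 (sd 0.25) -> (-1, 1, 0)
        """
        etc = _one_group_etc({
            "s1": [[1.0, 2.0, 3.0], [3.0, 3.0, 3.0]],
            "s2": [[2.0, 4.0, 6.0], [1.0, 3.0, 2.0]],
        })
        norm, flags = heatmap_normalize(etc)
        np.testing.assert_allclose(norm.loc["g0"], [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(norm.loc["g1"], [-1.0, 1.0, 0.0], atol=1e-12)
        assert not flags.any().any()

    def test_postconditions_on_random_matrix(self):
        etc, _ = simulate_expression(SimConfig(n_genes=50, seed=31))
        norm, flags = heatmap_normalize(etc)
        assert norm.shape == (50, 28)  # one column per (group, timepoint)
        for group in ("young", "old"):
            block = norm.loc[:, [c for c in norm.columns if c.startswith(group)]]
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-10)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_gene_flagged_and_zeroed(self, study_design):
        etc, _ = simulate_expression(SimConfig(n_genes=2, seed=1))
        etc.values.iloc[0] = 7.0
        norm, flags = heatmap_normalize(etc)
        np.testing.assert_allclose(norm.iloc[0], 0.0)
        assert flags["zero_sd"].iloc[0]

    def test_round3_idempotent(self):
        etc, _ = simulate_expression(SimConfig(n_genes=20, seed=33))
        norm, _ = heatmap_normalize(etc)
        for group in ("young", "old"):
            block = norm.loc[:, [c for c in norm.columns if c.startswith(group)]].to_numpy()
            rez = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, ddof=1, keepdims=True)
            np.testing.assert_allclose(rez, block, atol=1e-10)
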