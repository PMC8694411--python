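"""Outcome summaries, accuracies, filters, grid and subset retraining."""

from __future__ import annotations

import numpy as np
import pytest

from soilmfc import (
    Classification,
    ConfusionSummary,
    GeneratorConfig,
    GridSetting,
    ModelResult,
    confusion_by_class,
    default_grid,
    filter_models,
    general_accuracy,
    identified_accuracy,
    results_table,
    run_grid,
    simulate_experiment,
    subset_experiment,
    summarize,
)

# Published per-model outcome rows: (CI, CU, II, IU, Unknown, AccAll, AccID).
# Blank printed cells are 0.  Used to validate the accuracy formulas against
# every fully printed row (both published rankings, duplicates removed).
PUBLISHED_ROWS = [
    (69.1, 0.0, 2.4, 0.0, 28.5, 96.6, 96.6),
    (69.1, 4.1, 2.4, 0.8, 23.6, 95.7, 96.6),
    (69.1, 3.3, 2.4, 1.6, 23.6, 94.7, 96.6),
    (70.1, 0.0, 4.2, 0.0, 25.8, 94.4, 94.4),
    (72.7, 0.0, 6.3, 0.0, 21.0, 92.0, 92.0),
    (70.1, 7.2, 4.2, 3.6, 15.0, 90.9, 94.4),
    (72.7, 0.0, 7.7, 0.0, 19.6, 90.4, 90.4),
    (70.1, 6.6, 4.2, 4.2, 15.0, 90.1, 94.4),
    (68.3, 8.1, 8.9, 0.8, 13.8, 88.7, 88.4),
    (68.3, 0.0, 0.0, 8.9, 22.8, 88.4, 100.0),
    (25.2, 52.7, 0.0, 22.2, 0.0, 77.8, 100.0),
    (29.3, 49.7, 0.6, 20.4, 0.0, 79.0, 98.0),
    (32.5, 43.1, 1.6, 22.8, 0.0, 75.6, 95.2),
]


def make_preds(spec: list[tuple[str | None, str]]) -> list[Classification]:
    return [Classification(label, conf, [], "dominant") for label, conf in spec]


class TestSummarize:
    def test_all_correct_identified(self):
        preds = make_preds([("A", "Identified")] * 4)
        s = summarize(preds, ["A"] * 4)
        assert s.counts == (4, 0, 0, 0, 0)
        assert s.pct_correct_identified == 100.0

    def test_all_unknown(self):
        preds = make_preds([(None, "Unknown")] * 3)
        s = summarize(preds, ["A"] * 3)
        assert s.pct_unknown == 100.0

    def test_mixed_hand_tally(self):
        """Ten hand-built outcomes across all five bins."""
        spec = [
            ("A", "Identified"), ("A", "Identified"), ("B", "Identified"),
            ("A", "Uncertain"), ("B", "Uncertain"), ("B", "Uncertain"),
            (None, "Unknown"), (None, "Unknown"),
            ("A", "Identified"), ("B", "Uncertain"),
        ]
        truths = ["A", "A", "A", "A", "A", "B", "A", "B", "B", "B"]
        s = summarize(make_preds(spec), truths)
        assert s.counts == (2, 3, 2, 1, 2)
        assert s.n_test == 10
        total = (s.pct_correct_identified + s.pct_correct_unclear
                 + s.pct_incorrect_identified + s.pct_incorrect_unclear + s.pct_unknown)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            summarize(make_preds([("A", "Identified")]), ["A", "B"])


class TestAccuracyFormulas:
    def test_flagship_row_reproduces_exactly(self):
        s = ConfusionSummary.from_percentages(69.1, 0.0, 2.4, 0.0, 28.5)
        assert round(general_accuracy(s), 1) == 96.6
        assert round(identified_accuracy(s), 1) == 96.6

    def test_unanimous_5pt_row(self):
        s = ConfusionSummary.from_percentages(72.7, 0.0, 6.3, 0.0, 21.0)
        assert round(general_accuracy(s), 1) == 92.0

    def test_perfect_identified_accuracy_row(self):
        s = ConfusionSummary.from_percentages(68.3, 0.0, 0.0, 8.9, 22.8)
        assert identified_accuracy(s) == 100.0

    @pytest.mark.parametrize("ci,cu,ii,iu,unk,acc_all,acc_id", PUBLISHED_ROWS)
    def test_every_printed_row_within_rounding(self, ci, cu, ii, iu, unk, acc_all, acc_id):
        """Both accuracies recomputed from each published row's cells agree
        with the printed accuracy columns within the +/-0.2 rounding budget."""
        s = ConfusionSummary.from_percentages(ci, cu, ii, iu, unk)
        assert general_accuracy(s) == pytest.approx(acc_all, abs=0.2)
        assert identified_accuracy(s) == pytest.approx(acc_id, abs=0.2)

    def test_equal_correct_incorrect_is_fifty(self):
        s = ConfusionSummary.from_percentages(25.0, 0.0, 25.0, 0.0, 50.0)
        assert identified_accuracy(s) == 50.0

    def test_all_unknown_undefined(self):
        s = ConfusionSummary.from_percentages(0.0, 0.0, 0.0, 0.0, 100.0)
        with pytest.raises(ValueError):
            general_accuracy(s)
        with pytest.raises(ValueError):
            identified_accuracy(s)

    def test_percentages_must_sum_to_100(self):
        with pytest.raises(ValueError):
            ConfusionSummary.from_percentages(50.0, 0.0, 0.0, 0.0, 30.0)


class TestFilters:
    def make_result(self, ci, cu, ii, iu, unk):
        s = ConfusionSummary.from_percentages(ci, cu, ii, iu, unk)
        try:
            ga = general_accuracy(s)
        except ValueError:
            ga = None
        try:
            ia = identified_accuracy(s)
        except ValueError:
            ia = None
        return ModelResult(GridSetting(6, "all", "RBF", "dominant"), s, ga, ia)

    def test_excess_unknowns_excluded(self):
        out = filter_models([self.make_result(20.0, 10.0, 5.0, 3.5, 61.5)])
        assert out[0].excluded
        assert "Unknown" in out[0].reason

    def test_boundary_unknowns_retained(self):
        out = filter_models([self.make_result(30.0, 10.0, 5.0, 5.0, 50.0)])
        assert not out[0].excluded

    def test_low_identified_share_excluded(self):
        out = filter_models([self.make_result(20.0, 40.0, 4.9, 25.2, 9.9)])
        assert out[0].excluded
        assert "Identified share" in out[0].reason

    def test_filter_preserves_summaries(self):
        r = self.make_result(20.0, 10.0, 5.0, 3.5, 61.5)
        out = filter_models([r])
        assert out[0].summary is r.summary
        assert not r.excluded  # the input object is untouched

    def test_ranking_by_general_then_identified(self):
        a = self.make_result(60.0, 0.0, 10.0, 0.0, 30.0)   # GA 85.7
        b = self.make_result(66.5, 0.0, 3.5, 0.0, 30.0)    # GA 95.0
        out = filter_models([a, b])
        assert out[0].general_accuracy > out[1].general_accuracy


class TestGrid:
    def test_default_grid_has_120_configurations(self):
        grid = default_grid()
        assert len(grid) == 120
        assert len(set(grid)) == 120
        assert {s.w for s in grid} == {4, 5, 6}
        assert len({s.scheme for s in grid}) == 4
        assert sum(s.method == "KNN" for s in grid) == 60

    def test_restricted_grid_runs_one_model(self, default_experiment):
        settings = [GridSetting(6, "all", "RBF", "unanimous")]
        results = run_grid(default_experiment, settings, seed=1)
        assert len(results) == 1
        assert results[0].summary is not None
        assert results[0].summary.n_test > 0

    def test_grid_is_deterministic(self, default_experiment):
        settings = [
            GridSetting(6, "all", "RBF", "dominant"),
            GridSetting(6, "all", "KNN", "dominant", k=3),
        ]
        r1 = run_grid(default_experiment, settings, seed=4)
        r2 = run_grid(default_experiment, settings, seed=4)
        for a, b in zip(r1, r2):
            assert a.summary.counts == b.summary.counts
            assert a.general_accuracy == b.general_accuracy

    def test_unanimous_is_conservative_on_separated_classes(self):
        """With well-separated treatment signatures, RBF+Unanimous makes no
        Incorrect-Identified calls."""
        offsets = {"control": (0.0, 0.0), "gasoline": (-472.09, 1.65), "urea": (15.7, 7.08)}
        cfg = GeneratorConfig(
            seed=70, treatment_offsets=offsets, sd_a=5.0, sd_b=0.2, sd_eps=2.0,
            variance_scale={t: 1.0 for t in offsets},
        )
        exp = simulate_experiment(cfg)
        results = run_grid(exp, [GridSetting(6, "all", "RBF", "unanimous")], seed=70)
        assert results[0].summary.pct_incorrect_identified == 0.0
        assert results[0].general_accuracy == pytest.approx(100.0)


class TestConfusionByClass:
    def test_perfect_classifier_identity_table(self):
        preds = make_preds([("A", "Identified"), ("B", "Identified")])
        table = confusion_by_class(preds, ["A", "B"])
        assert table.loc["A", "correct"] == 100.0
        assert table.loc["B", "correct"] == 100.0
        assert table.loc["A", "to_B"] == 0.0

    def test_hand_built_tally(self):
        spec = [
            ("A", "Identified"), ("B", "Identified"), (None, "Unknown"),
            ("A", "Identified"), ("C", "Uncertain"), ("A", "Identified"),
            ("B", "Identified"), ("B", "Uncertain"), (None, "Unknown"),
            ("C", "Identified"), ("C", "Identified"), ("A", "Uncertain"),
        ]
        truths = ["A", "A", "A", "A", "A", "A", "B", "B", "B", "C", "C", "C"]
        table = confusion_by_class(make_preds(spec), truths)
        assert table.loc["A", "correct"] == pytest.approx(100 * 3 / 6)
        assert table.loc["A", "to_B"] == pytest.approx(100 * 1 / 6)
        assert table.loc["A", "to_C"] == pytest.approx(100 * 1 / 6)
        assert table.loc["A", "unknown"] == pytest.approx(100 * 1 / 6)
        assert table.loc["B", "correct"] == pytest.approx(100 * 2 / 3)
        assert table.loc["C", "to_A"] == pytest.approx(100 * 1 / 3)

    def test_lookalike_treatments_confuse_each_other(self, default_experiment):
        """Control and DNT share nearly identical generating lines, so their
        mutual confusion exceeds control's confusion with urea."""
        from soilmfc import build_dataset, classify_dataset, split, train_rbf

        ds = build_dataset(default_experiment, 6)
        train, test = split(ds, 0.2, seed=9)
        model = train_rbf(train, shuffle_seed=9)
        preds = classify_dataset(model, test, interpreter="dominant")
        table = confusion_by_class(preds, test.labels())
        control_dnt = table.loc["control", "to_DNT"] + table.loc["DNT", "to_control"]
        control_urea = table.loc["control", "to_urea"] + table.loc["urea", "to_control"]
        assert control_dnt > control_urea


class TestSubsetExperiment:
    def test_empty_drop_is_identity(self, default_experiment):
        out = subset_experiment(default_experiment, set())
        assert out.n_tmfc == default_experiment.n_tmfc

    def test_drop_to_single_label_rejected(self, default_experiment):
        labels = set(default_experiment.treatments)
        with pytest.raises(ValueError):
            subset_experiment(default_experiment, labels - {"control"})

    def test_removing_lookalikes_improves_accuracy(self, default_experiment):
        """Retraining without DNT and petroleum (the classes overlapping the
        control) raises the best General Accuracy."""
        settings = [
            GridSetting(6, "all", "RBF", "unanimous"),
            GridSetting(6, "all", "RBF", "dominant"),
            GridSetting(6, "all", "KNN", "dominant", k=3),
        ]
        full = run_grid(default_experiment, settings, seed=12)
        sub = run_grid(
            subset_experiment(default_experiment, {"DNT", "petroleum"}),
            settings, seed=12,
        )
        best = lambda rs: max(r.general_accuracy for r in rs if r.general_accuracy)
        assert best(sub) >= best(full)


class TestResultsTable:
    def test_table_mirrors_published_layout(self, default_experiment):
        settings = [
            GridSetting(5, "raw", "RBF", "min_consensus", min_consensus=2),
            GridSetting(4, "control", "KNN", "dominant", k=10),
        ]
        table = results_table(run_grid(default_experiment, settings, seed=2))
        assert list(table.columns[:4]) == ["#pts", "Standard.", "Method", "Interpreter"]
        assert set(table["Interpreter"]) <= {"D", "BM", "U", "MC-2", "MC-3"}
        assert "KNN-10" in set(table["Method"])
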