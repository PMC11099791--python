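"""Density-grid training, cell labeling, rolling votes, confusion
matrices."""

import numpy as np
import pytest

from exitblock.core import CLASS_ORDER, Diagnosis, RRSeries, extract_triples
from exitblock.grid import (
    NO_DECISION,
    OUTSIDE,
    GridModel,
    cell_index,
    classify_series,
    classify_triple,
    confusion_matrix,
    train_grid,
)


class TestCellIndex:
    def test_origin(self):
        assert cell_index((0.0, 0.0, 0.0)) == (0, 0, 0)

    def test_floor_division(self):
        # intervals from a published exit-block example
        assert cell_index((660.0, 2633.0, 1336.0)) == (11, 43, 22)

    def test_upper_bound_is_half_open(self):
        assert cell_index((6000.0, 100.0, 100.0)) is OUTSIDE

    def test_negative_outside(self):
        assert cell_index((-1.0, 100.0, 100.0)) is OUTSIDE


def _tiny_cohort():
    return [
        (RRSeries(np.array([600.0] * 4)), Diagnosis.BALANCED),
        (RRSeries(np.array([900.0] * 5)), Diagnosis.HPLSM),
        (RRSeries(np.array([300.0, 1200.0, 300.0, 1200.0])), Diagnosis.SND),
    ]


class TestTrainGrid:
    def test_identical_triples_accumulate_in_one_cell(self):
        model = train_grid(_tiny_cohort())
        flat = model.flatten((10, 10, 10))
        assert model.counts[flat][Diagnosis.BALANCED.value] == 2

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValueError, match="SND"):
            train_grid(_tiny_cohort()[:2])

    def test_empty_recording_contributes_nothing(self):
        cohort = _tiny_cohort() + [(RRSeries(np.array([])), Diagnosis.SND)]
        a = train_grid(_tiny_cohort())
        b = train_grid(cohort)
        np.testing.assert_array_equal(a.class_totals, b.class_totals)

    def test_conservation_per_class(self, train_cohort, grid_model):
        """Sum of cell counts plus outside tally equals the triples
        presented for each class."""
        presented = np.zeros(3, dtype=np.int64)
        for series, label in train_cohort:
            presented[label.value] += extract_triples(series).shape[0]
        cell_sums = np.sum(list(grid_model.counts.values()), axis=0)
        np.testing.assert_array_equal(cell_sums + grid_model.outside_counts, presented)
        np.testing.assert_array_equal(grid_model.class_totals + grid_model.outside_counts,
                                      presented)


class TestClassifyTriple:
    def test_single_class_cell(self):
        model = train_grid(_tiny_cohort())
        assert classify_triple(model, (600.0, 600.0, 600.0)) is Diagnosis.BALANCED

    def test_empty_cell_abstains(self):
        model = train_grid(_tiny_cohort())
        assert classify_triple(model, (5000.0, 5000.0, 5000.0)) is NO_DECISION

    def test_outside_abstains(self):
        model = train_grid(_tiny_cohort())
        assert classify_triple(model, (6500.0, 600.0, 600.0)) is NO_DECISION

    def test_normalized_density_beats_raw_count(self):
        """10/1000 balanced vs 5/100 SND: the minority class with the
        higher per-class density owns the cell."""
        model = GridModel(class_totals=np.array([1000, 1, 100]))
        flat = model.flatten((10, 10, 10))
        model.counts[flat] = np.array([10, 0, 5])
        assert classify_triple(model, (630.0, 630.0, 630.0)) is Diagnosis.SND
        model.normalized = False
        assert classify_triple(model, (630.0, 630.0, 630.0)) is Diagnosis.BALANCED


class TestClassifySeries:
    def test_unanimous_votes(self):
        model = train_grid(_tiny_cohort())
        result = classify_series(model, RRSeries(np.array([600.0] * 10)))
        assert all(c is Diagnosis.BALANCED for c in result.interval_classes)
        assert result.fractions[Diagnosis.BALANCED] == 1.0
        assert result.diagnosis is Diagnosis.BALANCED

    def test_plurality_vote_with_disagreement(self):
        # alternating series crosses cells of two classes; every
        # interval still receives exactly one assignment
        model = train_grid(_tiny_cohort())
        result = classify_series(model, RRSeries(np.array([600.0, 900.0] * 4)))
        assert len(result.interval_classes) == 8
        assert sum(result.fractions.values()) == pytest.approx(1.0)

    def test_unseen_region_yields_no_decision(self):
        model = train_grid(_tiny_cohort())
        result = classify_series(model, RRSeries(np.array([4000.0] * 5)))
        assert all(c is NO_DECISION for c in result.interval_classes)
        assert result.fractions[NO_DECISION] == 1.0

    def test_requires_three_intervals(self):
        model = train_grid(_tiny_cohort())
        with pytest.raises(ValueError):
            classify_series(model, RRSeries(np.array([600.0, 600.0])))

    def test_class_relabeling_permutes_predictions(self):
        """Swapping two classes' training labels swaps the predicted
        diagnoses accordingly."""
        swap = {
            Diagnosis.BALANCED: Diagnosis.SND,
            Diagnosis.SND: Diagnosis.BALANCED,
            Diagnosis.HPLSM: Diagnosis.HPLSM,
        }
        cohort = _tiny_cohort()
        swapped = [(s, swap[d]) for s, d in cohort]
        m1, m2 = train_grid(cohort), train_grid(swapped)
        probe = RRSeries(np.array([600.0] * 6))
        assert classify_series(m2, probe).diagnosis is swap[classify_series(m1, probe).diagnosis]

    def test_heldout_hplsm_recording_diagnosed_hplsm(self, grid_model, test_cohort):
        series, label = next((s, d) for s, d in test_cohort if d is Diagnosis.HPLSM)
        assert classify_series(grid_model, series).diagnosis is Diagnosis.HPLSM


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        labels = [d for d in CLASS_ORDER for _ in range(5)]
        np.testing.assert_array_equal(confusion_matrix(labels, labels), np.eye(3) * 5)

    def test_all_predicted_balanced_fills_first_row(self):
        actual = [d for d in CLASS_ORDER for _ in range(4)]
        predicted = [Diagnosis.BALANCED] * 12
        mat = confusion_matrix(actual, predicted)
        np.testing.assert_array_equal(mat[0], [4, 4, 4])
        assert mat[1:].sum() == 0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            confusion_matrix([Diagnosis.SND], [])

    def test_column_sums_are_actual_class_sizes(self, grid_model, test_cohort):
        actual = [d for _, d in test_cohort]
        predicted = [classify_series(grid_model, s).diagnosis for s, _ in test_cohort]
        mat = confusion_matrix(actual, predicted)
        np.testing.assert_array_equal(mat.sum(axis=0), [3, 3, 3])


def test_model_json_round_trip(tmp_path, grid_model):
    path = tmp_path / "grid.json"
    grid_model.save(path)
    back = GridModel.load(path)
    assert back.n_cells == grid_model.n_cells
    np.testing.assert_array_equal(back.class_totals, grid_model.class_totals)
    probe = (600.0, 600.0, 600.0)
    assert classify_triple(back, probe) is classify_triple(grid_model, probe)
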