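"""Cross-validation protocol and confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imuact import (
    CLASS_ORDER,
    ConfusionMatrix,
    CVConfig,
    LabeledDataset,
    MetricsReport,
    WindowSpec,
    ablation_delta,
    assign_folds,
    confusion_tallies,
    cross_validate,
    load_reference_ablation,
    load_reference_confusion,
    per_class_recall,
    round_half_up,
    stratified_kfold,
    weighted_average_accuracy,
)


def make_dataset(X, y, groups=None):
    X = np.asarray(X, dtype=float)
    groups = groups if groups is not None else ["S01"] * len(X)
    return LabeledDataset(
        X=X,
        y=np.asarray(y, dtype=object),
        groups=np.asarray(groups, dtype=object),
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        sensor_mode="accel_only",
        window=WindowSpec(),
    )


class TestStratifiedKfold:
    def test_exact_divisibility(self):
        labels = np.repeat(CLASS_ORDER, 10)
        folds = stratified_kfold(labels, n_folds=10, seed=0)
        for f in range(10):
            fold_labels = labels[folds == f]
            assert sorted(fold_labels) == sorted(CLASS_ORDER)

    def test_partition(self):
        labels = np.repeat(CLASS_ORDER, 13)
        folds = stratified_kfold(labels, n_folds=10, seed=1)
        assert folds.min() >= 0 and folds.max() < 10
        assert len(folds) == len(labels)
        assert np.all(folds != -1)

    def test_seeded_determinism(self):
        labels = np.repeat(CLASS_ORDER, 12)
        a = stratified_kfold(labels, 10, seed=5)
        b = stratified_kfold(labels, 10, seed=5)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, stratified_kfold(labels, 10, seed=6))

    def test_small_class_rejected(self):
        labels = ["C1"] * 20 + ["C2"] * 3
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(labels, n_folds=10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(5, 40), min_size=2, max_size=9),
        seed=st.integers(0, 1000),
    )
    def test_per_class_balance_property(self, counts, seed):
        labels = np.concatenate(
            [np.repeat(CLASS_ORDER[i], c) for i, c in enumerate(counts)]
        )
        folds = stratified_kfold(labels, n_folds=5, seed=seed)
        for i, c in enumerate(counts):
            per_fold = [
                np.sum((labels == CLASS_ORDER[i]) & (folds == f)) for f in range(5)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_by_participant_grouping_keeps_groups_whole(self):
        rng = np.random.default_rng(0)
        groups = np.repeat([f"S{i:02d}" for i in range(12)], 20)
        labels = np.array(list(np.tile(CLASS_ORDER, 240 // 9 + 1))[:240], dtype=object)
        folds = assign_folds(labels, groups, CVConfig(n_folds=4, grouping="by_participant"))
        for g in set(groups):
            assert len(set(folds[groups == g])) == 1


class TestConfusionMatrixMetrics:
    def test_reference_recalls_match_published_table(self):
        matrix = load_reference_confusion()
        recalls = per_class_recall(matrix)
        expected = {
            "C2": 92.0, "C3": 90.1, "C4": 91.7, "C5": 100.0,
            "C6": 69.8, "C7": 79.4, "C8": 70.4, "C9": 52.3,
        }
        for c, val in expected.items():
            assert round_half_up(recalls[c]) == pytest.approx(val)
        assert round_half_up(weighted_average_accuracy(matrix)) == pytest.approx(90.2)

    def test_identity_matrix_recall(self):
        matrix = ConfusionMatrix(np.eye(9, dtype=int) * 7)
        assert all(v == 100.0 for v in per_class_recall(matrix).values())
        assert weighted_average_accuracy(matrix) == 100.0

    def test_zero_diagonal_accuracy(self):
        counts = np.ones((9, 9), dtype=int)
        np.fill_diagonal(counts, 0)
        assert weighted_average_accuracy(ConfusionMatrix(counts)) == 0.0

    def test_empty_row_rejected(self):
        counts = np.eye(9, dtype=int)
        counts[3, 3] = 0
        with pytest.raises(ValueError, match="empty"):
            per_class_recall(ConfusionMatrix(counts))

    def test_reference_tallies(self):
        tallies = confusion_tallies(load_reference_confusion())
        assert tallies == {
            "walking_speed": 101,
            "stair_vs_level": 103,
            "brisk_walk_vs_jog": 57,
        }

    def test_csv_round_trip(self, tmp_path):
        matrix = load_reference_confusion()
        path = matrix.to_csv(tmp_path / "cm.csv")
        back = ConfusionMatrix.from_csv(path)
        np.testing.assert_array_equal(back.counts, matrix.counts)


class TestAblationDelta:
    def test_published_columns_reproduce_printed_differences(self):
        table = load_reference_ablation()
        deltas = ablation_delta(table["accel_only"], table["accel_gyro"])
        assert deltas["C7"] == pytest.approx(13.4)
        assert deltas["C1"] == pytest.approx(4.5)
        assert deltas["C3"] == pytest.approx(12.1)
        assert deltas["C5"] == pytest.approx(0.0)
        assert deltas["weighted_average"] == pytest.approx(6.5)

    def test_identical_reports_zero_delta(self):
        table = load_reference_ablation()
        deltas = ablation_delta(table["accel_gyro"], table["accel_gyro"])
        assert all(v == 0.0 for v in deltas.values())

    def test_mismatched_classes_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            ablation_delta({"C1": 1.0}, {"C2": 1.0})


class TestCrossValidate:
    def _separable_dataset(self, rows_per_class=20, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for i, c in enumerate(CLASS_ORDER):
            X.append(rng.normal(loc=10.0 * i, scale=0.1, size=(rows_per_class, 3)))
            y.extend([c] * rows_per_class)
        return make_dataset(np.vstack(X), y)

    def test_separable_dataset_gives_diagonal_matrix(self):
        ds = self._separable_dataset()
        matrix = cross_validate(ds, "knn", config=CVConfig(seed=3))
        assert np.all(matrix.counts == np.diag(np.diag(matrix.counts)))
        assert weighted_average_accuracy(matrix) == 100.0

    def test_matrix_total_equals_row_count(self):
        ds = self._separable_dataset(rows_per_class=17)
        matrix = cross_validate(ds, "knn", config=CVConfig(seed=3))
        assert matrix.total == len(ds)

    def test_permuted_labels_give_chance_accuracy(self):
        ds = self._separable_dataset(rows_per_class=30, seed=1)
        rng = np.random.default_rng(99)
        ds.y = rng.permutation(ds.y)
        matrix = cross_validate(ds, "knn", config=CVConfig(seed=5))
        acc = weighted_average_accuracy(matrix)
        assert 5.0 <= acc <= 20.0  # chance for 9 balanced classes ~ 11%

    def test_gnb_classifier_path(self):
        ds = self._separable_dataset()
        matrix = cross_validate(ds, "gnb", config=CVConfig(seed=3))
        assert weighted_average_accuracy(matrix) == 100.0

    def test_normalizer_leakage_is_detectable(self):
        """Per-fold vs whole-dataset normalizer fits must be distinguishable.

        f1 separates the classes at unit scale.  f2 is a sentinel laid
        out so that each row's nearest f2-neighbor always belongs to
        the other class (C1 rows sit at integer positions, C2 rows at
        integers + 0.5).  An extreme f1 outlier sits in fold 0: a
        global normalizer fit sees it for every fold and squashes f1,
        handing fold 0's decisions to the misleading f2, while the
        per-fold fit keeps fold 0 clean."""
        rng = np.random.default_rng(42)
        n_pairs = 20
        f1 = np.concatenate([rng.normal(0.0, 0.01, n_pairs), rng.normal(1.0, 0.01, n_pairs)])
        f2 = np.concatenate([np.arange(n_pairs), np.arange(n_pairs) + 0.5]).astype(float)
        y = ["C1"] * n_pairs + ["C2"] * n_pairs
        X = np.column_stack([f1, f2])
        # outlier row in class C1, pinned to fold 0
        X = np.vstack([X, [1e6, 0.0]])
        y = y + ["C1"]
        ds = make_dataset(X, y)
        folds = np.array(([0, 1] * n_pairs) + [0])
        proper = cross_validate(ds, "knn", folds=folds, normalizer_scope="fold")
        leaky = cross_validate(ds, "knn", folds=folds, normalizer_scope="global")
        acc_proper = weighted_average_accuracy(proper)
        acc_leaky = weighted_average_accuracy(leaky)
        assert acc_proper > acc_leaky
        assert not np.array_equal(proper.counts, leaky.counts)

    def test_fold_assignment_mismatch_rejected(self):
        ds = self._separable_dataset()
        with pytest.raises(ValueError, match="fold assignment"):
            cross_validate(ds, "knn", folds=np.zeros(3, dtype=int))


class TestMetricsReport:
    def test_report_consistency_invariant(self):
        matrix = load_reference_confusion()
        report = MetricsReport.from_matrix(matrix)
        row_totals = matrix.counts.sum(axis=1)
        manual = sum(
            row_totals[i] * report.recalls[c]
            for i, c in enumerate(matrix.classes)
        ) / row_totals.sum()
        assert report.weighted_average == pytest.approx(manual)

    def test_json_and_text_render(self, tmp_path):
        report = MetricsReport.from_matrix(load_reference_confusion())
        text = report.to_text()
        assert "Weighted average" in text and "90.2%" in text
        report.to_json(tmp_path / "report.json")
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["weighted_average_pct"] == 90.2
        assert payload["tallies"]["walking_speed"] == 101


def test_round_half_up_convention():
    # exact binary ties round away from zero, not to even
    assert round_half_up(91.75) == 91.8
    assert round_half_up(0.25) == 0.3
    assert round_half_up(-0.25) == -0.3
    assert round_half_up(0.0) == 0.0
    assert round_half_up(90.2031) == 90.2
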