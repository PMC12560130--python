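import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmotaste.chemometrics import (
    CenteredMatrix,
    cluster_class_purity,
    lda_classify,
    row_standardize,
    run_pca,
    stratified_split,
    two_way_hca,
)
from plasmotaste.fingerprinting import (
    FingerprintMatrix,
    METADATA_COLUMNS,
    SENSOR_COLUMNS,
)


def _matrix(values, labels=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids or [f"s{i}" for i in range(n)],
            "class_label": labels or ["a"] * n,
            "replicate": 1,
            "time_s": 30.0,
            "status": "ok",
        }
    )
    frame[SENSOR_COLUMNS] = values
    return FingerprintMatrix(frame[METADATA_COLUMNS + SENSOR_COLUMNS])


class TestRowStandardize:
    def test_constant_row_becomes_zero(self):
        centered = row_standardize(_matrix([np.full(24, 3.7)]))
        np.testing.assert_allclose(centered.values, 0.0, atol=1e-12)
        assert centered.centering_log[0] == pytest.approx(3.7)

    def test_invariant_to_adding_row_constant(self, rng):
        base = rng.normal(size=(5, 24))
        shifted = base + rng.normal(size=(5, 1))
        a = row_standardize(_matrix(base))
        b = row_standardize(_matrix(shifted))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_hand_arithmetic_example(self):
        row = np.arange(1, 25) / 10.0
        centered = row_standardize(_matrix([row]))
        np.testing.assert_allclose(centered.values[0], row - 1.25, atol=1e-12)

    def test_rows_sum_to_zero(self, rng):
        centered = row_standardize(_matrix(rng.normal(size=(10, 24))))
        np.testing.assert_allclose(centered.values.sum(axis=1), 0.0, atol=1e-9)

    def test_idempotent(self, rng):
        matrix = _matrix(rng.normal(size=(6, 24)))
        once = row_standardize(matrix)
        twice = row_standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_missing_entries_rejected(self):
        values = np.zeros((2, 24))
        values[1, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            row_standardize(_matrix(values))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bulk_shift_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(4, 24))
        constants = rng.normal(scale=10, size=(4, 1))
        a = row_standardize(_matrix(base)).values
        b = row_standardize(_matrix(base + constants)).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestPCA:
    def test_rank_one_data_gives_full_pc1_variance(self, rng):
        direction = rng.normal(size=24)
        scores = rng.normal(size=(30, 1))
        values = scores @ direction[None, :]
        _, _, var = run_pca(_matrix(values), n_components=3)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_bulk_dominated_data_has_uniform_pc1_loadings(self, rng):
        bulk = rng.uniform(0, 5, size=(200, 1))
        pattern = 0.05 * rng.normal(size=(200, 24))
        values = bulk * np.ones((1, 24)) + pattern
        _, loadings, _ = run_pca(_matrix(values), n_components=2)
        cv = np.std(loadings[0]) / np.mean(loadings[0])
        assert cv < 0.10

    def test_two_cluster_data_separates_on_pc1(self, rng):
        direction = np.zeros(24)
        direction[:12] = 1.0
        a = rng.normal(0, 0.01, size=(20, 24)) + 2 * direction
        b = rng.normal(0, 0.01, size=(20, 24)) - 2 * direction
        scores, _, _ = run_pca(_matrix(np.vstack([a, b])), n_components=1)
        assert np.all(scores[:20, 0] * scores[20:, 0].mean() < 0) or np.all(
            scores[:20, 0] * scores[20:, 0].mean() > 0
        )
        assert np.min(scores[:20, 0]) > np.max(scores[20:, 0]) or np.max(
            scores[:20, 0]
        ) < np.min(scores[20:, 0])

    def test_sign_convention_deterministic(self, rng):
        values = rng.normal(size=(40, 24))
        _, loadings_a, _ = run_pca(_matrix(values))
        _, loadings_b, _ = run_pca(_matrix(values))
        np.testing.assert_allclose(loadings_a, loadings_b)
        for row in loadings_a:
            assert row[np.argmax(np.abs(row))] > 0

    def test_variance_fractions_sum_below_one(self, rng):
        _, _, var = run_pca(_matrix(rng.normal(size=(30, 24))), n_components=5)
        assert var.sum() <= 1.0 + 1e-9

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            run_pca(_matrix(np.zeros((1, 24))))

    def test_centered_scores_invariant_to_global_constant(self, rng):
        values = rng.normal(size=(20, 24))
        a = row_standardize(_matrix(values))
        b = row_standardize(_matrix(values + 42.0))
        scores_a, _, _ = run_pca(a)
        scores_b, _, _ = run_pca(b)
        np.testing.assert_allclose(scores_a, scores_b, atol=1e-9)


class TestStratifiedSplit:
    def test_even_stratum_splits_fifteen_fifteen(self, rng):
        values = rng.normal(size=(30, 24))
        matrix = _matrix(values, sample_ids=["x"] * 30)
        train, val = stratified_split(matrix, "sample_id", 0.5, 0)
        assert len(train) == 15 and len(val) == 15

    def test_odd_stratum_gives_extra_to_train(self, rng):
        matrix = _matrix(rng.normal(size=(11, 24)), sample_ids=["x"] * 11)
        train, val = stratified_split(matrix, "sample_id", 0.5, 0)
        assert len(train) == 6 and len(val) == 5

    def test_same_seed_identical_partition(self, rng):
        matrix = _matrix(rng.normal(size=(40, 24)), sample_ids=["a", "b"] * 20)
        t1, v1 = stratified_split(matrix, "sample_id", 0.5, 3)
        t2, v2 = stratified_split(matrix, "sample_id", 0.5, 3)
        assert t1.frame.equals(t2.frame) and v1.frame.equals(v2.frame)

    def test_singleton_stratum_rejected(self, rng):
        matrix = _matrix(rng.normal(size=(3, 24)), sample_ids=["a", "a", "b"])
        with pytest.raises(ValueError, match="single row"):
            stratified_split(matrix, "sample_id", 0.5, 0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_partition_disjoint_exhaustive_balanced(self, seed):
        rng = np.random.default_rng(0)
        ids = ["a"] * 10 + ["b"] * 7 + ["c"] * 4
        values = rng.normal(size=(21, 24))
        values[:, 0] = np.arange(21)  # unique marker column
        matrix = _matrix(values, sample_ids=ids)
        train, val = stratified_split(matrix, "sample_id", 0.5, seed)
        train_marks = set(train.values[:, 0])
        val_marks = set(val.values[:, 0])
        assert train_marks.isdisjoint(val_marks)
        assert len(train_marks | val_marks) == 21
        assert list(train.frame.sample_id.value_counts()[["a", "b", "c"]]) == [5, 4, 2]


class TestLDA:
    def _separable(self, rng, n_per=30):
        labels, blocks, sample_ids = [], [], []
        for i, label in enumerate(["u", "v", "w"]):
            direction = np.zeros(24)
            direction[8 * i : 8 * (i + 1)] = 1.0
            blocks.append(rng.normal(0, 0.05, size=(n_per, 24)) + 3 * direction)
            labels += [label] * n_per
            sample_ids += [f"{label}{j % 3}" for j in range(n_per)]
        return _matrix(np.vstack(blocks), labels=labels, sample_ids=sample_ids)

    def test_separable_classes_perfect_for_ten_seeds(self, rng):
        matrix = self._separable(rng)
        for seed in range(10):
            train, val = stratified_split(matrix, "sample_id", 0.5, seed)
            report = lda_classify(train, val, "class_label", split_seed=seed)
            assert report.accuracy == 1.0

    def test_overlapping_classes_near_chance(self, rng):
        values = rng.normal(size=(400, 24))
        labels = ["p"] * 200 + ["q"] * 200
        matrix = _matrix(values, labels=labels, sample_ids=labels)
        train, val = stratified_split(matrix, "class_label", 0.5, 0)
        report = lda_classify(train, val, "class_label")
        assert 0.35 < report.accuracy < 0.65

    def test_single_label_training_rejected(self, rng):
        matrix = _matrix(rng.normal(size=(10, 24)), labels=["a"] * 10)
        with pytest.raises(ValueError, match="2 labels"):
            lda_classify(matrix, matrix, "class_label")

    def test_unseen_validation_label_rejected(self, rng):
        train = _matrix(rng.normal(size=(10, 24)), labels=["a", "b"] * 5)
        val = _matrix(rng.normal(size=(4, 24)), labels=["a", "b", "c", "c"])
        with pytest.raises(ValueError, match="absent"):
            lda_classify(train, val, "class_label")

    def test_confusion_matrix_bookkeeping(self, rng):
        matrix = self._separable(rng)
        train, val = stratified_split(matrix, "sample_id", 0.5, 1)
        report = lda_classify(train, val, "class_label")
        assert report.confusion.sum() == len(val)
        counts = val.frame.class_label.value_counts()
        for label, i in zip(report.label_set, range(len(report.label_set))):
            assert report.confusion[i].sum() == counts[label]
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum()
        )
        percent = report.confusion_percent
        np.testing.assert_allclose(percent.sum(axis=1), 100.0)


class TestHCA:
    def test_identical_rows_merge_at_height_zero(self, rng):
        values = rng.normal(size=(4, 24))
        values[1] = values[0]
        centered = row_standardize(_matrix(values))
        result = two_way_hca(centered)
        assert result.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = set(result.row_linkage[0, :2].astype(int))
        assert merged == {0, 1}

    def test_all_identical_input_zero_height_tree(self):
        values = np.tile(np.arange(24.0), (5, 1))
        centered = row_standardize(_matrix(values))
        result = two_way_hca(centered)
        np.testing.assert_allclose(result.row_linkage[:, 2], 0.0, atol=1e-12)

    def test_correlated_chemistries_co_cluster(self, rng):
        # sensors 0-11 follow one latent factor, 12-23 another
        f1 = rng.normal(size=(60, 1))
        f2 = rng.normal(size=(60, 1))
        values = np.hstack(
            [f1 @ np.ones((1, 12)), f2 @ np.ones((1, 12))]
        ) + 0.01 * rng.normal(size=(60, 24))
        centered = CenteredMatrix(
            frame=_matrix(values).frame, centering_log=np.zeros(60)
        )
        result = two_way_hca(centered)
        from scipy.cluster.hierarchy import fcluster

        col_groups = fcluster(result.col_linkage, t=2, criterion="maxclust")
        assert len(set(col_groups[:12])) == 1
        assert len(set(col_groups[12:])) == 1
        assert col_groups[0] != col_groups[-1]

    def test_too_few_rows_rejected(self, rng):
        centered = row_standardize(_matrix(rng.normal(size=(2, 24))))
        with pytest.raises(ValueError, match="3 rows"):
            two_way_hca(centered)

    def test_ordered_values_match_permutation(self, rng):
        centered = row_standardize(_matrix(rng.normal(size=(8, 24))))
        result = two_way_hca(centered)
        np.testing.assert_allclose(
            result.ordered_values,
            centered.values[np.ix_(result.row_order, result.col_order)],
        )


class TestClusterPurity:
    def test_perfect_clustering_purity_one(self):
        assert cluster_class_purity([1, 1, 2, 2], ["a", "a", "b", "b"]) == 1.0

    def test_mixed_cluster_purity(self):
        # cluster 1: 2 a + 1 b -> majority 2; cluster 2: 1 b -> 1; total 3/4
        assert cluster_class_purity([1, 1, 1, 2], ["a", "a", "b", "b"]) == 0.75
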