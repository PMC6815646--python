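"""Confusion counting, SE/SP/ACC, stratified folds, and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehgpipe.cnn import default_train_config
from ehgpipe.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    compute_metrics,
    confusion,
    cross_validate,
    make_folds,
    positional_evaluate,
    round_half_away,
)


class TestComputeMetrics:
    def test_clinical_table_worked_example_cv_fold(self):
        m = compute_metrics(ConfusionCounts(tp=1194, fp=97, tn=1338, fn=241)).rounded()
        assert (m.se, m.sp, m.acc) == (0.83, 0.93, 0.88)

    def test_clinical_table_worked_example_positional(self):
        m = compute_metrics(ConfusionCounts(tp=948, fp=130, tn=926, fn=108)).rounded()
        assert (m.se, m.sp, m.acc) == (0.90, 0.88, 0.89)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=7, fp=0, tn=7, fn=0))
        assert m.se == m.sp == m.acc == 1.0

    def test_exact_accuracy_identity(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 500, 4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            if c.tp + c.fn == 0 or c.tn + c.fp == 0:
                continue
            m = compute_metrics(c)
            assert m.acc * c.total == pytest.approx(c.tp + c.tn, abs=1e-9)
            assert 0 <= m.se <= 1 and 0 <= m.sp <= 1

    def test_empty_class_raises_not_silent_zero(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=0, fp=3, tn=5, fn=0))
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)

    def test_reporting_rounds_half_away_from_zero(self):
        assert round_half_away(0.875) == 0.88
        assert round_half_away(0.8749999) == 0.87


class TestConfusion:
    def test_all_correct(self):
        truth = ["UC"] * 10 + ["nonUC"] * 10
        c = confusion(truth, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 0, 10, 0)

    def test_always_positive_classifier(self):
        truth = ["UC"] * 10 + ["nonUC"] * 10
        c = confusion(["UC"] * 20, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 10, 0, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["UC", "nonUC"]), st.sampled_from(["UC", "nonUC"])
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_per_item_counting_loop(self, pairs):
        pred = [p for p, _ in pairs]
        truth = [t for _, t in pairs]
        c = confusion(pred, truth)
        tp = sum(1 for p, t in pairs if t == "UC" and p == "UC")
        fn = sum(1 for p, t in pairs if t == "UC" and p != "UC")
        tn = sum(1 for p, t in pairs if t != "UC" and p != "UC")
        fp = sum(1 for p, t in pairs if t != "UC" and p == "UC")
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion(["UC"], ["UC", "nonUC"])


class TestMakeFolds:
    def test_database_scale_fold_sizes(self):
        """7136 units per class split five ways -> {1428, 1427 x4}."""
        n = 7136
        units = list(range(2 * n))
        labels = ["UC"] * n + ["nonUC"] * n
        folds = make_folds(units, k=5, seed=0, class_labels=labels)
        y = np.array(labels)
        for cls in ("UC", "nonUC"):
            sizes = sorted(
                int(((folds.fold_of == f) & (y == cls)).sum()) for f in range(1, 6)
            )
            assert sizes == [1427, 1427, 1427, 1427, 1428]

    def test_small_balanced_split(self):
        units = list(range(20))
        labels = ["UC"] * 10 + ["nonUC"] * 10
        folds = make_folds(units, k=5, seed=1, class_labels=labels)
        y = np.array(labels)
        for f in range(1, 6):
            idx = folds.test_indices(f)
            assert idx.size == 4
            assert (y[idx] == "UC").sum() == 2

    def test_same_seed_reproduces_assignment(self):
        units = list(range(40))
        labels = (["UC"] * 20) + (["nonUC"] * 20)
        a = make_folds(units, 5, seed=3, class_labels=labels)
        b = make_folds(units, 5, seed=3, class_labels=labels)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert a.val_units == b.val_units

    def test_inner_split_is_disjoint_and_stratified(self):
        units = list(range(40))
        labels = (["UC"] * 20) + (["nonUC"] * 20)
        folds = make_folds(units, 5, seed=3, class_labels=labels)
        for f in range(1, 6):
            sub, val = folds.inner_split(f)
            assert set(sub).isdisjoint(val)
            assert len(sub) + len(val) == folds.train_indices(f).size
            y = np.array(labels)
            assert {"UC", "nonUC"} <= set(y[sub])

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            make_folds([1, 2, 3], k=5, class_labels=["UC", "UC", "nonUC"])


@pytest.fixture(scope="module")
def thin_images(image_sets):
    """Four channels per event: a cheap but structurally complete image set."""
    full, positional, _ = image_sets
    return (
        [im for im in full if im.channel_id <= 4],
        [im for im in positional if im.channel_id <= 4],
    )


class TestCrossValidate:
    def test_five_folds_produce_valid_metrics_and_logs(self, thin_images):
        full, _ = thin_images
        cfg = default_train_config("scaled", epochs=2, seed=0)
        result = cross_validate(full, variant="scaled", train_config=cfg, k=5, seed=0)
        assert len(result.fold_counts) == len(result.fold_metrics) == 5
        n_uc = len({im.group_key for im in full if im.label == "UC"})
        n_non = len({im.group_key for im in full if im.label == "nonUC"})
        # count conservation over folds
        assert sum(c.tp + c.fn for c in result.fold_counts) == n_uc
        assert sum(c.tn + c.fp for c in result.fold_counts) == n_non
        assert result.summed_counts.total == n_uc + n_non
        for m in result.fold_metrics:
            assert 0 <= m.se <= 1 and 0 <= m.sp <= 1 and 0 <= m.acc <= 1
        assert len(result.logs) == 5
        assert all(log["iterations"] > 0 for log in result.logs)
        frame = result.to_frame()
        assert list(frame["fold"]) == [f"Fold{i}" for i in range(1, 6)] + ["Average"]


class TestPositionalEvaluate:
    def test_all_22_labels_with_count_conservation(self, thin_images):
        full, positional = thin_images
        cfg = default_train_config("scaled", epochs=2, seed=0)
        from ehgpipe.cnn import build_architecture, train

        model = train(
            full, [im.label for im in full], cfg, build_architecture("scaled")
        )
        result = positional_evaluate(model, positional)
        assert len(result.per_label) == 22
        n_uc = len({im.group_key for im in positional if im.label == "UC"})
        for label, (c, m) in result.per_label.items():
            assert c.tp + c.fn == n_uc
            assert 0 <= m.se <= 1
        assert set(result.to_frame()["window"]) == {
            w for w in result.per_label
        }
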