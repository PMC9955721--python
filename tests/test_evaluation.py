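"""Metric engine and LOSO orchestration."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import mindtask.evaluation as ev
from mindtask.averaging import LabelMap
from mindtask.evaluation import (
    ConfusionMatrix,
    FoldResult,
    PipelineConfig,
    compare_input_criteria,
    confusion,
    metrics_from_confusion,
    run_loso,
)
from mindtask.io_formats import N_FEATURES, PSDFeatureMatrix, SubjectSessions
from mindtask.mlp import MLPConfig


def _feature_cohort(rng, n_subjects=3, n_sessions=3, rows_per_class=4):
    """Feature-level cohort with linearly separable class means."""
    cohort = []
    class_shift = rng.normal(size=(3, N_FEATURES)) * 5
    for s in range(n_subjects):
        sessions = []
        for k in range(n_sessions):
            labels = np.repeat([0, 1, 2], rows_per_class)
            values = 50 + class_shift[labels] + rng.normal(
                size=(labels.size, N_FEATURES)
            )
            sessions.append(PSDFeatureMatrix(
                values=np.abs(values), labels=labels,
                subject_id=f"s{s}", session_id=f"k{k}",
            ))
        cohort.append(SubjectSessions(f"s{s}", sessions))
    return cohort


FAST = PipelineConfig(
    pca_retain=5,
    mlp=MLPConfig(hidden_layers=(8,), dropout_rate=0.0, epochs=40,
                  learning_rate=1e-2),
    seed=0,
)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat([0, 1, 2], 3)
        cm = confusion(y, y)
        np.testing.assert_array_equal(cm.counts, np.diag([3, 3, 3]))

    def test_enumerated_example(self):
        cm = confusion(np.array([0, 1, 2]), np.array([1, 1, 2]))
        assert cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 1
        assert cm.counts[2, 2] == 1
        assert cm.total == 3

    def test_row_sums_are_class_supports(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        cm = confusion(y_true, y_pred)
        np.testing.assert_array_equal(
            cm.counts.sum(axis=1), np.bincount(y_true, minlength=3)
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion(np.array([0, 3]), np.array([0, 0]))


class TestMetrics:
    def test_perfect_matrix_all_ones(self):
        rep = metrics_from_confusion(ConfusionMatrix(np.diag([5, 5, 5])))
        assert rep.accuracy == 1.0
        assert rep.micro_tpr == 1.0 and rep.micro_tnr == 1.0
        for agg in ("micro", "macro", "weighted"):
            assert rep.aggregates[agg]["f1"] == 1.0

    def test_against_sklearn_oracle(self, rng):
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        rep = metrics_from_confusion(confusion(y_true, y_pred))
        assert rep.accuracy == pytest.approx((y_true == y_pred).mean())
        for agg in ("micro", "macro", "weighted"):
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average=agg, zero_division=0
            )
            assert rep.aggregates[agg]["precision"] == pytest.approx(p)
            assert rep.aggregates[agg]["recall"] == pytest.approx(r)
            assert rep.aggregates[agg]["f1"] == pytest.approx(f)

    def test_binary_embedded_case_hand_oracle(self):
        # word class empty: a 2x2 problem inside the 3x3 layout
        counts = np.array([[8, 2, 0], [3, 7, 0], [0, 0, 0]])
        rep = metrics_from_confusion(ConfusionMatrix(counts))
        assert rep.per_class["left"]["precision"] == pytest.approx(8 / 11)
        assert rep.per_class["left"]["recall"] == pytest.approx(8 / 10)
        assert rep.per_class["right"]["precision"] == pytest.approx(7 / 9)
        assert rep.per_class["right"]["recall"] == pytest.approx(7 / 10)
        assert "recall[word]" in rep.zero_division_flags
        assert rep.per_class["word"]["recall"] == 0.0

    def test_micro_identities_on_binary_entry_sweep(self):
        for flat in itertools.product((0, 1), repeat=9):
            counts = np.array(flat).reshape(3, 3)
            if counts.sum() == 0:
                continue
            rep = metrics_from_confusion(ConfusionMatrix(counts))
            n, d = counts.sum(), np.trace(counts)
            assert rep.micro_tpr == pytest.approx(d / n, abs=1e-12)
            assert rep.micro_tnr == pytest.approx((1 + d / n) / 2, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(ConfusionMatrix(np.zeros((3, 3))))


class TestRunLOSO:
    def test_structure_and_hygiene(self, rng):
        cohort = _feature_cohort(rng)
        result = run_loso(cohort, FAST)
        assert len(result.folds) == 3
        assert {f.spec.test_subject for f in result.folds} == {"s0", "s1", "s2"}
        for f in result.folds:
            assert not f.failed
            assert f.spec.test_subject not in f.spec.train_subjects
            assert f.metrics.leakage_flag is False
        assert 0.0 <= result.mean_accuracy <= 1.0
        assert result.mean_accuracy == pytest.approx(
            np.mean([f.metrics.accuracy for f in result.folds])
        )

    def test_separable_cohort_is_learned(self, rng):
        result = run_loso(_feature_cohort(rng), FAST)
        assert result.mean_accuracy > 0.8

    def test_label_matched_averaging_sets_leakage_flag(self, rng):
        from dataclasses import replace

        cfg = replace(FAST, test_averaging="label_matched")
        result = run_loso(_feature_cohort(rng), cfg)
        assert result.leakage_flag is True
        for f in result.folds:
            assert f.metrics.leakage_flag is True

    def test_failed_fold_is_isolated(self, rng, monkeypatch):
        real = ev.run_fold

        def flaky(fold, by_subject, config):
            if fold.fold_id == 1:
                raise RuntimeError("synthetic stage failure")
            return real(fold, by_subject, config)

        monkeypatch.setattr(ev, "run_fold", flaky)
        result = run_loso(_feature_cohort(rng), FAST)
        assert result.folds[1].failed
        assert "synthetic stage failure" in result.folds[1].error
        assert not result.folds[0].failed and not result.folds[2].failed

    def test_none_mode_uses_all_rows(self, rng):
        from dataclasses import replace

        cohort = _feature_cohort(rng)
        res = run_loso(cohort, replace(FAST, averaging_mode="none"))
        n_rows = sum(m.n_rows for m in cohort[0].sessions)
        assert res.folds[0].n_train == 2 * n_rows
        assert res.folds[0].n_test == n_rows


class TestCompareInputCriteria:
    def test_table_layout_and_consistency(self, rng):
        from dataclasses import replace

        cohort = _feature_cohort(rng)
        configs = {
            "after_averaging": replace(FAST, test_averaging="label_matched"),
            "no_averaging": replace(FAST, averaging_mode="none"),
        }
        table, results = compare_input_criteria(cohort, configs)
        assert len(table) == 6
        assert set(table["config"]) == set(configs)
        assert table[table.config == "after_averaging"]["leakage"].all()
        assert not table[table.config == "no_averaging"]["leakage"].any()
        # table metrics equal metrics recomputed from the stored confusions
        for _, row in table.iterrows():
            fold = next(
                f for f in results[row["config"]].folds
                if f.spec.test_subject == row["test_subject"]
            )
            rep = metrics_from_confusion(fold.confusion)
            assert row["accuracy"] == pytest.approx(rep.accuracy)
            assert row["f1"] == pytest.approx(rep.aggregates["micro"]["f1"])

    def test_requires_two_configs(self, rng):
        with pytest.raises(ValueError, match="two"):
            compare_input_criteria(_feature_cohort(rng), {"only": FAST})
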