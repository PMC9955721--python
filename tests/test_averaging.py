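"""Task sorting, within/cross-subject averaging, LOSO folds."""

import numpy as np
import pytest

from mindtask.averaging import (
    COMPETITION_LABELS,
    AveragedTrainingSet,
    FoldSpec,
    LabelMap,
    build_loso_folds,
    class_means,
    multi_subject_average,
    pairwise_subject_average,
    sort_by_task,
    within_subject_average,
)
from mindtask.averaging import test_time_average as blend_test_rows
from mindtask.io_formats import N_FEATURES, PSDFeatureMatrix, SubjectSessions

LM = LabelMap()


def _mat(rows, labels, subject="s", session="x"):
    values = np.asarray(rows, float)
    if values.ndim == 1:
        values = values[:, None]
    full = np.repeat(values, N_FEATURES // values.shape[1] + 1, axis=1)[:, :N_FEATURES]
    return PSDFeatureMatrix(values=full, labels=np.asarray(labels),
                            subject_id=subject, session_id=session)


class TestSortByTask:
    def test_canonical_order_with_stability(self):
        m = _mat([[10], [1], [5], [2]], [2, 0, 1, 0])  # word,left,right,left
        out, order = sort_by_task(m, LM)
        assert out.labels.tolist() == [0, 0, 1, 2]
        assert order.tolist() == [1, 3, 2, 0]
        assert out.values[0, 0] == 1 and out.values[1, 0] == 2

    def test_idempotent_on_sorted_input(self):
        m = _mat([[1], [2], [3]], [0, 1, 2])
        out, order = sort_by_task(m, LM)
        np.testing.assert_array_equal(out.values, m.values)
        assert order.tolist() == [0, 1, 2]

    def test_matches_independent_sort_oracle(self, rng):
        labels = rng.integers(0, 3, size=50)
        values = rng.uniform(size=(50, N_FEATURES))
        m = PSDFeatureMatrix(values=values, labels=labels)
        out, _ = sort_by_task(m, LM)
        oracle = sorted(range(50), key=lambda i: (labels[i], i))
        np.testing.assert_array_equal(out.values, values[oracle])

    def test_unmapped_label_is_error(self):
        m = _mat([[1]], [7])
        with pytest.raises(ValueError, match="alphabet"):
            sort_by_task(m, LM)

    def test_competition_codes(self):
        m = _mat([[1], [2]], [7, 2])
        out, _ = sort_by_task(m, COMPETITION_LABELS)
        assert out.labels.tolist() == [2, 7]


class TestWithinSubjectAverage:
    def test_identical_sessions_average_to_themselves(self):
        base = _mat([[1], [2], [3]], [0, 1, 2], session="a")
        s = SubjectSessions("s", [base, _mat([[1], [2], [3]], [0, 1, 2], session="b")])
        out = within_subject_average(s, LM)
        np.testing.assert_array_equal(out.features.values, base.values)

    def test_two_session_hand_arithmetic(self):
        s = SubjectSessions("s", [
            _mat([[2], [8]], [0, 1], session="a"),
            _mat([[4], [10]], [0, 1], session="b"),
        ])
        out = within_subject_average(s, LM)
        assert out.features.values[0, 0] == 3.0
        assert out.features.values[1, 0] == 9.0

    def test_min_count_truncation(self, rng):
        sessions = [
            _mat(rng.uniform(size=(k, 1)), [0] * k + [], session=f"s{k}")
            for k in (10, 12, 11)
        ]
        # add one row of each other class so validation passes
        sessions = [
            SubjectSessionsHelper.add_classes(m) for m in sessions
        ]
        s = SubjectSessions("s", sessions)
        out = within_subject_average(s, LM)
        left_rows = (out.features.labels == 0).sum()
        assert left_rows == 10

    def test_inconsistent_class_coverage_error_names_context(self):
        # word rows exist in one session but not the other
        s = SubjectSessions("subj7", [
            _mat([[1], [2], [3]], [0, 1, 2], subject="subj7", session="sessZ"),
            _mat([[1], [2]], [0, 1], subject="subj7", session="sessA"),
        ])
        with pytest.raises(ValueError, match="subj7.*sessA.*word"):
            within_subject_average(s, LM)

    def test_class_absent_everywhere_is_skipped(self):
        s = SubjectSessions("s", [
            _mat([[2], [8]], [0, 1], session="a"),
            _mat([[4], [10]], [0, 1], session="b"),
        ])
        out = within_subject_average(s, LM)
        assert out.features.labels.tolist() == [0, 1]

    def test_concat_mode_keeps_all_rows(self):
        s = SubjectSessions("s", [
            _mat([[1], [2], [3]], [0, 1, 2], session="a"),
            _mat([[4], [5], [6]], [0, 1, 2], session="b"),
        ])
        out = within_subject_average(s, LM, mode="concat")
        assert out.features.n_rows == 6
        assert out.features.labels.tolist() == [0, 0, 1, 1, 2, 2]


class SubjectSessionsHelper:
    @staticmethod
    def add_classes(m):
        extra = _mat([[0.5], [0.7]], [1, 2], session=m.session_id)
        return PSDFeatureMatrix(
            values=np.vstack([m.values, extra.values]),
            labels=np.concatenate([m.labels, extra.labels]),
            subject_id=m.subject_id,
            session_id=m.session_id,
        )


def _avg_set(rows, labels, subject):
    m = _mat(rows, labels, subject=subject)
    prov = [[(subject, "s1", i)] for i in range(m.n_rows)]
    return AveragedTrainingSet(features=m, provenance=prov)


class TestCrossSubjectAverage:
    def test_self_average_is_identity(self):
        a = _avg_set([[1], [2], [3]], [0, 1, 2], "a")
        out = pairwise_subject_average(a, a, LM)
        np.testing.assert_array_equal(out.features.values, a.features.values)

    def test_midpoint(self):
        a = _avg_set([[1], [1], [1]], [0, 1, 2], "a")
        b = _avg_set([[3], [3], [3]], [0, 1, 2], "b")
        out = pairwise_subject_average(a, b, LM)
        assert (out.features.values == 2.0).all()

    def test_matches_bruteforce_mean_oracle(self, rng):
        va = rng.uniform(size=(9, N_FEATURES))
        vb = rng.uniform(size=(9, N_FEATURES))
        labels = np.repeat([0, 1, 2], 3)
        a = _avg_set(va[:, :1], labels, "a")
        b = _avg_set(vb[:, :1], labels, "b")
        a.features.values, b.features.values = va, vb
        out = pairwise_subject_average(a, b, LM)
        np.testing.assert_allclose(out.features.values, (va + vb) / 2, atol=1e-15)

    def test_provenance_is_class_pure(self):
        a = _avg_set([[1], [2], [3]], [0, 1, 2], "a")
        b = _avg_set([[4], [5], [6]], [0, 1, 2], "b")
        out = pairwise_subject_average(a, b, LM)
        assert out.subjects() == {"a", "b"}
        for row_label, prov in zip(out.features.labels, out.provenance):
            # contributing rows must all carry the row's class
            for subj, _, idx in prov:
                src = a if subj == "a" else b
                assert src.features.labels[idx] == row_label

    def test_grand_mean_preserved_per_class(self, rng):
        va = rng.uniform(size=(6, N_FEATURES))
        vb = rng.uniform(size=(6, N_FEATURES))
        labels = np.repeat([0, 1, 2], 2)
        a, b = _avg_set(va[:, :1], labels, "a"), _avg_set(vb[:, :1], labels, "b")
        a.features.values, b.features.values = va, vb
        out = pairwise_subject_average(a, b, LM)
        for c in (0, 1, 2):
            sel = labels == c
            osel = out.features.labels == c
            np.testing.assert_allclose(
                out.features.values[osel].mean(0),
                (va[sel].mean(0) + vb[sel].mean(0)) / 2,
                atol=1e-15,
            )

    def test_k_way_generalization(self):
        parts = [_avg_set([[v], [v], [v]], [0, 1, 2], f"s{v}") for v in (1, 2, 6)]
        out = multi_subject_average(parts, LM)
        assert (out.features.values == 3.0).all()
        assert out.subjects() == {"s1", "s2", "s6"}


class TestFolds:
    def _cohort(self, ids):
        return [
            SubjectSessions(i, [_mat([[1], [2], [3]], [0, 1, 2], subject=i)])
            for i in ids
        ]

    def test_three_subjects_three_folds(self):
        folds = build_loso_folds(self._cohort(["s1", "s2", "s3"]))
        assert len(folds) == 3
        assert {f.test_subject for f in folds} == {"s1", "s2", "s3"}
        for f in folds:
            assert f.test_subject not in f.train_subjects
            assert len(f.train_subjects) == 2
        assert folds[2].train_subjects == ("s1", "s2")

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            build_loso_folds(self._cohort(["s1", "s2"]))

    def test_fold_spec_rejects_leaky_layout(self):
        with pytest.raises(ValueError, match="appears in the training set"):
            FoldSpec(fold_id=0, train_subjects=("a", "b"), test_subject="a")


class TestTestTimeAverage:
    def test_off_is_identity(self):
        m = _mat([[1], [5]], [0, 1])
        out, leak = blend_test_rows(m, {}, mode="off")
        assert out is m and leak is False

    def test_label_matched_blends_with_true_class_mean(self):
        m = _mat([[4.0]], [1])
        means = {1: np.full(N_FEATURES, 2.0), 0: np.zeros(N_FEATURES)}
        out, leak = blend_test_rows(m, means, mode="label_matched")
        assert leak is True
        np.testing.assert_allclose(out.values, 3.0)

    def test_missing_class_mean_is_error(self):
        m = _mat([[1.0]], [2])
        with pytest.raises(ValueError, match="class mean"):
            blend_test_rows(m, {0: np.zeros(N_FEATURES)}, mode="label_matched")

    def test_class_means(self):
        m = _mat([[1], [3], [5]], [0, 0, 1])
        means = class_means(m, LM)
        assert means[0][0] == 2.0 and means[1][0] == 5.0
        assert 2 not in means
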