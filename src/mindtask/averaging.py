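"""Task-wise averaging and leave-one-subject-out fold construction.

The cross-subject pipeline rests on three mean-based reductions of the
PSD feature rows, always within one task class, never across classes:

1. *task sort* — rows of a session are stably re-arranged by mental task;
2. *within-subject average* — aligned class blocks of a subject's sessions
   are averaged element-wise (after truncating to the shortest block);
3. *cross-subject average* — aligned class blocks of the training
   subjects are averaged the same way (the pairwise case for two).

Folds are leave-one-subject-out: each subject is the test set exactly
once and contributes nothing to any training artifact of its fold. An
optional test-time averaging mode blends each test row with the training
mean of its *true* class; because that uses test labels it is information
leakage and is loudly flagged in every report it touches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CLASS_NAMES, PSDFeatureMatrix, SubjectSessions

logger = logging.getLogger(__name__)

#: provenance entry: (subject_id, session_id, original row index)
Provenance = tuple[str, str, int]


@dataclass(frozen=True)
class LabelMap:
    """Ordered mapping from file label codes to internal classes.

    ``codes[i]`` is the file code of internal class ``i`` in the canonical
    (left, right, word) order. The competition files historically use
    (2, 3, 7); synthetic files use (0, 1, 2).
    """

    codes: tuple[int, int, int] = (0, 1, 2)

    def to_internal(self, labels: np.ndarray) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.codes)}
        out = np.empty(len(labels), dtype=np.int64)
        for i, v in enumerate(np.asarray(labels)):
            if int(v) not in lut:
                raise ValueError(
                    f"label {int(v)} not in alphabet {self.codes}"
                )
            out[i] = lut[int(v)]
        return out

    def class_name(self, code: int) -> str:
        return CLASS_NAMES[self.to_internal(np.array([code]))[0]]


COMPETITION_LABELS = LabelMap((2, 3, 7))


@dataclass
class FoldSpec:
    """One leave-one-subject-out fold."""

    fold_id: int
    train_subjects: tuple[str, ...]
    test_subject: str
    averaging_mode: str = "train_averaged"   # none | train_averaged
    test_averaging: str = "off"              # off | label_matched

    def __post_init__(self) -> None:
        if self.test_subject in self.train_subjects:
            raise ValueError(
                f"fold {self.fold_id}: test subject {self.test_subject!r} "
                "appears in the training set"
            )
        if self.averaging_mode not in ("none", "train_averaged"):
            raise ValueError(f"unknown averaging_mode {self.averaging_mode!r}")
        if self.test_averaging not in ("off", "label_matched"):
            raise ValueError(f"unknown test_averaging {self.test_averaging!r}")


@dataclass
class AveragedTrainingSet:
    """Labelled averaged features plus per-row contribution lists."""

    features: PSDFeatureMatrix
    provenance: list[list[Provenance]]

    def __post_init__(self) -> None:
        if len(self.provenance) != self.features.n_rows:
            raise ValueError("one provenance list required per row")
        if any(len(p) == 0 for p in self.provenance):
            raise ValueError("empty provenance entry")

    def subjects(self) -> set[str]:
        return {subj for row in self.provenance for subj, _, _ in row}


def sort_by_task(
    m: PSDFeatureMatrix, label_map: LabelMap = LabelMap()
) -> tuple[PSDFeatureMatrix, np.ndarray]:
    """Stable sort of rows by canonical class order (left, right, word).

    Returns the sorted matrix and the original row indices in their new
    order (the sort's provenance).
    """
    if not m.has_labels:
        raise ValueError("cannot task-sort an unlabelled matrix")
    internal = label_map.to_internal(m.labels)
    order = np.argsort(internal, kind="stable")
    return m.copy_with(m.values[order], m.labels[order]), order


def _class_blocks(
    m: PSDFeatureMatrix, label_map: LabelMap
) -> dict[int, np.ndarray]:
    """Row indices per internal class, in stable within-class order."""
    internal = label_map.to_internal(m.labels)
    return {c: np.flatnonzero(internal == c) for c in range(len(CLASS_NAMES))}


def within_subject_average(
    s: SubjectSessions,
    label_map: LabelMap = LabelMap(),
    mode: str = "average",
) -> AveragedTrainingSet:
    """Collapse a subject's sessions into one task-sorted feature file.

    ``mode="average"``: per class, each session's class block is truncated
    to the minimum per-class row count over sessions and the aligned rows
    are averaged element-wise. ``mode="concat"``: class blocks are stacked
    instead (no truncation). Output rows are grouped by class in canonical
    order.
    """
    if mode not in ("average", "concat"):
        raise ValueError(f"unknown within-subject mode {mode!r}")
    blocks = [_class_blocks(sess, label_map) for sess in s.sessions]
    present = [
        c for c in range(len(CLASS_NAMES))
        if any(bl[c].size for bl in blocks)
    ]
    for sess, bl in zip(s.sessions, blocks):
        for c in present:
            if bl[c].size == 0:
                raise ValueError(
                    f"subject {s.subject_id!r} session {sess.session_id!r} "
                    f"has no rows of class {CLASS_NAMES[c]!r}"
                )
    values, labels, prov = [], [], []
    for c in present:
        code = label_map.codes[c]
        if mode == "concat":
            for sess, bl in zip(s.sessions, blocks):
                for i in bl[c]:
                    values.append(sess.values[i])
                    labels.append(code)
                    prov.append([(s.subject_id, sess.session_id, int(i))])
            continue
        n_min = min(bl[c].size for bl in blocks)
        dropped = sum(bl[c].size for bl in blocks) - n_min * len(blocks)
        if dropped:
            logger.info(
                "subject %s class %s: truncated %d rows to align sessions",
                s.subject_id, CLASS_NAMES[c], dropped,
            )
        for i in range(n_min):
            rows = [sess.values[bl[c][i]] for sess, bl in zip(s.sessions, blocks)]
            values.append(np.mean(rows, axis=0))
            labels.append(code)
            prov.append([
                (s.subject_id, sess.session_id, int(bl[c][i]))
                for sess, bl in zip(s.sessions, blocks)
            ])
    features = PSDFeatureMatrix(
        values=np.asarray(values),
        labels=np.asarray(labels, dtype=np.int64),
        subject_id=s.subject_id,
    )
    return AveragedTrainingSet(features=features, provenance=prov)


def multi_subject_average(
    parts: list[AveragedTrainingSet], label_map: LabelMap = LabelMap()
) -> AveragedTrainingSet:
    """Task-wise element-wise mean across k subjects' averaged files.

    Per class, every subject's block is truncated to the common minimum
    count and aligned rows (by within-class index) are averaged. With two
    subjects this is the pairwise cross-subject average.
    """
    if len(parts) < 2:
        raise ValueError("need at least two subjects to average")
    blocks = [_class_blocks(p.features, label_map) for p in parts]
    present = [
        c for c in range(len(CLASS_NAMES))
        if any(bl[c].size for bl in blocks)
    ]
    for p, bl in zip(parts, blocks):
        for c in present:
            if bl[c].size == 0:
                raise ValueError(
                    f"class {CLASS_NAMES[c]!r} missing for subject "
                    f"{p.features.subject_id!r}"
                )
    values, labels, prov = [], [], []
    for c in present:
        n_min = min(bl[c].size for bl in blocks)
        for i in range(n_min):
            rows = [p.features.values[bl[c][i]] for p, bl in zip(parts, blocks)]
            values.append(np.mean(rows, axis=0))
            labels.append(label_map.codes[c])
            prov.append([
                entry
                for p, bl in zip(parts, blocks)
                for entry in p.provenance[bl[c][i]]
            ])
    features = PSDFeatureMatrix(
        values=np.asarray(values), labels=np.asarray(labels, dtype=np.int64)
    )
    return AveragedTrainingSet(features=features, provenance=prov)


def pairwise_subject_average(
    a: AveragedTrainingSet | PSDFeatureMatrix,
    b: AveragedTrainingSet | PSDFeatureMatrix,
    label_map: LabelMap = LabelMap(),
) -> AveragedTrainingSet:
    """Two-subject task-wise average (the canonical training-file step)."""
    return multi_subject_average(
        [_as_averaged(a), _as_averaged(b)], label_map
    )


def _as_averaged(x: AveragedTrainingSet | PSDFeatureMatrix) -> AveragedTrainingSet:
    if isinstance(x, AveragedTrainingSet):
        return x
    prov = [[(x.subject_id, x.session_id, i)] for i in range(x.n_rows)]
    return AveragedTrainingSet(features=x, provenance=prov)


def build_loso_folds(
    cohort: list[SubjectSessions],
    averaging_mode: str = "train_averaged",
    test_averaging: str = "off",
) -> list[FoldSpec]:
    """One fold per subject as the held-out test set."""
    if len(cohort) < 3:
        raise ValueError(
            f"leave-one-subject-out needs >= 3 subjects, got {len(cohort)}"
        )
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject ids: {ids}")
    return [
        FoldSpec(
            fold_id=i,
            train_subjects=tuple(x for x in ids if x != test),
            test_subject=test,
            averaging_mode=averaging_mode,
            test_averaging=test_averaging,
        )
        for i, test in enumerate(ids)
    ]


def class_means(
    m: PSDFeatureMatrix, label_map: LabelMap = LabelMap()
) -> dict[int, np.ndarray]:
    """Per-class mean feature vector, keyed by file label code."""
    blocks = _class_blocks(m, label_map)
    out = {}
    for c, idx in blocks.items():
        if idx.size:
            out[label_map.codes[c]] = m.values[idx].mean(axis=0)
    return out


def test_time_average(
    test: PSDFeatureMatrix,
    train_means: dict[int, np.ndarray],
    mode: str = "off",
    label_map: LabelMap = LabelMap(),
) -> tuple[PSDFeatureMatrix, bool]:
    """Optionally blend each test row with its true-class training mean.

    ``mode="off"`` returns the input untouched. ``mode="label_matched"``
    replaces row r of class c by ``(r + train_mean_c) / 2``. That consults
    the test row's *true* label, so the returned leakage flag is True and
    must be propagated to every downstream report.
    """
    if mode == "off":
        return test, False
    if mode != "label_matched":
        raise ValueError(f"unknown test averaging mode {mode!r}")
    if not test.has_labels:
        raise ValueError("label-matched averaging requires test labels")
    values = np.empty_like(test.values)
    for i, code in enumerate(test.labels):
        if int(code) not in train_means:
            raise ValueError(
                f"no training class mean for label {int(code)} "
                f"({label_map.class_name(int(code))})"
            )
        values[i] = (test.values[i] + train_means[int(code)]) / 2.0
    return test.copy_with(values, test.labels.copy()), True
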