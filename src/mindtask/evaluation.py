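"""Confusion matrices, the metric suite, and LOSO experiment orchestration.

Metrics follow the one-vs-rest convention: per class c, Tp are rows
predicted c that are c, Fp predicted c but not c, Fn are c predicted
otherwise, Tn the rest. Precision Tp/(Tp+Fp), recall (= TPR) Tp/(Tp+Fn),
F1 their harmonic mean, accuracy the diagonal fraction. Aggregations:

* micro — pool Tp/Fp/Fn/Tn over classes first (for single-label
  multiclass data micro TPR equals accuracy, and for C classes micro TNR
  equals ((C-2)N + diag)/((C-1)N); both identities are asserted on every
  report);
* macro — unweighted mean of per-class values;
* weighted — support-weighted mean.

Zero-denominator metrics are reported as 0 with an explicit flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .averaging import (
    AveragedTrainingSet,
    FoldSpec,
    LabelMap,
    _as_averaged,
    build_loso_folds,
    class_means,
    multi_subject_average,
    test_time_average,
    within_subject_average,
)
from .io_formats import CLASS_NAMES, PSDFeatureMatrix, SubjectSessions, concat_matrices
from .mlp import MLPConfig, init_mlp, predict, train_mlp
from .pca import fit_pca, transform

logger = logging.getLogger(__name__)

AGGREGATIONS = ("micro", "macro", "weighted")


@dataclass
class ConfusionMatrix:
    """3x3 actual-by-predicted counts in canonical class order."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError(f"confusion matrix must be {c}x{c}")
        if np.any(self.counts < 0) or not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3
) -> ConfusionMatrix:
    """Count actual-vs-predicted pairs of internal class indices."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        bad = (y < 0) | (y >= n_classes)
        if np.any(bad):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts, class_names=CLASS_NAMES[:n_classes])


@dataclass
class MetricsReport:
    accuracy: float
    micro_tpr: float
    micro_tnr: float
    per_class: dict[str, dict[str, float]]
    aggregates: dict[str, dict[str, float]]  # aggregation -> metric -> value
    aggregation: str = "micro"
    leakage_flag: bool = False
    fold_id: int | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.aggregates[self.aggregation]["precision"]

    @property
    def recall(self) -> float:
        return self.aggregates[self.aggregation]["recall"]

    @property
    def f1(self) -> float:
        return self.aggregates[self.aggregation]["f1"]


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def metrics_from_confusion(
    cm: ConfusionMatrix, aggregation: str = "micro"
) -> MetricsReport:
    """The full metric suite from one confusion matrix."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    counts = cm.counts
    n = counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = counts.shape[0]
    diag = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)   # per-class actual support
    col = counts.sum(axis=0).astype(float)   # per-class predicted
    tp = diag
    fn = row - diag
    fp = col - diag
    tn = n - row - col + diag

    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cm.class_names):
        p = _safe_div(tp[i], tp[i] + fp[i], flags, f"precision[{name}]")
        r = _safe_div(tp[i], tp[i] + fn[i], flags, f"recall[{name}]")
        f1 = _safe_div(2 * p * r, p + r, flags, f"f1[{name}]")
        per_class[name] = {
            "precision": p, "recall": r, "f1": f1, "support": row[i],
            "tp": tp[i], "fp": fp[i], "fn": fn[i], "tn": tn[i],
        }

    accuracy = float(diag.sum() / n)
    micro_tpr = _safe_div(tp.sum(), tp.sum() + fn.sum(), flags, "micro_tpr")
    micro_tnr = _safe_div(tn.sum(), tn.sum() + fp.sum(), flags, "micro_tnr")

    micro_p = _safe_div(tp.sum(), tp.sum() + fp.sum(), flags, "micro_precision")
    micro_f1 = _safe_div(
        2 * micro_p * micro_tpr, micro_p + micro_tpr, flags, "micro_f1"
    )
    pc = np.array([per_class[nm]["precision"] for nm in cm.class_names])
    rc = np.array([per_class[nm]["recall"] for nm in cm.class_names])
    fc = np.array([per_class[nm]["f1"] for nm in cm.class_names])
    w = row / n
    aggregates = {
        "micro": {"precision": micro_p, "recall": micro_tpr, "f1": micro_f1},
        "macro": {
            "precision": float(pc.mean()),
            "recall": float(rc.mean()),
            "f1": float(fc.mean()),
        },
        "weighted": {
            "precision": float(pc @ w),
            "recall": float(rc @ w),
            "f1": float(fc @ w),
        },
    }

    # structural identities of single-label multiclass one-vs-rest pooling
    assert abs(micro_tpr - accuracy) < 1e-12
    expected_tnr = ((c - 2) * n + diag.sum()) / ((c - 1) * n)
    assert abs(micro_tnr - expected_tnr) < 1e-12

    return MetricsReport(
        accuracy=accuracy,
        micro_tpr=float(micro_tpr),
        micro_tnr=float(micro_tnr),
        per_class=per_class,
        aggregates=aggregates,
        aggregation=aggregation,
        zero_division_flags=flags,
    )


@dataclass
class PipelineConfig:
    """Everything run_loso needs; echoed into the result for provenance."""

    label_map: LabelMap = field(default_factory=LabelMap)
    averaging_mode: str = "train_averaged"   # none | train_averaged
    test_averaging: str = "off"              # off | label_matched
    within_subject: str = "average"          # average | concat
    pca_retain: float | int = 0.95
    standardize_scores: bool = True  # z-score PCA scores with training stats
    mlp: MLPConfig = field(default_factory=MLPConfig)
    seed: int = 0


@dataclass
class FoldResult:
    spec: FoldSpec
    confusion: ConfusionMatrix | None = None
    metrics: MetricsReport | None = None
    n_train: int = 0
    n_test: int = 0
    pca_components: int = 0
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class LOSOResult:
    folds: list[FoldResult]
    mean_accuracy: float
    config: PipelineConfig
    leakage_flag: bool


def _fold_seed(base_seed: int, fold_id: int) -> int:
    return int(
        np.random.SeedSequence((base_seed, fold_id)).generate_state(1)[0]
        % (2 ** 31)
    )


def _audit_no_test_subject(train_subjects: set[str], fold: FoldSpec) -> None:
    if fold.test_subject in train_subjects:
        raise RuntimeError(
            f"fold {fold.fold_id}: test subject {fold.test_subject!r} leaked "
            "into a training artifact"
        )


def _prepare_fold(
    fold: FoldSpec,
    by_subject: dict[str, SubjectSessions],
    config: PipelineConfig,
) -> tuple[PSDFeatureMatrix, PSDFeatureMatrix, bool]:
    """Build the training and test matrices of one fold, audited."""
    lm = config.label_map
    test_subject = by_subject[fold.test_subject]
    if fold.averaging_mode == "none":
        train = concat_matrices(
            [sess for sid in fold.train_subjects for sess in by_subject[sid].sessions]
        )
        train_subjects = {
            sess.subject_id or sid
            for sid in fold.train_subjects
            for sess in by_subject[sid].sessions
        }
        test = concat_matrices(test_subject.sessions)
    else:
        averaged = [
            within_subject_average(by_subject[sid], lm, mode=config.within_subject)
            for sid in fold.train_subjects
        ]
        train_set = (
            multi_subject_average(averaged, lm)
            if len(averaged) > 1
            else averaged[0]
        )
        train = train_set.features
        train_subjects = train_set.subjects()
        test = within_subject_average(test_subject, lm,
                                      mode=config.within_subject).features
    _audit_no_test_subject(train_subjects, fold)
    test, leak = test_time_average(
        test, class_means(train, lm), mode=fold.test_averaging, label_map=lm
    )
    return train, test, leak


def run_fold(
    fold: FoldSpec,
    by_subject: dict[str, SubjectSessions],
    config: PipelineConfig,
) -> FoldResult:
    """Averaging -> PCA -> classifier -> metrics for one fold."""
    train, test, leak = _prepare_fold(fold, by_subject, config)
    lm = config.label_map
    y_train = lm.to_internal(train.labels)
    y_test = lm.to_internal(test.labels)

    model_pca = fit_pca(train, retain=config.pca_retain)
    z_train = transform(model_pca, train)
    z_test = transform(model_pca, test)
    if config.standardize_scores:
        # conditioning only; statistics come from training rows alone
        mu, sd = z_train.mean(axis=0), z_train.std(axis=0)
        sd[sd == 0] = 1.0
        z_train = (z_train - mu) / sd
        z_test = (z_test - mu) / sd
    logger.info(
        "fold %d: %d train rows, %d test rows, %d principal components",
        fold.fold_id, len(y_train), len(y_test), model_pca.n_components_retained,
    )

    mlp_cfg = replace(config.mlp, seed=_fold_seed(config.seed, fold.fold_id))
    model = init_mlp(z_train.shape[1], mlp_cfg)
    model = train_mlp(model, z_train, y_train)
    y_pred = predict(model, z_test)

    cm = confusion(y_test, y_pred)
    report = metrics_from_confusion(cm)
    report.leakage_flag = leak
    report.fold_id = fold.fold_id
    return FoldResult(
        spec=fold,
        confusion=cm,
        metrics=report,
        n_train=len(y_train),
        n_test=len(y_test),
        pca_components=model_pca.n_components_retained,
    )


def run_loso(
    cohort: list[SubjectSessions], config: PipelineConfig | None = None
) -> LOSOResult:
    """Full leave-one-subject-out experiment over a feature-level cohort.

    A failing fold is recorded with its diagnostic and the run continues;
    the summary averages the accuracies of the folds that completed.
    """
    config = config or PipelineConfig()
    folds = build_loso_folds(
        cohort,
        averaging_mode=config.averaging_mode,
        test_averaging=config.test_averaging,
    )
    by_subject = {s.subject_id: s for s in cohort}
    results = []
    for fold in folds:
        try:
            results.append(run_fold(fold, by_subject, config))
        except Exception as exc:  # noqa: BLE001 — fold isolation is the contract
            logger.error("fold %d failed: %s", fold.fold_id, exc)
            results.append(FoldResult(spec=fold, error=str(exc)))
    done = [r for r in results if not r.failed]
    if not done:
        raise RuntimeError("every fold failed; see fold diagnostics")
    mean_acc = float(np.mean([r.metrics.accuracy for r in done]))
    return LOSOResult(
        folds=results,
        mean_accuracy=mean_acc,
        config=config,
        leakage_flag=any(r.metrics.leakage_flag for r in done),
    )


def compare_input_criteria(
    cohort: list[SubjectSessions],
    configs: dict[str, PipelineConfig],
) -> tuple[pd.DataFrame, dict[str, LOSOResult]]:
    """Accuracy/precision/recall/F1 per (configuration, test subject).

    The table mirrors the input-criteria comparison layout: one row per
    configuration and held-out subject, with the leakage flag per row.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    rows = []
    results: dict[str, LOSOResult] = {}
    for name, cfg in configs.items():
        res = run_loso(cohort, cfg)
        results[name] = res
        for fr in res.folds:
            if fr.failed:
                rows.append({
                    "config": name, "test_subject": fr.spec.test_subject,
                    "error": fr.error,
                })
                continue
            rows.append({
                "config": name,
                "test_subject": fr.spec.test_subject,
                "accuracy": fr.metrics.accuracy,
                "precision": fr.metrics.precision,
                "recall": fr.metrics.recall,
                "f1": fr.metrics.f1,
                "leakage": fr.metrics.leakage_flag,
            })
    return pd.DataFrame(rows), results
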