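"""Reference confusion matrices for the three benchmark subjects.

These are the published per-subject confusion matrices of a cross-subject
averaged DNN pipeline evaluated on BCI competition III dataset V
(rows: actual left hand / right hand / word generation; columns: the same,
predicted). They are shipped as *inputs* for validating the metric
engine — the micro-pooled TPR and TNR computed from them by
:func:`mindtask.evaluation.metrics_from_confusion` must match the values
published alongside them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix, metrics_from_confusion

BENCHMARK_CONFUSIONS: dict[str, np.ndarray] = {
    "subject1": np.array([
        [757, 71, 57],
        [112, 1000, 184],
        [10, 49, 1183],
    ]),
    "subject2": np.array([
        [528, 198, 85],
        [113, 970, 264],
        [222, 192, 851],
    ]),
    "subject3": np.array([
        [714, 5, 4],
        [188, 825, 38],
        [201, 322, 1126],
    ]),
}


def benchmark_metric_table() -> pd.DataFrame:
    """Micro TPR/TNR recomputed from the shipped confusion matrices."""
    rows = []
    for name, counts in BENCHMARK_CONFUSIONS.items():
        rep = metrics_from_confusion(ConfusionMatrix(counts))
        rows.append({
            "subject": name,
            "n": int(counts.sum()),
            "micro_tpr": rep.micro_tpr,
            "micro_tnr": rep.micro_tnr,
            "accuracy": rep.accuracy,
        })
    return pd.DataFrame(rows)
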