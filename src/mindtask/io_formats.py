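"""Readers and writers for band-power (PSD) feature files.

The on-disk dialect is the precomputed-feature format distributed with
BCI competition III dataset V: plain ASCII, no header, one PSD sample per
line, 96 whitespace-separated numeric fields (8 centro-parietal channels
x 12 frequency bins spanning 8-30 Hz at 2 Hz resolution, channel-major),
optionally followed by a 97th field holding the integer mental-task label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Analysis channels, in feature-column order (channel-major layout).
PSD_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4")

#: Centre frequencies of the 12 bins per channel, Hz.
PSD_BIN_HZ: tuple[int, ...] = tuple(range(8, 31, 2))

#: Total feature dimensionality: 8 channels x 12 bins.
N_FEATURES: int = len(PSD_CHANNELS) * len(PSD_BIN_HZ)

#: Decimal precision used when writing feature files.
WRITE_DECIMALS: int = 6

#: Canonical internal class order. All reports and confusion matrices use it.
CLASS_NAMES: tuple[str, ...] = ("left", "right", "word")


class FormatError(ValueError):
    """A feature file violates the expected row/column structure."""


@dataclass
class PSDFeatureMatrix:
    """A block of PSD feature rows with optional per-row task labels.

    ``values`` is ``n_rows x 96``; column ``c * 12 + b`` is channel
    ``PSD_CHANNELS[c]`` at ``PSD_BIN_HZ[b]`` Hz. ``labels`` holds one
    integer task code per row (any <=3-symbol alphabet; see
    :func:`mindtask.averaging.LabelMap`), or is empty when unlabelled.
    """

    values: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape[1] != N_FEATURES:
            raise FormatError(
                f"expected exactly {N_FEATURES} feature columns, "
                f"got {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("feature values must be finite")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and self.labels.shape != (self.values.shape[0],):
            raise FormatError(
                f"labels length {self.labels.shape} does not match "
                f"{self.values.shape[0]} rows"
            )
        if self.labels.size and np.unique(self.labels).size > len(CLASS_NAMES):
            raise FormatError(
                "label alphabet has more than "
                f"{len(CLASS_NAMES)} distinct values: {np.unique(self.labels)}"
            )
        if self.values.size and np.any(self.values < 0):
            warnings.warn(
                "negative PSD values present; rows retained unaltered",
                stacklevel=3,
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def has_labels(self) -> bool:
        return self.labels.size > 0

    def copy_with(self, values: np.ndarray, labels: np.ndarray) -> "PSDFeatureMatrix":
        return PSDFeatureMatrix(
            values=values,
            labels=labels,
            subject_id=self.subject_id,
            session_id=self.session_id,
        )


@dataclass
class SubjectSessions:
    """Ordered labelled training sessions for one subject."""

    subject_id: str
    sessions: list[PSDFeatureMatrix]

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError(f"subject {self.subject_id!r} has no sessions")
        for s in self.sessions:
            if s.subject_id and s.subject_id != self.subject_id:
                raise ValueError(
                    f"session subject_id {s.subject_id!r} != {self.subject_id!r}"
                )


def read_psd_ascii(
    path: str | Path,
    label_column_present: bool = True,
    subject_id: str = "",
    session_id: str = "",
) -> PSDFeatureMatrix:
    """Read a competition-dialect ASCII feature file.

    Each line must carry 96 numeric fields, plus a 97th integer label when
    ``label_column_present``. Any whitespace run separates fields. Row order
    is preserved. Negative PSD entries trigger a warning but are kept.
    """
    path = Path(path)
    expected = N_FEATURES + (1 if label_column_present else 0)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue  # blank line
            if len(tokens) != expected:
                raise FormatError(
                    f"{path}:{lineno}: expected {expected} fields, "
                    f"got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
    if not rows:
        values = np.empty((0, N_FEATURES))
        labels = np.empty(0, dtype=np.int64)
    else:
        arr = np.asarray(rows, dtype=np.float64)
        if label_column_present:
            values, labels = arr[:, :N_FEATURES], arr[:, N_FEATURES]
            if not np.allclose(labels, np.round(labels)):
                raise FormatError(f"{path}: non-integer values in label column")
            labels = labels.astype(np.int64)
        else:
            values, labels = arr, np.empty(0, dtype=np.int64)
    return PSDFeatureMatrix(
        values=values, labels=labels, subject_id=subject_id, session_id=session_id
    )


def write_psd_ascii(
    matrix: PSDFeatureMatrix, path: str | Path, with_labels: bool = True
) -> None:
    """Write a feature matrix in the competition ASCII dialect.

    One line per PSD sample: 96 fields at ``WRITE_DECIMALS`` fixed decimals
    separated by single spaces, then the integer label when ``with_labels``.
    No header line. An empty matrix produces an empty file.
    """
    if with_labels and matrix.n_rows and not matrix.has_labels:
        raise ValueError("with_labels=True but matrix carries no labels")
    path = Path(path)
    fmt = f"{{:.{WRITE_DECIMALS}f}}"
    with path.open("w") as fh:
        for i in range(matrix.n_rows):
            fields = [fmt.format(v) for v in matrix.values[i]]
            if with_labels:
                fields.append(str(int(matrix.labels[i])))
            fh.write(" ".join(fields) + "\n")


def concat_matrices(parts: Sequence[PSDFeatureMatrix]) -> PSDFeatureMatrix:
    """Stack feature blocks row-wise; labels must be present in all or none."""
    if not parts:
        raise ValueError("nothing to concatenate")
    values = np.vstack([p.values for p in parts])
    labelled = [p.has_labels for p in parts if p.n_rows]
    if any(labelled) and not all(labelled):
        raise ValueError("cannot mix labelled and unlabelled blocks")
    if all(labelled) and labelled:
        labels = np.concatenate([p.labels for p in parts if p.n_rows])
    else:
        labels = np.empty(0, dtype=np.int64)
    sids = {p.subject_id for p in parts}
    return PSDFeatureMatrix(
        values=values,
        labels=labels,
        subject_id=sids.pop() if len(sids) == 1 else "",
        session_id="",
    )
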