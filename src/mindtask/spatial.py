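"""Scalp montages and the surface Laplacian spatial filter.

The filter implemented here is the unweighted *small* Laplacian: each
analysis channel minus the mean of its nearest 10-20 neighbours. It acts
as a spatial high-pass, rejecting signal common to a neighbourhood (volume
conduction, reference drift) and sharpening locally generated rhythms.
Neighbourhoods are explicit, editable data — never inferred silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MontageError(ValueError):
    """A channel or its neighbourhood is missing or inadequate."""


@dataclass
class Montage:
    """Named electrode set with schematic 2-D positions and a neighbour map.

    ``positions`` maps label -> (x, y) in a unitless head scheme
    (x: left negative, right positive; y: anterior positive).
    ``neighbors`` is kept symmetric: if b is a neighbour of a then a is a
    neighbour of b.
    """

    name: str
    labels: list[str]
    positions: dict[str, tuple[float, float]]
    neighbors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise MontageError("duplicate electrode labels")
        missing = [l for l in self.labels if l not in self.positions]
        if missing:
            raise MontageError(f"labels without positions: {missing}")
        # symmetrize the neighbour relation
        sym: dict[str, set[str]] = {l: set() for l in self.labels}
        for ch, nbrs in self.neighbors.items():
            if ch not in sym:
                raise MontageError(f"neighbour table names unknown channel {ch!r}")
            for n in nbrs:
                if n not in sym:
                    raise MontageError(
                        f"channel {ch!r} lists unknown neighbour {n!r}"
                    )
                sym[ch].add(n)
                sym[n].add(ch)
        self.neighbors = {l: sorted(sym[l]) for l in self.labels}

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage {self.name!r}")

    def subset(self, labels: list[str]) -> "Montage":
        keep = set(labels)
        return Montage(
            name=f"{self.name}-subset",
            labels=list(labels),
            positions={l: self.positions[l] for l in labels},
            neighbors={
                l: [n for n in self.neighbors.get(l, []) if n in keep]
                for l in labels
            },
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "labels": self.labels,
                    "positions": {k: list(v) for k, v in self.positions.items()},
                    "neighbors": self.neighbors,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            labels=d["labels"],
            positions={k: tuple(v) for k, v in d["positions"].items()},
            neighbors=d["neighbors"],
        )


def _grid(rows: dict[float, list[tuple[str, float]]]) -> dict[str, tuple[float, float]]:
    return {lab: (x, y) for y, chans in rows.items() for lab, x in chans}


#: 32-channel 10-20 superset: the 8 centro-parietal analysis channels plus
#: the neighbours the small Laplacian needs.
_POSITIONS = _grid(
    {
        0.6: [("F3", -0.5), ("Fz", 0.0), ("F4", 0.5)],
        0.3: [("FC3", -0.5), ("FC1", -0.25), ("FCz", 0.0), ("FC2", 0.25), ("FC4", 0.5)],
        0.0: [
            ("T7", -1.0), ("C5", -0.75), ("C3", -0.5), ("C1", -0.25), ("Cz", 0.0),
            ("C2", 0.25), ("C4", 0.5), ("C6", 0.75), ("T8", 1.0),
        ],
        -0.3: [("CP3", -0.5), ("CP1", -0.25), ("CPz", 0.0), ("CP2", 0.25), ("CP4", 0.5)],
        -0.6: [
            ("P5", -0.75), ("P3", -0.5), ("P1", -0.25), ("Pz", 0.0),
            ("P2", 0.25), ("P4", 0.5), ("P6", 0.75),
        ],
        -0.9: [("PO3", -0.25), ("POz", 0.0), ("PO4", 0.25)],
    }
)

_NEIGHBORS = {
    "C3": ["C5", "C1", "FC3", "CP3"],
    "Cz": ["C1", "C2", "FCz", "CPz"],
    "C4": ["C2", "C6", "FC4", "CP4"],
    "CP1": ["C1", "CP3", "CPz", "P1"],
    "CP2": ["C2", "CPz", "CP4", "P2"],
    "P3": ["P5", "P1", "CP3", "PO3"],
    "Pz": ["P1", "P2", "CPz", "POz"],
    "P4": ["P2", "P6", "CP4", "PO4"],
}


def default_montage() -> Montage:
    """The shipped 32-channel centro-parietal montage."""
    return Montage(
        name="cp32",
        labels=list(_POSITIONS),
        positions=dict(_POSITIONS),
        neighbors={k: list(v) for k, v in _NEIGHBORS.items()},
    )


@dataclass
class RawEEGRecording:
    """Multi-channel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate_hz: float
    montage: Montage
    annotations: np.ndarray | None = None  # per-sample task code, or None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage.labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{len(self.montage.labels)} labels"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=np.int64)
            if self.annotations.shape != (self.data.shape[1],):
                raise ValueError("annotations must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]


def save_recording_npz(rec: RawEEGRecording, path: str | Path) -> None:
    """Persist a raw recording (data, rate, montage, annotations) as .npz."""
    np.savez(
        path,
        data=rec.data,
        rate_hz=np.array(rec.rate_hz),
        montage_json=np.array(
            json.dumps(
                {
                    "name": rec.montage.name,
                    "labels": rec.montage.labels,
                    "positions": {k: list(v) for k, v in rec.montage.positions.items()},
                    "neighbors": rec.montage.neighbors,
                }
            )
        ),
        annotations=(
            rec.annotations if rec.annotations is not None else np.array([])
        ),
    )


def load_recording_npz(path: str | Path) -> RawEEGRecording:
    with np.load(path, allow_pickle=False) as z:
        d = json.loads(str(z["montage_json"]))
        montage = Montage(
            name=d["name"],
            labels=d["labels"],
            positions={k: tuple(v) for k, v in d["positions"].items()},
            neighbors=d["neighbors"],
        )
        ann = z["annotations"]
        return RawEEGRecording(
            data=z["data"],
            rate_hz=float(z["rate_hz"]),
            montage=montage,
            annotations=None if ann.size == 0 else ann.astype(np.int64),
        )


def surface_laplacian(
    rec: RawEEGRecording, channels: list[str] | None = None
) -> RawEEGRecording:
    """Unweighted small-Laplacian filter.

    For each requested channel c: ``out[c, t] = in[c, t] - mean_n in[n, t]``
    over c's montage neighbours. Channels not requested are dropped from the
    output; annotations pass through unchanged. Channels whose neighbourhood
    is incomplete (< 2 neighbours present) are rejected — zero-padding the
    scalp edge would bias band power.
    """
    if channels is None:
        channels = [c for c in rec.montage.labels if rec.montage.neighbors.get(c)]
    out = np.empty((len(channels), rec.n_samples))
    for i, ch in enumerate(channels):
        idx = rec.montage.index(ch)
        nbrs = rec.montage.neighbors.get(ch, [])
        missing = [n for n in nbrs if n not in rec.montage.labels]
        if missing:
            raise MontageError(f"channel {ch!r}: neighbours missing: {missing}")
        if len(nbrs) < 2:
            raise MontageError(
                f"channel {ch!r} has {len(nbrs)} neighbours; >= 2 required"
            )
        nbr_idx = [rec.montage.index(n) for n in nbrs]
        out[i] = rec.data[idx] - rec.data[nbr_idx].mean(axis=0)
    return RawEEGRecording(
        data=out,
        rate_hz=rec.rate_hz,
        montage=rec.montage.subset(channels),
        annotations=None if rec.annotations is None else rec.annotations.copy(),
    )
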