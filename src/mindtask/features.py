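"""Band-power feature extraction: raw EEG -> 96-dimensional PSD rows.

A sliding 1 s window advanced 16 times per second is taken over the
recording; within each window the power spectral density of each analysis
channel is estimated by Welch's method and aggregated onto 12 bins at
2 Hz resolution spanning 8-30 Hz. With 8 centro-parietal channels this
yields 96 features per window, matching the precomputed-feature layout of
BCI competition III dataset V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sp_signal

from .io_formats import PSD_BIN_HZ, PSD_CHANNELS, PSDFeatureMatrix
from .spatial import RawEEGRecording

#: Conventional EEG frequency bands, Hz (low, high).
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 40.0),
    "gamma": (40.0, float("inf")),
}


def band_definitions() -> dict[str, tuple[float, float]]:
    """Return the conventional EEG band edges in Hz."""
    return dict(EEG_BANDS)


def band_edges(name: str) -> tuple[float, float]:
    try:
        return EEG_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(EEG_BANDS)}"
        ) from None


@dataclass
class PSDConfig:
    """Parameters of the sliding-window Welch band-power extractor.

    Defaults reproduce the competition feature layout: 8-30 Hz at 2 Hz
    resolution over C3, Cz, C4, CP1, CP2, P3, Pz, P4, a 1 s analysis
    window advanced every 62.5 ms (16 rows of features per second).
    """

    band_low_hz: float = 8.0
    band_high_hz: float = 30.0
    resolution_hz: float = 2.0
    window_s: float = 1.0
    step_s: float = 0.0625
    channels: tuple[str, ...] = PSD_CHANNELS
    welch_segment_s: float = 0.5
    welch_overlap_fraction: float = 0.5
    welch_window: str = "boxcar"
    detrend: str = "constant"

    def __post_init__(self) -> None:
        n_bins = (self.band_high_hz - self.band_low_hz) / self.resolution_hz + 1
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("band range must be an integer number of bins")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if self.window_s < 1.0 / self.resolution_hz:
            raise ValueError("window shorter than 1/resolution cannot resolve bins")
        if not 0 <= self.welch_overlap_fraction < 1:
            raise ValueError("welch_overlap_fraction must be in [0, 1)")

    @property
    def bin_centers_hz(self) -> np.ndarray:
        return np.arange(
            self.band_low_hz, self.band_high_hz + self.resolution_hz / 2,
            self.resolution_hz,
        )

    @property
    def n_features(self) -> int:
        return len(self.channels) * len(self.bin_centers_hz)


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    if n_samples < win:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - win + 1, step)


def extract_psd(
    rec: RawEEGRecording,
    cfg: PSDConfig | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> PSDFeatureMatrix:
    """Slide a window over ``rec`` and emit one band-power row per window.

    Each row is labelled with the task annotation at the window's final
    sample; windows spanning a task boundary are dropped rather than
    majority-labelled. A recording shorter than one window yields an empty
    matrix with a warning. Rows are ordered by window start time.
    """
    cfg = cfg or PSDConfig()
    missing = [c for c in cfg.channels if c not in rec.montage.labels]
    if missing:
        raise ValueError(f"channels absent from recording: {missing}")

    win = int(round(cfg.window_s * rec.rate_hz))
    step = int(round(cfg.step_s * rec.rate_hz))
    if step < 1:
        raise ValueError("step_s shorter than one sample at this rate")
    starts = _window_starts(rec.n_samples, win, step)
    if starts.size == 0:
        warnings.warn("recording shorter than one analysis window; empty output")
        return PSDFeatureMatrix(
            values=np.empty((0, cfg.n_features)),
            subject_id=subject_id,
            session_id=session_id,
        )

    ch_idx = [rec.montage.index(c) for c in cfg.channels]
    data = rec.data[ch_idx]  # (n_ch, n_samples)

    # windows crossing an annotation boundary are dropped
    if rec.annotations is not None:
        ann = rec.annotations
        keep = np.array(
            [np.all(ann[s : s + win] == ann[s + win - 1]) for s in starts]
        )
        starts = starts[keep]
        labels = ann[starts + win - 1] if starts.size else np.empty(0, np.int64)
    else:
        labels = np.empty(0, dtype=np.int64)

    # (n_win, n_ch, win) stack, one Welch call over the last axis
    windows = np.stack([data[:, s : s + win] for s in starts], axis=0) \
        if starts.size else np.empty((0, len(ch_idx), win))
    nperseg = min(int(round(cfg.welch_segment_s * rec.rate_hz)), win)
    noverlap = int(round(nperseg * cfg.welch_overlap_fraction))
    freqs, psd = sp_signal.welch(
        windows,
        fs=rec.rate_hz,
        window=cfg.welch_window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=cfg.detrend,
        axis=-1,
    )

    # aggregate spectral lines onto the 2 Hz bins centred at 8..30 Hz
    half = cfg.resolution_hz / 2
    n_win, n_ch = psd.shape[0], psd.shape[1]
    values = np.empty((n_win, n_ch, len(cfg.bin_centers_hz)))
    for b, fc in enumerate(cfg.bin_centers_hz):
        sel = (freqs > fc - half) & (freqs <= fc + half)
        if not np.any(sel):
            sel = np.zeros_like(freqs, dtype=bool)
            sel[np.argmin(np.abs(freqs - fc))] = True
        values[:, :, b] = psd[:, :, sel].mean(axis=-1)

    out = PSDFeatureMatrix(
        values=values.reshape(n_win, -1),
        labels=labels,
        subject_id=subject_id,
        session_id=session_id,
    )
    return out


def band_power_from_features(
    matrix: PSDFeatureMatrix, cfg: PSDConfig | None = None
) -> np.ndarray:
    """Integrated 8-30 Hz band power per row and channel (µV²).

    Sums PSD bins times the bin width; shape (n_rows, n_channels).
    """
    cfg = cfg or PSDConfig()
    n_bins = len(cfg.bin_centers_hz)
    cube = matrix.values.reshape(matrix.n_rows, len(cfg.channels), n_bins)
    return cube.sum(axis=2) * cfg.resolution_hz
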