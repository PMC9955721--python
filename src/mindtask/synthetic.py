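"""Seeded synthetic multi-subject EEG with task-dependent band power.

The generator emulates the statistical shape of a three-class imagined
mental-task study: three subjects, three labelled sessions each, balanced
trials of imagined left-hand movement, imagined right-hand movement and
word generation. Each channel is a sum of band-limited sinusoids whose
power follows a 1/f-sloped baseline spectrum times a task-specific
modulation (mu/beta desynchronisation contralateral to the imagined hand;
a parietal signature for word generation), plus pink background noise,
a common-mode component shared by all channels, and white sensor noise.

Inter-subject variability — the phenomenon cross-subject averaging
targets — enters as per-channel multiplicative gains and per-band additive
baseline offsets drawn once per subject. All randomness flows from a
single seed through ``numpy.random.SeedSequence``; per-subject streams are
keyed by a CRC-32 of the subject identifier, so regenerating a cohort
with the subjects listed in a different order changes nothing but order.

Every default here is a fixture parameter describing the simulated study,
not an estimate of any real recording.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import CLASS_NAMES, PSD_BIN_HZ, PSD_CHANNELS
from .spatial import Montage, RawEEGRecording, default_montage

#: Internal task codes, aligned with CLASS_NAMES order.
TASK_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class TaskSignature:
    """Multiplicative band-power modulation of one mental task.

    ``band_modulation`` maps ``(channel, bin_hz)`` to a positive factor
    applied to that channel/bin's baseline power while the task is
    performed; unlisted pairs are unmodulated (factor 1).
    """

    task_class: str
    band_modulation: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        if self.task_class not in TASK_CODES:
            raise ValueError(f"unknown task class {self.task_class!r}")
        if any(v <= 0 for v in self.band_modulation.values()):
            raise ValueError("modulations must be positive")

    def factor(self, channel: str, bin_hz: int) -> float:
        return self.band_modulation.get((channel, bin_hz), 1.0)


def default_task_signatures() -> dict[str, TaskSignature]:
    """Fixture signatures for the three tasks.

    Imagined hand movement suppresses mu (10-12 Hz) and, more weakly, beta
    (20-22 Hz) power over the contralateral sensorimotor channels; word
    generation suppresses parietal alpha at P3 and enhances beta at Pz.
    """
    left = {
        ("C4", 10): 0.15, ("C4", 12): 0.15, ("C4", 20): 0.35, ("C4", 22): 0.35,
        ("CP2", 10): 0.3, ("CP2", 12): 0.3,
    }
    right = {
        ("C3", 10): 0.15, ("C3", 12): 0.15, ("C3", 20): 0.35, ("C3", 22): 0.35,
        ("CP1", 10): 0.3, ("CP1", 12): 0.3,
    }
    word = {
        ("P3", 10): 0.25, ("P3", 12): 0.25,
        ("Pz", 18): 2.5, ("Pz", 20): 2.5, ("Pz", 22): 2.5,
    }
    return {
        "left": TaskSignature("left", left),
        "right": TaskSignature("right", right),
        "word": TaskSignature("word", word),
    }


def _base_density(bin_hz: np.ndarray, slope: float = 1.0) -> np.ndarray:
    """Baseline PSD height (µV²/Hz) at each bin: 30 µV²/Hz at 10 Hz, 1/f slope."""
    return 30.0 * (10.0 / np.asarray(bin_hz, dtype=float)) ** slope


@dataclass
class SubjectProfile:
    """Per-subject signal statistics.

    ``channel_gain`` multiplies band power per channel; ``baseline_band_power``
    is the resting PSD height per (channel, bin) in µV²/Hz after the
    subject's additive offsets; ``noise_scale`` is the white-noise standard
    deviation in µV; ``one_over_f_exponent`` shapes the pink background.
    """

    subject_id: str
    channel_gain: dict[str, float]
    baseline_band_power: np.ndarray  # (n_channels, n_bins) for montage order
    noise_scale: float = 5.0
    one_over_f_exponent: float = 1.0
    pink_scale: float = 4.0        # per-channel 1/f background, µV std
    common_mode_scale: float = 5.0  # background shared by all channels, µV std
    trial_power_jitter: float = 0.15  # log-normal sigma of per-trial band power
    phase_jitter: float = 0.1  # per-channel phase decoherence, radians

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.channel_gain.values()):
            raise ValueError("channel gains must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        self.baseline_band_power = np.asarray(self.baseline_band_power, float)
        if np.any(self.baseline_band_power < 0):
            raise ValueError("baseline band power must be non-negative")


@dataclass
class CohortSpec:
    """Shape and seed of a synthetic study."""

    n_subjects: int = 3
    n_sessions_per_subject: int = 3
    trials_per_task_per_session: int = 8
    trial_duration_s: float = 1.5
    sampling_rate_hz: float = 512.0
    montage_name: str = "cp32"
    seed: int = 0
    gain_sigma: float = 0.8        # log-normal sigma of per-channel gains
    offset_rel_sigma: float = 0.6  # relative sigma of additive per-band offsets

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects, self.n_sessions_per_subject,
            self.trials_per_task_per_session,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.sampling_rate_hz < 2 * max(PSD_BIN_HZ):
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz below Nyquist for "
                f"{max(PSD_BIN_HZ)} Hz content"
            )


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode())


def make_subject_profiles(
    subject_ids: list[str],
    spec: CohortSpec,
    montage: Montage | None = None,
) -> list[SubjectProfile]:
    """Draw one profile per subject from the cohort's variability model.

    Gains are log-normal with sigma ``spec.gain_sigma``; baselines are the
    1/f template plus additive normal offsets of relative sigma
    ``spec.offset_rel_sigma`` (clipped at a small positive floor). Streams
    are keyed by subject id, not list position.
    """
    montage = montage or default_montage()
    bins = np.asarray(PSD_BIN_HZ, float)
    base = _base_density(bins)
    profiles = []
    for sid in subject_ids:
        rng = np.random.default_rng(
            np.random.SeedSequence((spec.seed, _subject_key(sid), 0))
        )
        gains = {
            ch: float(np.exp(spec.gain_sigma * rng.standard_normal()))
            for ch in montage.labels
        }
        offsets = spec.offset_rel_sigma * base * rng.standard_normal(
            (len(montage.labels), bins.size)
        )
        baseline = np.clip(base[None, :] + offsets, 0.5, None)
        profiles.append(
            SubjectProfile(
                subject_id=sid, channel_gain=gains, baseline_band_power=baseline
            )
        )
    return profiles


def analytic_band_power(
    profile: SubjectProfile,
    signature: TaskSignature,
    montage: Montage | None = None,
    channels: tuple[str, ...] = PSD_CHANNELS,
    resolution_hz: float = 2.0,
) -> np.ndarray:
    """Integrated sinusoid power (µV²) per (channel, bin) for one task.

    This is the generator's ground truth: amplitude²/2 of each synthesized
    component, before background and sensor noise.
    """
    montage = montage or default_montage()
    out = np.empty((len(channels), len(PSD_BIN_HZ)))
    for i, ch in enumerate(channels):
        row = montage.index(ch)
        for b, f in enumerate(PSD_BIN_HZ):
            out[i, b] = (
                profile.channel_gain[ch]
                * profile.baseline_band_power[row, b]
                * signature.factor(ch, f)
                * resolution_hz
            )
    return out


def _pink_noise(rng: np.random.Generator, n: int, rate: float, exponent: float,
                scale: float) -> np.ndarray:
    """1/f^exponent noise of unit-free std ``scale``, seeded."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = (freqs[nz] / 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def generate_trial(
    profile: SubjectProfile,
    signature: TaskSignature,
    duration_s: float,
    rate_hz: float,
    seed: int | np.random.SeedSequence,
    montage: Montage | None = None,
    session_gain: float = 1.0,
) -> RawEEGRecording:
    """Synthesize one constant-task trial on the full montage.

    Per channel: one sinusoid per 2 Hz bin with random phase and amplitude
    ``sqrt(2 * gain * baseline * modulation * bin_width)``, plus pink and
    white noise, plus a common-mode background shared across channels.
    Annotations are the task code at every sample.
    """
    montage = montage or default_montage()
    if rate_hz < 2 * max(PSD_BIN_HZ):
        raise ValueError("sampling rate below Nyquist for synthesized bands")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    n_ch = len(montage.labels)
    bins = np.asarray(PSD_BIN_HZ, float)

    # one random phase per rhythm per trial, shared across the scalp
    # (volume-conducted rhythms are spatially coherent), plus a small
    # per-channel decoherence
    band_phases = rng.uniform(0, 2 * np.pi, size=bins.size)
    phases = band_phases[None, :] + profile.phase_jitter * rng.standard_normal(
        (n_ch, bins.size)
    )
    # per-trial band-power fluctuation, mean one: a single imagined trial is
    # never a clean copy of the subject's average rhythm
    jit = profile.trial_power_jitter
    jitter = np.exp(
        jit * rng.standard_normal((n_ch, bins.size)) - jit ** 2 / 2.0
    )
    data = np.zeros((n_ch, n))
    for i, ch in enumerate(montage.labels):
        power = (
            session_gain
            * profile.channel_gain[ch]
            * profile.baseline_band_power[i]
            * np.array([signature.factor(ch, int(f)) for f in bins])
            * jitter[i]
            * 2.0  # bin width, Hz
        )
        amp = np.sqrt(2.0 * power)
        data[i] = (amp[:, None] * np.sin(
            2 * np.pi * bins[:, None] * t[None, :] + phases[:, :, None][i]
        )).sum(axis=0)
        data[i] += _pink_noise(
            rng, n, rate_hz, profile.one_over_f_exponent, profile.pink_scale
        )
        if profile.noise_scale > 0:
            data[i] += profile.noise_scale * rng.standard_normal(n)
    if profile.common_mode_scale > 0:
        data += _pink_noise(
            rng, n, rate_hz, profile.one_over_f_exponent,
            profile.common_mode_scale,
        )[None, :]

    code = TASK_CODES[signature.task_class]
    return RawEEGRecording(
        data=data,
        rate_hz=rate_hz,
        montage=montage,
        annotations=np.full(n, code, dtype=np.int64),
    )


@dataclass
class TrialRecord:
    """One generated trial with its provenance."""

    subject_id: str
    session_id: str
    task: int  # internal code
    recording: RawEEGRecording


def generate_cohort(
    spec: CohortSpec,
    profiles: list[SubjectProfile] | None = None,
    signatures: dict[str, TaskSignature] | None = None,
    session_gain_sigma: float = 0.05,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Generate a full multi-subject study plus its ground-truth manifest.

    Returns the trials (balanced classes within every session) and a
    manifest DataFrame with one row per trial carrying subject, session,
    task and the analytic per-(channel, bin) band powers ``bp_<ch>_<hz>``
    for the eight analysis channels.
    """
    montage = default_montage()
    subject_ids = [f"s{i + 1}" for i in range(spec.n_subjects)]
    if profiles is None:
        profiles = make_subject_profiles(subject_ids, spec, montage)
    if len(profiles) != spec.n_subjects:
        raise ValueError("profiles length must equal n_subjects")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject_ids: {ids}")
    signatures = signatures or default_task_signatures()

    trials: list[TrialRecord] = []
    rows = []
    for profile in profiles:
        skey = _subject_key(profile.subject_id)
        for sess in range(spec.n_sessions_per_subject):
            session_id = f"sess{sess + 1}"
            g_rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, skey, 1, sess))
            )
            session_gain = float(
                np.exp(session_gain_sigma * g_rng.standard_normal())
            )
            counter = 0
            for task_name in CLASS_NAMES:
                sig = signatures[task_name]
                bp = analytic_band_power(profile, sig, montage)
                for k in range(spec.trials_per_task_per_session):
                    ss = np.random.SeedSequence(
                        (spec.seed, skey, 2, sess, counter)
                    )
                    rec = generate_trial(
                        profile, sig, spec.trial_duration_s,
                        spec.sampling_rate_hz, ss, montage,
                        session_gain=session_gain,
                    )
                    trials.append(
                        TrialRecord(profile.subject_id, session_id,
                                    TASK_CODES[task_name], rec)
                    )
                    row = {
                        "subject": profile.subject_id,
                        "session": session_id,
                        "trial": counter,
                        "task": TASK_CODES[task_name],
                        "task_name": task_name,
                        "session_gain": session_gain,
                    }
                    row.update({
                        f"bp_{ch}_{hz}": bp[i, b] * session_gain
                        for i, ch in enumerate(PSD_CHANNELS)
                        for b, hz in enumerate(PSD_BIN_HZ)
                    })
                    rows.append(row)
                    counter += 1
    return trials, pd.DataFrame(rows)


def zero_shift_spec(spec: CohortSpec) -> CohortSpec:
    """The same study with inter-subject variability switched off."""
    return replace(spec, gain_sigma=0.0, offset_rel_sigma=0.0)
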