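"""Synthetic three-channel surface-EMG session generator.

Emulates the recording protocol the rest of the pipeline assumes: 20 kHz raw
acquisition, 2 s trials of six elbow/shoulder motions, 50 repetitions per
motion per session, a 70/30 stratified train/test split, plus rest and
contraction calibration segments.

Signal model per channel::

    x(t) = envelope(t) * gain[motion, channel] * jitter * n_band(t)
           + mains_amplitude * sin(2*pi*50*t)
           + drift_amplitude * sin(2*pi*drift_freq*t + phase)
           + sensor_noise_sd * n_white(t)

where ``n_band`` is unit-RMS Gaussian noise band-limited to 20–450 Hz (the
physiological sEMG band) and ``envelope`` is a raised-cosine
rise–hold–fall profile over the trial, reflecting a motion completed at a
constant rate within the trial. The per-trial lognormal gain jitter models
repetition-to-repetition force variability around a comfortable 30–40% MVC
effort level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .motions import CHANNEL_NAMES, N_CLASSES, MotionClass, as_motion

__all__ = [
    "SynthParams",
    "Recording",
    "LabeledDataset",
    "default_envelope_gains",
    "make_trial",
    "make_rest_calibration",
    "make_contraction_calibration",
    "make_session",
    "save_recording",
    "load_recording",
    "save_dataset",
    "load_dataset",
]


def default_envelope_gains() -> np.ndarray:
    """Per-motion, per-channel activation amplitudes (6 x 3).

    Rows follow the MotionClass encoding; columns are (biceps, triceps,
    deltoid). Single-joint rows encode the dominant muscle for each motion
    (EF biceps, EE triceps, SF/SE deltoid with SE the stronger concentric
    contraction); the compound rows ESF/ESE are the sums of their constituent
    single-joint rows, so they correlate with them and keep the classes
    separable but overlapping.
    """
    ef = np.array([1.00, 0.15, 0.20])
    ee = np.array([0.15, 1.00, 0.20])
    sf = np.array([0.20, 0.25, 0.70])
    se = np.array([0.25, 0.20, 1.00])
    return np.vstack([ef, ee, sf, se, ef + sf, ee + se])


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Parameters
    ----------
    sampling_rate : float
        Raw acquisition rate in Hz. The acquisition card runs at 20 kHz.
    trial_duration : float
        Trial length in seconds; motions are completed within 2 s.
    envelope_gains : ndarray of shape (6, 3)
        Per-motion per-channel activation amplitude (normalized mV scale).
    mains_amplitude : float
        Amplitude of the additive 50 Hz mains line, as a fraction of unit
        signal amplitude.
    mains_freq : float
        Mains frequency in Hz.
    drift_amplitude, drift_freq : float
        Baseline-wander sinusoid amplitude and frequency (Hz).
    sensor_noise_sd : float
        Standard deviation of additive white sensor noise.
    gain_jitter_sd : float
        Sigma of the lognormal per-trial, per-channel multiplicative gain
        jitter (repetition-to-repetition force variability).
    ramp_time : float
        Raised-cosine rise/fall time of the activation envelope, seconds.
    band : (float, float)
        Physiological band of the EMG carrier noise, Hz.
    """

    sampling_rate: float = 20_000.0
    trial_duration: float = 2.0
    envelope_gains: np.ndarray = field(default_factory=default_envelope_gains)
    mains_amplitude: float = 0.10
    mains_freq: float = 50.0
    drift_amplitude: float = 0.05
    drift_freq: float = 0.5
    sensor_noise_sd: float = 0.02
    gain_jitter_sd: float = 0.15
    ramp_time: float = 0.25
    band: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self):
        gains = np.asarray(self.envelope_gains, dtype=float)
        if gains.shape != (N_CLASSES, len(CHANNEL_NAMES)):
            raise ValueError(f"envelope_gains must be 6x3, got {gains.shape}")
        if np.any(gains < 0):
            raise ValueError("envelope_gains must be non-negative")
        if len({tuple(row) for row in gains}) != N_CLASSES:
            raise ValueError("envelope_gains rows must be pairwise distinct")
        object.__setattr__(self, "envelope_gains", gains)
        if self.sampling_rate < 2000:
            raise ValueError("sampling_rate must be >= 2 kHz")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")


@dataclass
class Recording:
    """A multi-channel sampled signal.

    ``samples`` is a (channels, time) float array; ``kind`` distinguishes
    motion trials from the rest / contraction calibration segments recorded
    at the pre-collection stage.
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str] = CHANNEL_NAMES
    label: MotionClass | None = None
    kind: str = "trial"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("one row of samples per channel required")
        if self.label is not None:
            self.label = as_motion(self.label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class LabeledDataset:
    """A session's labeled trials with a stratified train/test assignment."""

    recordings: list[Recording]
    split_assignment: list[str]  # "train" / "test" per trial recording
    rest_calibration: Recording
    contraction_calibration: Recording
    repetitions: int
    split_fraction: float

    def trials(self, split: str | None = None) -> list[Recording]:
        if split is None:
            return list(self.recordings)
        return [r for r, s in zip(self.recordings, self.split_assignment) if s == split]

    def labels(self, split: str | None = None) -> np.ndarray:
        return np.array([int(r.label) for r in self.trials(split)])


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``.

    A sharp linear-phase FIR keeps >= 95% of the trial's periodogram power
    inside the physiological band even after envelope modulation.
    """
    white = rng.standard_normal(n)
    hi = min(band[1], 0.99 * fs / 2.0)
    taps = signal.firwin(2049, [band[0], hi], pass_zero=False, fs=fs)
    x = signal.fftconvolve(white, taps, mode="same")
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _envelope(n: int, fs: float, ramp_time: float) -> np.ndarray:
    """Raised-cosine rise–hold–fall activation profile over n samples."""
    t = np.arange(n) / fs
    total = n / fs
    ramp = min(ramp_time, total / 2)
    env = np.ones(n)
    rise = t < ramp
    env[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / ramp))
    fall = t > total - ramp
    env[fall] = 0.5 * (1 - np.cos(np.pi * (total - t[fall]) / ramp))
    return env


def _trial_channels(motion: MotionClass, params: SynthParams,
                    rng: np.random.Generator, active: bool = True,
                    duration: float | None = None,
                    jitter: bool = True) -> np.ndarray:
    dur = params.trial_duration if duration is None else duration
    n = int(round(dur * params.sampling_rate))
    if n <= 0:
        raise ValueError("non-positive trial duration")
    t = np.arange(n) / params.sampling_rate
    env = _envelope(n, params.sampling_rate, params.ramp_time) if active else 0.0
    gains = params.envelope_gains[int(motion)] if active else np.zeros(3)
    chans = np.empty((len(CHANNEL_NAMES), n))
    for c in range(len(CHANNEL_NAMES)):
        g = gains[c]
        if jitter and active and params.gain_jitter_sd > 0:
            g = g * rng.lognormal(mean=0.0, sigma=params.gain_jitter_sd)
        emg = env * g * _bandlimited_noise(rng, n, params.sampling_rate, params.band) \
            if active else np.zeros(n)
        mains = params.mains_amplitude * np.sin(
            2 * np.pi * params.mains_freq * t + rng.uniform(0, 2 * np.pi))
        drift = params.drift_amplitude * np.sin(
            2 * np.pi * params.drift_freq * t + rng.uniform(0, 2 * np.pi))
        noise = params.sensor_noise_sd * rng.standard_normal(n)
        chans[c] = emg + mains + drift + noise
    return chans


def make_trial(motion, params: SynthParams | None = None, seed: int = 0) -> Recording:
    """Generate one labeled 2 s motion trial.

    Identical (motion, params, seed) reproduce the signal bit-for-bit.
    """
    params = params or SynthParams()
    motion = as_motion(motion)
    rng = np.random.default_rng(seed)
    samples = _trial_channels(motion, params, rng)
    return Recording(samples, params.sampling_rate, CHANNEL_NAMES, motion, "trial")


def make_rest_calibration(params: SynthParams | None = None, seed: int = 0,
                          duration: float = 5.0) -> Recording:
    """Rest segment (noise + interference only) from the pre-collection stage."""
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    samples = _trial_channels(MotionClass.EF, params, rng, active=False,
                              duration=duration)
    return Recording(samples, params.sampling_rate, CHANNEL_NAMES, None,
                     "rest_calibration")


def make_contraction_calibration(params: SynthParams | None = None,
                                 seed: int = 0) -> Recording:
    """Contraction calibration: one trial per motion at default gains, concatenated.

    Gain jitter is disabled so the calibration reflects the nominal effort
    level that normalization and trigger thresholds reference.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    parts = [_trial_channels(m, params, rng, jitter=False) for m in MotionClass]
    return Recording(np.concatenate(parts, axis=1), params.sampling_rate,
                     CHANNEL_NAMES, None, "contraction_calibration")


def make_session(params: SynthParams | None = None, repetitions: int = 50,
                 split_fraction: float = 0.7, seed: int = 0) -> LabeledDataset:
    """Generate a full session: repetitions x 6 labeled trials plus calibration.

    The train/test split is stratified per motion with per-motion train count
    round(split_fraction * repetitions); at the 50-repetition protocol this is
    the canonical 210/90 (35/15 per motion) split. Deterministic under seed.
    """
    params = params or SynthParams()
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    root = np.random.default_rng(seed)
    # independent child seeds, kept below 2**31
    trial_seeds = root.integers(0, 2**31 - 1, size=repetitions * N_CLASSES)
    recordings: list[Recording] = []
    splits: list[str] = []
    # conventional half-up rounding: preserves 35/15 at the 50-rep protocol
    # and keeps one trial per motion in train at repetitions=1, split=0.5
    n_train = int(np.floor(split_fraction * repetitions + 0.5))
    n_train = min(max(n_train, 1), repetitions - 1) if repetitions > 1 else n_train
    k = 0
    for motion in MotionClass:
        # per-motion shuffle of which repetitions land in train
        order = root.permutation(repetitions)
        assign = np.array(["test"] * repetitions, dtype=object)
        assign[order[:n_train]] = "train"
        for rep in range(repetitions):
            recordings.append(make_trial(motion, params, int(trial_seeds[k])))
            splits.append(str(assign[rep]))
            k += 1
    rest = make_rest_calibration(params, seed=int(root.integers(0, 2**31 - 1)))
    contraction = make_contraction_calibration(
        params, seed=int(root.integers(0, 2**31 - 1)))
    return LabeledDataset(recordings, splits, rest, contraction,
                          repetitions, split_fraction)


# ---------------------------------------------------------------------------
# File formats: delimited text per recording + JSON sidecar + dataset manifest


def save_recording(rec: Recording, path: str | Path, seed: int | None = None) -> None:
    """Write a recording as CSV (one column per channel) + JSON sidecar."""
    path = Path(path)
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.samples.T, delimiter=",", header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "label": rec.label.name if rec.label is not None else None,
        "kind": rec.kind,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    names = path.read_text().splitlines()[0].split(",")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    label = as_motion(meta["label"]) if meta.get("label") else None
    return Recording(np.atleast_2d(data).T if data.ndim == 1 else data.T,
                     meta["fs"], names, label, meta.get("kind", "trial"))


def save_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write all recordings plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (rec, split) in enumerate(zip(ds.recordings, ds.split_assignment)):
        fname = f"trial_{i:04d}_{rec.label.name}.csv"
        save_recording(rec, out / fname)
        entries.append({"file": fname, "split": split, "label": rec.label.name})
    save_recording(ds.rest_calibration, out / "rest_calibration.csv")
    save_recording(ds.contraction_calibration, out / "contraction_calibration.csv")
    manifest = {
        "repetitions": ds.repetitions,
        "split_fraction": ds.split_fraction,
        "rest_calibration": "rest_calibration.csv",
        "contraction_calibration": "contraction_calibration.csv",
        "trials": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.json"
    manifest = json.loads(mpath.read_text())
    root = mpath.parent
    recs = [load_recording(root / e["file"]) for e in manifest["trials"]]
    splits = [e["split"] for e in manifest["trials"]]
    rest = load_recording(root / manifest["rest_calibration"])
    contraction = load_recording(root / manifest["contraction_calibration"])
    return LabeledDataset(recs, splits, rest, contraction,
                          manifest["repetitions"], manifest["split_fraction"])
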