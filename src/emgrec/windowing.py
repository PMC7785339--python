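"""Sliding analysis windows and the MAV motion trigger.

Preprocessed 1 kHz signals are segmented into 192 ms analysis windows advanced
by a 15 ms slide. A window is deemed to contain motion intent when any
channel's mean absolute value exceeds its threshold — 75% of the mean
per-window MAV measured on the contraction calibration at the pre-collection
stage. The triggering window plus the next two windows form a Burst, the unit
on which one classification decision is made; detection then resumes after the
burst's last window so each motion yields one decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CalibrationProfile
from .synth import Recording

__all__ = [
    "WindowConfig",
    "AnalysisWindow",
    "TriggerThresholds",
    "Burst",
    "sliding_windows",
    "calibrate_thresholds",
    "detect_bursts",
    "StreamingTrigger",
]


@dataclass(frozen=True)
class WindowConfig:
    """Analysis-window geometry and trigger settings.

    window_ms=192 and slide_ms=15 give the 576-point (192 x 3) window at
    1 kHz and a 222 ms acquisition span for a three-window decision.
    """

    window_ms: float = 192.0
    slide_ms: float = 15.0
    windows_per_decision: int = 3
    trigger_fraction: float = 0.75
    retrigger: str = "immediate"

    def __post_init__(self):
        if self.slide_ms > self.window_ms:
            raise ValueError("slide_ms must be <= window_ms")
        if self.windows_per_decision % 2 != 1 or self.windows_per_decision < 1:
            raise ValueError("windows_per_decision must be odd and positive")
        if not 0 <= self.trigger_fraction:
            raise ValueError("trigger_fraction must be non-negative")
        if self.retrigger not in ("immediate", "rearm"):
            raise ValueError("retrigger must be 'immediate' or 'rearm'")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def slide_samples(self, fs: float) -> int:
        return int(round(self.slide_ms * fs / 1000.0))

    @property
    def acquisition_ms(self) -> float:
        """Signal span from window start to the last decision window's end."""
        return self.window_ms + (self.windows_per_decision - 1) * self.slide_ms


@dataclass
class AnalysisWindow:
    """One fixed-length slice of all channels of a preprocessed recording."""

    samples: np.ndarray  # (channels, window_samples)
    start_time: float  # ms
    window_index: int

    @property
    def n_points(self) -> int:
        """Total data points across channels (192 x 3 = 576 at defaults)."""
        return int(self.samples.size)

    def mav(self) -> np.ndarray:
        """Per-channel mean absolute value of this window."""
        return np.mean(np.abs(self.samples), axis=1)


@dataclass
class TriggerThresholds:
    """Per-channel MAV thresholds (normalized amplitude units)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("thresholds must be non-negative")


@dataclass
class Burst:
    """windows_per_decision consecutive windows following a trigger."""

    windows: list[AnalysisWindow]
    trigger_time: float  # ms, start time of the triggering window

    def __post_init__(self):
        idx = [w.window_index for w in self.windows]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("burst windows must have consecutive indices")

    def stacked(self) -> np.ndarray:
        """(n_windows, channels, window_samples) array for classification."""
        return np.stack([w.samples for w in self.windows])


def sliding_windows(rec: Recording, cfg: WindowConfig) -> list[AnalysisWindow]:
    """Segment a preprocessed recording into overlapping analysis windows.

    Windows start at 0, slide, 2*slide, ...; a recording shorter than one
    window yields an empty list. Count = floor((L - W) / S) + 1.
    """
    w = cfg.window_samples(rec.fs)
    s = cfg.slide_samples(rec.fs)
    n = rec.n_samples
    if n < w:
        return []
    out = []
    for i, start in enumerate(range(0, n - w + 1, s)):
        out.append(AnalysisWindow(rec.samples[:, start:start + w],
                                  start_time=start * 1000.0 / rec.fs,
                                  window_index=i))
    return out


def calibrate_thresholds(calib_contraction: Recording | CalibrationProfile,
                         cfg: WindowConfig,
                         fs: float | None = None) -> TriggerThresholds:
    """Per-channel threshold = trigger_fraction x mean calibration-window MAV.

    Accepts either a preprocessed contraction recording (windowed here) or a
    ready CalibrationProfile whose contraction_mav is reused.
    """
    if isinstance(calib_contraction, CalibrationProfile):
        return TriggerThresholds(cfg.trigger_fraction *
                                 calib_contraction.contraction_mav)
    windows = sliding_windows(calib_contraction, cfg)
    if not windows:
        raise ValueError("calibration recording shorter than one window")
    mavs = np.stack([w.mav() for w in windows])
    return TriggerThresholds(cfg.trigger_fraction * mavs.mean(axis=0))


def detect_bursts(windows: list[AnalysisWindow], thresholds: TriggerThresholds,
                  cfg: WindowConfig) -> list[Burst]:
    """Scan ordered windows for motion intent and group them into bursts.

    A window triggers when any channel's MAV exceeds its threshold; it and the
    next windows_per_decision - 1 windows form a Burst. If fewer windows
    remain, the trigger is discarded. After a burst, scanning resumes at the
    window following the burst's last window ("immediate" retrigger); with
    cfg.retrigger = "rearm" the trigger additionally waits for an all-channel
    sub-threshold window before it can fire again, so one sustained
    contraction yields exactly one decision.
    """
    bursts: list[Burst] = []
    k = cfg.windows_per_decision
    armed = True
    i = 0
    while i < len(windows):
        hot = bool(np.any(windows[i].mav() > thresholds.values))
        if hot and armed:
            if i + k > len(windows):
                break  # not enough windows left to complete a decision
            bursts.append(Burst(windows[i:i + k], windows[i].start_time))
            i += k
            if cfg.retrigger == "rearm":
                armed = False
        else:
            if not hot:
                armed = True
            i += 1
    return bursts


class StreamingTrigger:
    """Incremental windowing + burst detection over a sample stream.

    Buffers preprocessed samples, emits each analysis window as soon as it is
    complete, and applies the same trigger/refractory rule as
    :func:`detect_bursts`, so chunked streaming reproduces the batch burst
    sequence exactly.
    """

    def __init__(self, fs: float, n_channels: int, thresholds: TriggerThresholds,
                 cfg: WindowConfig):
        self.fs = fs
        self.cfg = cfg
        self.thresholds = thresholds
        self._buf = np.empty((n_channels, 0))
        self._next_start = 0  # absolute sample index of the next window start
        self._consumed = 0  # samples dropped from the left of the buffer
        self._window_index = 0
        self._pending: list[AnalysisWindow] = []  # windows of an open burst
        self._skip_until = -1  # window index to resume scanning at
        self._armed = True

    def push(self, chunk: np.ndarray) -> list[Burst]:
        """Feed preprocessed samples; return any bursts completed."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        self._buf = np.concatenate([self._buf, chunk], axis=1)
        w = self.cfg.window_samples(self.fs)
        s = self.cfg.slide_samples(self.fs)
        out: list[Burst] = []
        while self._next_start + w <= self._consumed + self._buf.shape[1]:
            lo = self._next_start - self._consumed
            win = AnalysisWindow(self._buf[:, lo:lo + w].copy(),
                                 start_time=self._next_start * 1000.0 / self.fs,
                                 window_index=self._window_index)
            burst = self._scan(win)
            if burst is not None:
                out.append(burst)
            self._window_index += 1
            self._next_start += s
            drop = self._next_start - self._consumed
            if drop > 0:
                self._buf = self._buf[:, drop:]
                self._consumed = self._next_start
        return out

    def _scan(self, win: AnalysisWindow) -> Burst | None:
        k = self.cfg.windows_per_decision
        if self._pending:
            self._pending.append(win)
            if len(self._pending) == k:
                burst = Burst(self._pending, self._pending[0].start_time)
                self._pending = []
                self._skip_until = win.window_index + 1
                if self.cfg.retrigger == "rearm":
                    self._armed = False
                return burst
            return None
        hot = bool(np.any(win.mav() > self.thresholds.values))
        if win.window_index < self._skip_until:
            if not hot:
                self._armed = True
            return None
        if hot and self._armed:
            if k == 1:
                self._skip_until = win.window_index + 1
                if self.cfg.retrigger == "rearm":
                    self._armed = False
                return Burst([win], win.start_time)
            self._pending = [win]
        elif not hot:
            self._armed = True
        return None
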