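"""End-to-end offline experiment plumbing.

Glues the stages together for the standard study protocol: preprocess a
labeled session against its calibration recordings, derive trigger
thresholds, extract supra-threshold training windows, and score a classifier
at the burst level (one three-window majority-vote decision per trial, the
same granularity at which a motion execution produces one command).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import confusion
from .preprocess import (CalibrationProfile, PreprocessConfig, build_calibration,
                         run_chain)
from .synth import LabeledDataset, Recording
from .windowing import (TriggerThresholds, WindowConfig, calibrate_thresholds,
                        detect_bursts, sliding_windows)

__all__ = ["PreparedSession", "prepare_session", "training_windows",
           "decision_windows", "evaluate_bursts"]


@dataclass
class PreparedSession:
    """Preprocessed trials plus the calibration products they share."""

    train_trials: list[Recording]
    train_labels: np.ndarray
    test_trials: list[Recording]
    test_labels: np.ndarray
    calibration: CalibrationProfile
    thresholds: TriggerThresholds
    pre_cfg: PreprocessConfig
    win_cfg: WindowConfig


def prepare_session(ds: LabeledDataset, pre_cfg: PreprocessConfig | None = None,
                    win_cfg: WindowConfig | None = None) -> PreparedSession:
    """Preprocess every trial of a session through the four-stage chain.

    Calibration (normalization max-abs, trigger thresholds) is derived from
    the session's pre-collection contraction/rest recordings only — never
    from the trials themselves.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    win_cfg = win_cfg or WindowConfig()
    w = win_cfg.window_samples(pre_cfg.target_fs)
    s = win_cfg.slide_samples(pre_cfg.target_fs)
    calib = build_calibration(ds.contraction_calibration, ds.rest_calibration,
                              pre_cfg, window_samples=w, slide_samples=s)
    thresholds = calibrate_thresholds(calib, win_cfg)
    train = [run_chain(r, pre_cfg, calib) for r in ds.trials("train")]
    test = [run_chain(r, pre_cfg, calib) for r in ds.trials("test")]
    return PreparedSession(train, ds.labels("train"), test, ds.labels("test"),
                           calib, thresholds, pre_cfg, win_cfg)


def _active_windows(trial: Recording, prepared: PreparedSession):
    wins = sliding_windows(trial, prepared.win_cfg)
    if not wins:
        return []
    active = [w for w in wins
              if np.any(w.mav() > prepared.thresholds.values)]
    return active if active else [max(wins, key=lambda w: w.mav().max())]


def training_windows(prepared: PreparedSession, per_trial: int = 8,
                     split: str = "train") -> tuple[np.ndarray, np.ndarray]:
    """Supra-threshold windows for classifier training.

    Up to ``per_trial`` windows are taken per trial, evenly spaced across the
    trial's active (above-trigger) region, so the set covers onset, hold and
    offset phases deterministically. Returns (X, y) with X of shape
    (n, channels, window_samples).
    """
    trials = prepared.train_trials if split == "train" else prepared.test_trials
    labels = prepared.train_labels if split == "train" else prepared.test_labels
    X, y = [], []
    for trial, label in zip(trials, labels):
        active = _active_windows(trial, prepared)
        if len(active) > per_trial:
            idx = np.linspace(0, len(active) - 1, per_trial).round().astype(int)
            active = [active[i] for i in idx]
        for w in active:
            X.append(w.samples)
            y.append(label)
    return np.stack(X), np.asarray(y, dtype=int)


def decision_windows(trial: Recording, prepared: PreparedSession) -> np.ndarray:
    """The trial's decision burst as a (k, channels, window_samples) stack.

    The first triggered burst of the trial is used — the same burst the
    real-time loop would act on. If no trigger fires (weak trial), the k
    consecutive windows centred on the maximum-MAV window stand in, so every
    trial still yields exactly one decision.
    """
    wins = sliding_windows(trial, prepared.win_cfg)
    k = prepared.win_cfg.windows_per_decision
    if len(wins) < k:
        raise ValueError("trial shorter than one decision burst")
    bursts = detect_bursts(wins, prepared.thresholds, prepared.win_cfg)
    if bursts:
        return bursts[0].stacked()
    peak = int(np.argmax([w.mav().max() for w in wins]))
    start = min(max(peak - k // 2, 0), len(wins) - k)
    return np.stack([w.samples for w in wins[start:start + k]])


def evaluate_bursts(model, prepared: PreparedSession,
                    split: str = "test") -> tuple[float, np.ndarray]:
    """Burst-level accuracy and confusion matrix of one decision per trial.

    ``model`` is any fitted estimator exposing ``predict_burst`` (the CNN or
    the SVM baseline).
    """
    trials = prepared.test_trials if split == "test" else prepared.train_trials
    labels = prepared.test_labels if split == "test" else prepared.train_labels
    preds = []
    for trial in trials:
        stack = decision_windows(trial, prepared)
        pred = model.predict_burst(stack)
        preds.append(int(getattr(pred, "voted_class", pred)))
    cm = confusion(labels, preds)
    acc = float(np.trace(cm) / cm.sum())
    return acc, cm
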