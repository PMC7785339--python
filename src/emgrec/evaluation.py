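"""Scoring and statistics: confusion matrices, precision/recall/F1, ANOVA.

Per-class metrics follow the standard definitions precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), with the 0/0 convention of reporting 0
and flagging the class. The ANOVA helpers implement the classical balanced
fixed-effects sums-of-squares decomposition with eta-squared
(SS_effect/SS_total) and omega-squared
((SS_effect - df_effect*MS_error)/(SS_total + MS_error)) effect sizes, the
quantities used to compare classifier and testing-mode factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .motions import N_CLASSES, MotionClass

__all__ = ["confusion", "ClassMetrics", "metrics",
           "AnovaEffect", "AnovaResult", "anova_one_way", "anova_two_way"]


def confusion(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size == 0:
        return np.zeros((n_classes, n_classes), dtype=int)
    if np.any((t < 0) | (t >= n_classes)) or np.any((p < 0) | (p >= n_classes)):
        raise ValueError("unknown label outside the class range")
    return _sk_confusion(t, p, labels=np.arange(n_classes)).astype(int)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus overall accuracy.

    ``degenerate`` flags classes where a 0/0 was replaced by the 0 convention
    (class never predicted and/or never true).
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    degenerate: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "motion": [m.name for m in MotionClass][: len(self.precision)],
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        })


def metrics(cm: np.ndarray) -> ClassMetrics:
    """Per-class precision, recall and F1 from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    total = cm.sum()
    accuracy = float(tp.sum() / total) if total > 0 else 0.0
    degenerate = (tp + fp == 0) | (tp + fn == 0)
    return ClassMetrics(precision, recall, f1, accuracy, degenerate)


@dataclass
class AnovaEffect:
    """One factor's (or the interaction's) row of the ANOVA table."""

    name: str
    ss: float
    df: int
    F: float
    p: float
    eta_squared: float
    omega_squared: float


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]
    ss_error: float
    df_error: int
    ss_total: float

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"effect": e.name, "SS": e.ss, "df": e.df, "F": e.F, "p": e.p,
                 "eta2": e.eta_squared, "omega2": e.omega_squared}
                for e in self.effects]
        rows.append({"effect": "error", "SS": self.ss_error,
                     "df": self.df_error, "F": np.nan, "p": np.nan,
                     "eta2": np.nan, "omega2": np.nan})
        return pd.DataFrame(rows)


def _effect(name: str, ss: float, df: int, ms_error: float, df_error: int,
            ss_total: float) -> AnovaEffect:
    ms = ss / df
    if ms_error > 0:
        F = ms / ms_error
        p = float(stats.f.sf(F, df, df_error))
    else:
        F, p = np.inf if ss > 0 else 0.0, 0.0 if ss > 0 else 1.0
    eta2 = ss / ss_total if ss_total > 0 else 0.0
    omega2 = (ss - df * ms_error) / (ss_total + ms_error) if ss_total + ms_error > 0 else 0.0
    return AnovaEffect(name, float(ss), int(df), float(F), p,
                       float(eta2), float(omega2))


def anova_one_way(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over a list of sample arrays."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    allv = np.concatenate(groups)
    gm = allv.mean()
    ss_between = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    ss_total = np.sum((allv - gm) ** 2)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    ms_error = ss_within / df_w
    eff = _effect("group", ss_between, df_b, ms_error, df_w, ss_total)
    return AnovaResult([eff], float(ss_within), df_w, float(ss_total))


def anova_two_way(values, factor_a, factor_b) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``values`` are the observations (e.g. per-subject accuracies); factor_a
    and factor_b are the level labels of the two crossed factors (e.g.
    classifier and testing mode). The design must be balanced: every (a, b)
    cell holds the same number (>= 2) of observations.
    """
    y = np.asarray(values, dtype=float).ravel()
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("values and factors must have equal length")
    la, lb = np.unique(a), np.unique(b)
    if la.size < 2 or lb.size < 2:
        raise ValueError("both factors need at least 2 levels")
    cells = {}
    for ai in la:
        for bi in lb:
            cells[ai, bi] = y[(a == ai) & (b == bi)]
    sizes = {k: v.size for k, v in cells.items()}
    n = next(iter(sizes.values()))
    if len(set(sizes.values())) != 1:
        raise ValueError("unbalanced design: all cells must have equal size")
    if n < 2:
        raise ValueError("need at least 2 observations per cell")

    gm = y.mean()
    mean_a = {ai: y[a == ai].mean() for ai in la}
    mean_b = {bi: y[b == bi].mean() for bi in lb}
    cell_mean = {k: v.mean() for k, v in cells.items()}

    ss_a = lb.size * n * sum((mean_a[ai] - gm) ** 2 for ai in la)
    ss_b = la.size * n * sum((mean_b[bi] - gm) ** 2 for bi in lb)
    ss_ab = n * sum((cell_mean[ai, bi] - mean_a[ai] - mean_b[bi] + gm) ** 2
                    for ai in la for bi in lb)
    ss_err = sum(np.sum((cells[ai, bi] - cell_mean[ai, bi]) ** 2)
                 for ai in la for bi in lb)
    ss_total = np.sum((y - gm) ** 2)

    df_a, df_b = la.size - 1, lb.size - 1
    df_ab = df_a * df_b
    df_err = y.size - la.size * lb.size
    ms_error = ss_err / df_err
    effects = [
        _effect("A", ss_a, df_a, ms_error, df_err, ss_total),
        _effect("B", ss_b, df_b, ms_error, df_err, ss_total),
        _effect("AxB", ss_ab, df_ab, ms_error, df_err, ss_total),
    ]
    return AnovaResult(effects, float(ss_err), df_err, float(ss_total))
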