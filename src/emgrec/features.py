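"""Classical time-domain / autoregressive EMG features and SVM baselines.

Per analysis window and channel: mean absolute value (MAV), root mean square
(RMS), waveform length (WL), zero crossings (ZC), slope sign changes (SSC) and
fourth-order autoregressive (AR) coefficients. ZC and SSC use a small
amplitude deadzone so sensor noise does not dominate the counts.

Three feature-set variants feed kernel-SVM baselines:

====== ==========================  ===============
set    per-channel features        vector length
====== ==========================  ===============
SVM1   AR(4), RMS, WL, ZC          7 x 3 = 21
SVM2   MAV, ZC, WL, SSC            4 x 3 = 12
SVM3   RMS, MAV, AR(4), WL         7 x 3 = 21
====== ==========================  ===============

Vectors are channel-major: all of channel 1's features, then channel 2's,
then channel 3's. :class:`EmgSvmClassifier` is a scikit-learn estimator
(standardization + RBF SVC) operating directly on raw (n, channels, samples)
window stacks; burst decisions reuse the same 3-window majority vote as the
CNN path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from statsmodels.regression.linear_model import burg

from .motions import CHANNEL_NAMES

__all__ = [
    "ZcSscConfig",
    "FEATURE_SETS",
    "mav",
    "rms",
    "wl",
    "zc",
    "ssc",
    "ar_coefficients",
    "build_feature_vector",
    "feature_names",
    "feature_matrix",
    "save_feature_matrix",
    "load_feature_matrix",
    "EmgSvmClassifier",
]


@dataclass(frozen=True)
class ZcSscConfig:
    """Deadzone threshold (normalized amplitude) for noise-robust ZC/SSC."""

    deadzone_threshold: float = 0.01

    def __post_init__(self):
        if self.deadzone_threshold < 0:
            raise ValueError("deadzone_threshold must be >= 0")


#: Ordered per-channel feature layout of each SVM feature-set variant.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "SVM1": ("ar1", "ar2", "ar3", "ar4", "rms", "wl", "zc"),
    "SVM2": ("mav", "zc", "wl", "ssc"),
    "SVM3": ("rms", "mav", "ar1", "ar2", "ar3", "ar4", "wl"),
}


def _vec(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


def mav(x) -> float:
    """Mean absolute value: (1/N) * sum |x_i|."""
    return float(np.mean(np.abs(_vec(x))))


def rms(x) -> float:
    """Root mean square: sqrt(mean(x^2))."""
    return float(np.sqrt(np.mean(_vec(x) ** 2)))


def wl(x) -> float:
    """Waveform length: sum |x_{i+1} - x_i|."""
    x = _vec(x)
    if x.size < 2:
        raise ValueError("wl needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zc(x, cfg: ZcSscConfig | None = None) -> int:
    """Zero crossings: sign changes whose step exceeds the deadzone."""
    cfg = cfg or ZcSscConfig()
    x = _vec(x)
    if x.size < 2:
        raise ValueError("zc needs at least 2 samples")
    sign_change = x[:-1] * x[1:] < 0
    big_step = np.abs(np.diff(x)) > cfg.deadzone_threshold
    return int(np.sum(sign_change & big_step))


def ssc(x, cfg: ZcSscConfig | None = None) -> int:
    """Slope sign changes with both adjacent steps above the deadzone."""
    cfg = cfg or ZcSscConfig()
    x = _vec(x)
    if x.size < 3:
        raise ValueError("ssc needs at least 3 samples")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    turning = d1 * d2 > 0
    big = (np.abs(d1) > cfg.deadzone_threshold) & (np.abs(d2) > cfg.deadzone_threshold)
    return int(np.sum(turning & big))


def ar_coefficients(x, order: int = 4) -> np.ndarray:
    """Autoregressive coefficients estimated by the Burg method.

    Returns `order` coefficients a_k of x_t = sum_k a_k x_{t-k} + e_t. Burg
    estimation is the standard choice for short EMG windows: it is stable and
    lower-variance than Yule-Walker at these lengths.
    """
    x = _vec(x)
    if x.size <= 2 * order:
        raise ValueError(f"window too short for AR({order})")
    if np.var(x) == 0:
        raise ValueError("zero-variance input has no AR representation")
    coeffs, _sigma2 = burg(x, order=order, demean=True)
    return np.asarray(coeffs, dtype=float)


_SCALAR_FEATURES = {"mav": mav, "rms": rms, "wl": wl}


def _channel_features(x: np.ndarray, layout: tuple[str, ...],
                      cfg: ZcSscConfig) -> list[float]:
    vals: list[float] = []
    ar = None
    for name in layout:
        if name.startswith("ar"):
            if ar is None:
                ar = ar_coefficients(x, order=4)
            vals.append(float(ar[int(name[2:]) - 1]))
        elif name == "zc":
            vals.append(float(zc(x, cfg)))
        elif name == "ssc":
            vals.append(float(ssc(x, cfg)))
        else:
            vals.append(_SCALAR_FEATURES[name](x))
    return vals


def build_feature_vector(window, set_id: str = "SVM3",
                         cfg: ZcSscConfig | None = None) -> np.ndarray:
    """Concatenate the set's features per channel, channel-major, fixed order.

    ``window`` is an AnalysisWindow or a (channels, samples) array.
    """
    cfg = cfg or ZcSscConfig()
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_id!r}")
    samples = getattr(window, "samples", window)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    layout = FEATURE_SETS[set_id]
    out: list[float] = []
    for ch in range(samples.shape[0]):
        out.extend(_channel_features(samples[ch], layout, cfg))
    vec = np.array(out, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


def feature_names(set_id: str, channel_names=CHANNEL_NAMES) -> list[str]:
    """Column names like ``ch1_rms`` matching build_feature_vector's order."""
    layout = FEATURE_SETS[set_id]
    return [f"ch{c + 1}_{f}" for c in range(len(channel_names)) for f in layout]


def feature_matrix(windows, set_id: str = "SVM3",
                   cfg: ZcSscConfig | None = None) -> np.ndarray:
    """Stack feature vectors for a sequence of windows into (n, d)."""
    return np.stack([build_feature_vector(w, set_id, cfg) for w in windows])


def save_feature_matrix(path, X: np.ndarray, y, set_id: str) -> None:
    """Delimited-text feature file: one row per window, features then label."""
    df = pd.DataFrame(X, columns=feature_names(set_id))
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False, float_format="%.12g")


def load_feature_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), y


class EmgSvmClassifier(ClassifierMixin, BaseEstimator):
    """Kernel-SVM baseline over a named time-domain/AR feature set.

    A scikit-learn classifier that consumes raw analysis-window stacks of
    shape (n_windows, n_channels, window_samples), extracts the configured
    feature set, standardizes it, and fits an RBF SVC (one-vs-one
    multiclass). ``predict_burst`` fuses the windows of one burst with the
    same majority vote used by the CNN path.

    Parameters
    ----------
    feature_set : {"SVM1", "SVM2", "SVM3"}, default "SVM3"
        SVM3 (RMS, MAV, AR(4), WL) is the strongest of the three variants.
    deadzone : float
        ZC/SSC deadzone threshold, normalized amplitude units.
    C, gamma, kernel
        Passed to :class:`sklearn.svm.SVC`.
    """

    def __init__(self, feature_set: str = "SVM3", deadzone: float = 0.01,
                 C: float = 1.0, gamma="scale", kernel: str = "rbf"):
        self.feature_set = feature_set
        self.deadzone = deadzone
        self.C = C
        self.gamma = gamma
        self.kernel = kernel

    def _features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # already a feature matrix
            return X
        if X.ndim != 3:
            raise ValueError("X must be (n, channels, samples) windows "
                             "or an (n, d) feature matrix")
        return feature_matrix(X, self.feature_set, ZcSscConfig(self.deadzone))

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        F = self._features(X)
        if F.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                decision_function_shape="ovo"),
        )
        self.pipeline_.fit(F, y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = F.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._features(X))

    def predict_burst(self, burst_windows) -> int:
        """Majority vote over the per-window predictions of one burst."""
        preds = self.predict(np.asarray(burst_windows, dtype=float))
        counts = np.bincount(preds, minlength=6)
        return int(np.argmax(counts))
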