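"""Lightweight CNN motion-intent classifier with burst majority voting.

The network classifies a single 192 ms x 3-channel analysis window (treated as
a 192 x 3 one-channel image) into the six motion classes. Topology: two
convolutional blocks, each conv(16, 3x3, stride 1, 'same') -> pool ->
conv(32, 3x3, 'same') -> pool, with 2x2 'same' max pooling after every
convolution; then flatten -> FC(512) -> dropout(0.5) -> FC(6) -> softmax.
Every conv/FC layer carries batch normalization and ReLU. The default
configuration uses 215,478 trainable parameters, comfortably inside the
367 k budget that keeps the model deployable on embedded real-time hardware.

Implemented in pure numpy (see :mod:`emgrec._nn`): seeded initialization,
Adam, and single-threaded-deterministic training.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .motions import N_CLASSES, MotionClass

__all__ = ["LwCnnConfig", "parameter_table", "parameter_count",
           "LwCNNClassifier", "BurstPrediction", "majority_vote",
           "PARAM_BUDGET"]

#: Hard trainable-parameter budget for the shipped defaults.
PARAM_BUDGET = 367_000


@dataclass(frozen=True)
class LwCnnConfig:
    """Architecture hyperparameters.

    input_shape is (window_samples, channels); block_filters are the filter
    counts of the two conv layers inside each block; n_blocks blocks are
    stacked. fc1_width=512 keeps the total parameter count under the budget.
    """

    input_shape: tuple[int, int] = (192, 3)
    block_filters: tuple[int, int] = (16, 32)
    kernel: int = 3
    n_blocks: int = 2
    fc1_width: int = 512
    n_classes: int = N_CLASSES
    dropout_p: float = 0.5

    def conv_channels(self) -> list[tuple[int, int]]:
        """(c_in, c_out) for each conv layer in order."""
        chans = []
        c_in = 1
        for _ in range(self.n_blocks):
            for c_out in self.block_filters:
                chans.append((c_in, c_out))
                c_in = c_out
        return chans

    def spatial_after_convs(self) -> tuple[int, int]:
        """(H, W) after all conv+pool stages ('same' pooling: ceil halving)."""
        h, w = self.input_shape
        for _ in range(self.n_blocks * len(self.block_filters)):
            h, w = -(-h // 2), -(-w // 2)
        return h, w


def parameter_table(cfg: LwCnnConfig | None = None) -> list[dict]:
    """Layer-by-layer trainable parameter arithmetic.

    conv: k*k*c_in*c_out + c_out; batch norm: 2*c; dense: d_in*d_out + d_out.
    """
    cfg = cfg or LwCnnConfig()
    rows = []
    k = cfg.kernel
    for i, (c_in, c_out) in enumerate(cfg.conv_channels(), start=1):
        rows.append({"layer": f"conv{i} ({k}x{k}, {c_out} filters)",
                     "params": k * k * c_in * c_out + c_out})
        rows.append({"layer": f"bn_conv{i}", "params": 2 * c_out})
    h, w = cfg.spatial_after_convs()
    flat = h * w * cfg.conv_channels()[-1][1]
    rows.append({"layer": f"flatten ({h}x{w}x{cfg.block_filters[-1]})", "params": 0})
    rows.append({"layer": f"fc1 ({flat}->{cfg.fc1_width})",
                 "params": flat * cfg.fc1_width + cfg.fc1_width})
    rows.append({"layer": "bn_fc1", "params": 2 * cfg.fc1_width})
    rows.append({"layer": f"fc2 ({cfg.fc1_width}->{cfg.n_classes})",
                 "params": cfg.fc1_width * cfg.n_classes + cfg.n_classes})
    return rows


def parameter_count(cfg: LwCnnConfig | None = None) -> int:
    return int(sum(r["params"] for r in parameter_table(cfg)))


@dataclass
class BurstPrediction:
    """Fused decision for one burst: per-window probabilities plus the vote."""

    window_probs: np.ndarray  # (windows_per_decision, 6)
    voted_class: MotionClass
    vote_counts: np.ndarray  # (6,) argmax votes per class


def majority_vote(window_probs) -> BurstPrediction:
    """Plurality vote over per-window argmaxes.

    Ties (all argmaxes distinct, or equal vote counts) are broken by the
    highest summed probability among the tied classes.
    """
    probs = np.asarray(window_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError("expected (n_windows, 6) probability array")
    argmaxes = probs.argmax(axis=1)
    counts = np.bincount(argmaxes, minlength=N_CLASSES)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        winner = int(tied[0])
    else:
        sums = probs.sum(axis=0)
        winner = int(tied[np.argmax(sums[tied])])
    return BurstPrediction(probs, MotionClass(winner), counts)


def _build_network(cfg: LwCnnConfig, rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    for c_in, c_out in cfg.conv_channels():
        layers += [_nn.Conv2D(c_in, c_out, cfg.kernel, rng),
                   _nn.BatchNorm(c_out), _nn.ReLU(), _nn.MaxPool2x2()]
    h, w = cfg.spatial_after_convs()
    flat = h * w * cfg.conv_channels()[-1][1]
    layers += [_nn.Flatten(),
               _nn.Dense(flat, cfg.fc1_width, rng),
               _nn.BatchNorm(cfg.fc1_width), _nn.ReLU(),
               _nn.Dropout(cfg.dropout_p),
               _nn.Dense(cfg.fc1_width, cfg.n_classes, rng)]
    return _nn.Sequential(layers)


class LwCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style CNN classifier over analysis windows.

    ``fit``/``predict`` consume window stacks of shape
    (n_windows, n_channels, window_samples); internally windows become
    (window_samples, n_channels, 1) images. Training minimizes softmax
    cross-entropy with Adam; it is deterministic for a fixed seed under
    single-threaded BLAS.

    Parameters
    ----------
    config : LwCnnConfig, optional
        Architecture; defaults to the 215 k-parameter network.
    epochs, batch_size, lr : training hyperparameters.
    validation_fraction : float
        Held-out fraction of the training windows used for early stopping.
    patience : int
        Early-stopping patience in epochs (0 disables early stopping).
    seed : int
        Seeds weight init, shuffling and dropout.
    strict_budget : bool
        If True, a config over the 367 k parameter budget raises; otherwise
        it warns.

    Attributes
    ----------
    network_ : the fitted numpy network.
    n_params_ : trainable parameter count.
    loss_curve_ : per-epoch mean training loss.
    classes_ : sorted class labels seen in fit.
    """

    def __init__(self, config: LwCnnConfig | None = None, epochs: int = 30,
                 batch_size: int = 32, lr: float = 1e-3,
                 validation_fraction: float = 0.1, patience: int = 5,
                 seed: int = 0, strict_budget: bool = False):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed
        self.strict_budget = strict_budget

    # ------------------------------------------------------------------
    def _cfg(self) -> LwCnnConfig:
        return self.config or LwCnnConfig()

    def _images(self, X) -> np.ndarray:
        cfg = self._cfg()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # single window (channels, samples)
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n, channels, samples)")
        n, c, t = X.shape
        if (t, c) != cfg.input_shape:
            raise ValueError(f"window shape {(t, c)} does not match "
                             f"configured input {cfg.input_shape}")
        return X.transpose(0, 2, 1)[..., None]  # (n, T, C, 1)

    def fit(self, X, y):
        cfg = self._cfg()
        count = parameter_count(cfg)
        if count > PARAM_BUDGET:
            msg = (f"configuration uses {count} parameters, over the "
                   f"{PARAM_BUDGET} budget")
            if self.strict_budget:
                raise ValueError(msg)
            warnings.warn(msg)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        imgs = self._images(X)
        if imgs.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.seed)
        net = _build_network(cfg, rng)
        opt = _nn.Adam(net, lr=self.lr)

        n = imgs.shape[0]
        n_val = int(round(self.validation_fraction * n)) if self.patience > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        best_val, best_state, stall = np.inf, None, 0
        losses = []
        for _epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss = 0.0
            for start in range(0, order.size, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = net.forward(imgs[idx], train=True, rng=rng)
                loss, grad = _nn.cross_entropy_grad(logits, y[idx])
                net.backward(grad)
                opt.step()
                epoch_loss += loss * idx.size
            losses.append(epoch_loss / order.size)
            if n_val > 0:
                logits = net.forward(imgs[val_idx], train=False)
                val_loss, _ = _nn.cross_entropy_grad(logits, y[val_idx])
                if val_loss < best_val - 1e-6:
                    best_val, stall = val_loss, 0
                    best_state = [{k: v.copy() for k, v in layer.params.items()}
                                  for layer in net.layers]
                    best_bn = [(layer.running_mean.copy(), layer.running_var.copy())
                               if isinstance(layer, _nn.BatchNorm) else None
                               for layer in net.layers]
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if n_val > 0 and best_state is not None:
            for layer, state, bn in zip(net.layers, best_state, best_bn):
                layer.params = state
                if bn is not None:
                    layer.running_mean, layer.running_var = bn
        self.network_ = net
        self.n_params_ = count
        self.loss_curve_ = losses
        self.classes_ = classes
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Per-window class probabilities (rows sum to 1)."""
        check_is_fitted(self, "network_")
        imgs = self._images(X)
        logits = self.network_.forward(imgs, train=False)
        return _nn.softmax(logits)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_window(self, window) -> np.ndarray:
        """Probability vector (6,) for a single (channels, samples) window."""
        return self.predict_proba(np.asarray(window)[None] if
                                  np.asarray(window).ndim == 2 else window)[0]

    def predict_burst(self, burst_windows, measure_time: bool = False):
        """Majority-vote decision for one burst's window stack.

        Returns a BurstPrediction, or (BurstPrediction, inference_ms) when
        ``measure_time`` is set.
        """
        t0 = time.perf_counter()
        probs = self.predict_proba(np.asarray(burst_windows, dtype=float))
        pred = majority_vote(probs)
        if measure_time:
            return pred, (time.perf_counter() - t0) * 1000.0
        return pred

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist architecture JSON + weights in one .npz container."""
        check_is_fitted(self, "network_")
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.network_.layers):
            for name, p in layer.params.items():
                arrays[f"{li}.{name}"] = p
            if isinstance(layer, _nn.BatchNorm):
                arrays[f"{li}.running_mean"] = layer.running_mean
                arrays[f"{li}.running_var"] = layer.running_var
        meta = {"config": asdict(self._cfg()), "classes": self.classes_.tolist(),
                "n_params": self.n_params_}
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LwCNNClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfgd = meta["config"]
        cfgd["input_shape"] = tuple(cfgd["input_shape"])
        cfgd["block_filters"] = tuple(cfgd["block_filters"])
        cfg = LwCnnConfig(**cfgd)
        est = cls(config=cfg)
        net = _build_network(cfg, np.random.default_rng(0))
        for li, layer in enumerate(net.layers):
            for name in layer.params:
                layer.params[name] = data[f"{li}.{name}"]
            if isinstance(layer, _nn.BatchNorm):
                layer.running_mean = data[f"{li}.running_mean"]
                layer.running_var = data[f"{li}.running_var"]
        est.network_ = net
        est.n_params_ = int(meta["n_params"])
        est.classes_ = np.array(meta["classes"])
        est.loss_curve_ = []
        return est
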