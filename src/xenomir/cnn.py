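"""A small 1-D convolutional network for one-hot encoded miRNA sequences.

Fixed architecture: input (18 steps x 4 channels) -> conv1d -> conv1d ->
flatten -> dense -> dense -> 2-unit softmax.  Convolutions are valid,
stride 1; conv and dense layers use the logistic sigmoid activation;
dropout and L2 weight decay are applied to the two dense layers.  Training
minimizes categorical cross-entropy with the Adam optimizer.

The network is written directly in numpy (forward pass and analytic
backpropagation); for inputs of this size that is fast and makes training
fully reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import ENCODING_BITS, ENCODING_LENGTH


@dataclass
class CNNConfig:
    """Hyperparameters of the convolutional classifier.

    The architecture is fixed at exactly two convolutional and two dense
    layers; only their sizes and the training schedule are tunable.
    """

    conv_channels: tuple[int, int] = (16, 32)
    conv_kernels: tuple[int, int] = (8, 4)
    dense_units: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.3
    l2_lambda: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 2 or len(self.conv_kernels) != 2:
            raise ValueError("exactly two convolutional layers")
        if len(self.dense_units) != 2:
            raise ValueError("exactly two dense layers")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _conv1d_forward(x, w, b):
    """Valid cross-correlation.  x: (n, steps, cin); w: (k, cin, cout).

    einsum indices: n=batch, o=output step, c=in channel, k=kernel
    position, f=out channel.
    """
    windows = sliding_window_view(x, w.shape[0], axis=1)  # (n, out, cin, k)
    z = np.einsum("nock,kcf->nof", windows, w) + b
    return z, windows


def _conv1d_backward(delta, windows, w, x_shape):
    """Gradients of a valid conv.  delta: (n, out, cout)."""
    dw = np.einsum("nock,nof->kcf", windows, delta)
    db = delta.sum(axis=(0, 1))
    k = w.shape[0]
    dx = np.zeros(x_shape)
    # scatter-add each kernel offset; k is small (<= 8)
    contrib = np.einsum("nof,kcf->nokc", delta, w)
    for j in range(k):
        dx[:, j:j + delta.shape[1], :] += contrib[:, :, j, :]
    return dx, dw, db


class CNNClassifier:
    """Two-conv / two-dense softmax classifier over 72-bit encodings."""

    def __init__(self, config: CNNConfig | None = None) -> None:
        self.config = config or CNNConfig()
        self._params: dict[str, np.ndarray] | None = None

    # -- architecture ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        k1, k2 = cfg.conv_kernels
        c1, c2 = cfg.conv_channels
        d1, d2 = cfg.dense_units
        steps1 = ENCODING_LENGTH - k1 + 1
        steps2 = steps1 - k2 + 1
        flat = steps2 * c2
        p = {
            "w1": _glorot(rng, (k1, 4, c1), k1 * 4, k1 * c1),
            "b1": np.zeros(c1),
            "w2": _glorot(rng, (k2, c1, c2), k2 * c1, k2 * c2),
            "b2": np.zeros(c2),
            "w3": _glorot(rng, (flat, d1), flat, d1),
            "b3": np.zeros(d1),
            "w4": _glorot(rng, (d1, d2), d1, d2),
            "b4": np.zeros(d2),
            "w5": _glorot(rng, (d2, 2), d2, 2),
            "b5": np.zeros(2),
        }
        return p

    def _forward(self, x: np.ndarray, p: dict[str, np.ndarray],
                 drop1: np.ndarray | None = None,
                 drop2: np.ndarray | None = None) -> dict[str, np.ndarray]:
        n = x.shape[0]
        xc = x.reshape(n, ENCODING_LENGTH, 4)
        z1, win1 = _conv1d_forward(xc, p["w1"], p["b1"])
        a1 = _sigmoid(z1)
        z2, win2 = _conv1d_forward(a1, p["w2"], p["b2"])
        a2 = _sigmoid(z2)
        flat = a2.reshape(n, -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = _sigmoid(z3)
        if drop1 is not None:
            a3 = a3 * drop1
        z4 = a3 @ p["w4"] + p["b4"]
        a4 = _sigmoid(z4)
        if drop2 is not None:
            a4 = a4 * drop2
        z5 = a4 @ p["w5"] + p["b5"]
        probs = _softmax(z5)
        return dict(xc=xc, win1=win1, a1=a1, win2=win2, a2=a2, flat=flat,
                    a3=a3, a4=a4, probs=probs)

    def _backward(self, cache: dict[str, np.ndarray], y_onehot: np.ndarray,
                  p: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        cfg = self.config
        n = y_onehot.shape[0]
        lam = cfg.l2_lambda
        g: dict[str, np.ndarray] = {}
        # softmax + cross-entropy
        d5 = (cache["probs"] - y_onehot) / n
        g["w5"] = cache["a4"].T @ d5 + lam * p["w5"]
        g["b5"] = d5.sum(axis=0)
        d4 = d5 @ p["w5"].T * cache["a4"] * (1 - cache["a4"])
        g["w4"] = cache["a3"].T @ d4 + lam * p["w4"]
        g["b4"] = d4.sum(axis=0)
        d3 = d4 @ p["w4"].T * cache["a3"] * (1 - cache["a3"])
        g["w3"] = cache["flat"].T @ d3 + lam * p["w3"]
        g["b3"] = d3.sum(axis=0)
        dflat = d3 @ p["w3"].T
        d2 = dflat.reshape(cache["a2"].shape) * cache["a2"] * (1 - cache["a2"])
        da1, g["w2"], g["b2"] = _conv1d_backward(
            d2, cache["win2"], p["w2"], cache["a1"].shape)
        d1 = da1 * cache["a1"] * (1 - cache["a1"])
        _, g["w1"], g["b1"] = _conv1d_backward(
            d1, cache["win1"], p["w1"], cache["xc"].shape)
        return g

    # -- training --------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        """Train on one-hot encodings x (n, 72) and binary labels y."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 2 or x.shape[1] != ENCODING_BITS:
            raise ValueError(
                f"expected input width {ENCODING_BITS}, got {x.shape}")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        p = self._init_params(rng)
        y_onehot = np.eye(2)[y]
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(v_) for k, v_ in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        keep = 1.0 - cfg.dropout_rate
        n = x.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y_onehot[idx]
                if cfg.dropout_rate > 0:
                    drop1 = rng.binomial(1, keep,
                                         (len(idx), cfg.dense_units[0])) / keep
                    drop2 = rng.binomial(1, keep,
                                         (len(idx), cfg.dense_units[1])) / keep
                else:
                    drop1 = drop2 = None
                cache = self._forward(xb, p, drop1, drop2)
                grads = self._backward(cache, yb, p)
                t += 1
                for key in p:
                    m[key] = beta1 * m[key] + (1 - beta1) * grads[key]
                    v[key] = beta2 * v[key] + (1 - beta2) * grads[key] ** 2
                    mhat = m[key] / (1 - beta1 ** t)
                    vhat = v[key] / (1 - beta2 ** t)
                    p[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        self._params = p
        return self

    # -- inference -------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("model is not trained")
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != ENCODING_BITS:
            raise ValueError(
                f"expected input width {ENCODING_BITS}, got {x.shape}")
        return self._forward(x, self._params)["probs"]

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Softmax probability of the positive class."""
        return self.predict_proba(x)[:, 1]

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_scores(x) >= threshold).astype(int)
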