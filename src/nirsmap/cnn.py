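"""A small convolutional network for topographic feature maps.

The classifier is a four-layer CNN (two convolutional, two fully connected
layers): each convolutional block applies 8 kernels of size 4x4 with
stride 1 and no padding, a ReLU, 2x2 max-pooling and dropout; the pooled
maps are flattened into a 128-unit ReLU layer followed by a 2-way softmax.
Training minimizes categorical cross-entropy with the Adam optimizer.

The spatial size chain for the 200x200 input is

    conv:  y = floor((h - k + 2p) / s) + 1      200 -> 197
    pool:  z = floor((y - p1) / sp) + 1          197 ->  98
    conv:                                         98 ->  95
    pool:                                         95 ->  47

so the flatten stage feeds 47 * 47 * 8 = 17,672 units into the first
fully connected layer.

The network is implemented directly in NumPy (im2col convolutions,
index-tracked max-pooling, inverted dropout) — deliberately compact, CPU
friendly, and bit-reproducible given a seed, which suits the tiny image
datasets this package produces.  Analytic gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CNNArchitecture",
    "TrainConfig",
    "SmallCNN",
    "conv_output_size",
    "pool_output_size",
    "relu",
]


def conv_output_size(size: int, kernel: int, padding: int = 0, stride: int = 1) -> int:
    """Spatial output size of a convolution: floor((h - k + 2p)/s) + 1."""
    if stride < 1:
        raise ValueError("stride must be at least 1")
    if kernel > size + 2 * padding:
        raise ValueError("kernel larger than padded input")
    out = (size - kernel + 2 * padding) // stride + 1
    if out <= 0:
        raise ValueError("non-positive convolution output size")
    return out


def pool_output_size(size: int, pool: int, stride: int) -> int:
    """Pooling output size: floor((y - p)/sp) + 1 (incomplete trailing
    windows are dropped)."""
    if pool > size:
        raise ValueError("pooling window larger than input")
    out = (size - pool) // stride + 1
    if out <= 0:
        raise ValueError("non-positive pooling output size")
    return out


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, max(0, x), elementwise."""
    return np.maximum(0, x)


@dataclass(frozen=True)
class CNNArchitecture:
    """Hyperparameters of the network; defaults give the canonical stack."""

    input_hw: tuple[int, int] = (200, 200)
    n_kernels: int = 8
    kernel_hw: tuple[int, int] = (4, 4)
    stride: int = 1
    padding: int = 0
    pool: int = 2
    pool_stride: int = 2
    # dropout after each pooling stage; 0.25 keeps train- and eval-mode
    # activation statistics consistent on smooth, low-contrast maps
    # (heavier rates make the two modes diverge on such inputs)
    dropout: float = 0.25
    hidden_units: int = 128
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.pool != self.pool_stride:
            raise ValueError("only non-overlapping pooling (pool == stride) is supported")
        self.layer_sizes()  # raises on an inconsistent geometry

    def layer_sizes(self) -> dict[str, tuple[int, ...]]:
        """Spatial sizes of every stage, from the size arithmetic above."""
        h, w = self.input_hw
        kh, kw = self.kernel_hw
        c1 = (conv_output_size(h, kh, self.padding, self.stride),
              conv_output_size(w, kw, self.padding, self.stride))
        p1 = (pool_output_size(c1[0], self.pool, self.pool_stride),
              pool_output_size(c1[1], self.pool, self.pool_stride))
        c2 = (conv_output_size(p1[0], kh, self.padding, self.stride),
              conv_output_size(p1[1], kw, self.padding, self.stride))
        p2 = (pool_output_size(c2[0], self.pool, self.pool_stride),
              pool_output_size(c2[1], self.pool, self.pool_stride))
        return {
            "input": (1, h, w),
            "conv1": (self.n_kernels, *c1),
            "pool1": (self.n_kernels, *p1),
            "conv2": (self.n_kernels, *c2),
            "pool2": (self.n_kernels, *p2),
            "flatten": (self.n_kernels * p2[0] * p2[1],),
            "fc1": (self.hidden_units,),
            "fc2": (self.n_classes,),
        }

    @property
    def flatten_size(self) -> int:
        return self.layer_sizes()["flatten"][0]

    def n_parameters(self) -> int:
        kh, kw = self.kernel_hw
        k = self.n_kernels
        n = k * (1 * kh * kw) + k              # conv1
        n += k * (k * kh * kw) + k             # conv2
        n += self.flatten_size * self.hidden_units + self.hidden_units
        n += self.hidden_units * self.n_classes + self.n_classes
        return n


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (unremarkable Adam defaults, all logged)."""

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    shuffle: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be at least 1")


def _conv_forward(x, W, b, stride, padding):
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    B, C, H, Wd = x.shape
    K, _, kh, kw = W.shape
    Ho = conv_output_size(H, kh, 0, stride)
    Wo = conv_output_size(Wd, kw, 0, stride)
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho, Wo, C * kh * kw)
    Wmat = W.reshape(K, C * kh * kw).T
    out = cols @ Wmat + b
    return out.transpose(0, 3, 1, 2), (cols, x.shape, W.shape, stride, padding)


def _conv_backward_full(dout, W, cache):
    cols, xshape, wshape, stride, padding = cache
    K, C, kh, kw = wshape
    B, _, Ho, Wo = dout.shape
    d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))       # (B,Ho,Wo,K)
    dWmat = np.tensordot(cols, d, axes=([0, 1, 2], [0, 1, 2]))  # (C*kh*kw, K)
    dW = dWmat.T.reshape(K, C, kh, kw)
    db = d.sum(axis=(0, 1, 2))
    Wmat = W.reshape(K, C * kh * kw)
    dcols = d @ Wmat                                            # (B,Ho,Wo,C*kh*kw)
    dc = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(xshape, dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += dc[..., i, j]
    if padding:
        dx = dx[:, :, padding:-padding, padding:-padding]
    return dx, dW, db


def _pool_forward(x, pool, stride):
    B, C, H, W = x.shape
    Ho = pool_output_size(H, pool, stride)
    Wo = pool_output_size(W, pool, stride)
    xc = x[:, :, : Ho * pool, : Wo * pool]
    win = np.ascontiguousarray(
        xc.reshape(B, C, Ho, pool, Wo, pool).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(B, C, Ho, Wo, pool * pool)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, pool, Ho, Wo)


def _pool_backward(dout, cache):
    idx, xshape, pool, Ho, Wo = cache
    B, C, _, _ = xshape
    dwin = np.zeros((B, C, Ho, Wo, pool * pool), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, : Ho * pool, : Wo * pool] = (
        dwin.reshape(B, C, Ho, Wo, pool, pool)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, Ho * pool, Wo * pool)
    )
    return dx


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Trainable instance of :class:`CNNArchitecture`.

    All randomness (He-style weight init, batch shuffling, dropout masks)
    flows from a single seeded generator, so two models built and trained
    with the same seed and data end up with identical weights.
    """

    def __init__(self, arch: CNNArchitecture = CNNArchitecture(), seed: int = 0,
                 dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self._fitted = False
        # input-normalization stage: the training-set mean intensity is
        # subtracted before the first convolution (set by fit()).  Centring
        # matters on low-contrast maps: with a positive input bias some
        # inits drive the first ReLU stage dead and training stalls.
        self.input_offset = 0.0
        kh, kw = arch.kernel_hw
        k = arch.n_kernels
        F = arch.flatten_size

        def he(shape, fan_in):
            return (self.rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

        self.params = {
            "W1": he((k, 1, kh, kw), kh * kw),
            "b1": np.zeros(k, dtype=dtype),
            "W2": he((k, k, kh, kw), k * kh * kw),
            "b2": np.zeros(k, dtype=dtype),
            "Wf1": he((F, arch.hidden_units), F),
            "bf1": np.zeros(arch.hidden_units, dtype=dtype),
            "Wf2": he((arch.hidden_units, arch.n_classes), arch.hidden_units),
            "bf2": np.zeros(arch.n_classes, dtype=dtype),
        }

    # ------------------------------------------------------------------ #

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _as_batch(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 3:
            X = X[:, None]
        h, w = self.arch.input_hw
        if X.shape[1:] != (1, h, w):
            raise ValueError(f"expected images of shape (1, {h}, {w}), got {X.shape[1:]}")
        return X

    def _dropout_mask(self, shape, training):
        rate = self.arch.dropout
        if not training or rate == 0:
            return None
        return (self.rng.random(shape) >= rate).astype(self.dtype) / self.dtype(1 - rate)

    def _forward(self, X, training=False):
        a = self.arch
        p = self.params
        cache = {}
        if self.input_offset != 0.0:
            X = X - self.dtype(self.input_offset)
        out, cache["conv1"] = _conv_forward(X, p["W1"], p["b1"], a.stride, a.padding)
        cache["relu1"] = out > 0
        out = relu(out)
        out, cache["pool1"] = _pool_forward(out, a.pool, a.pool_stride)
        cache["drop1"] = self._dropout_mask(out.shape, training)
        if cache["drop1"] is not None:
            out = out * cache["drop1"]
        out, cache["conv2"] = _conv_forward(out, p["W2"], p["b2"], a.stride, a.padding)
        cache["relu2"] = out > 0
        out = relu(out)
        out, cache["pool2"] = _pool_forward(out, a.pool, a.pool_stride)
        cache["drop2"] = self._dropout_mask(out.shape, training)
        if cache["drop2"] is not None:
            out = out * cache["drop2"]
        cache["flat_shape"] = out.shape
        flat = out.reshape(out.shape[0], -1)
        cache["flat"] = flat
        h1 = flat @ p["Wf1"] + p["bf1"]
        cache["relu_fc"] = h1 > 0
        h1 = relu(h1)
        cache["h1"] = h1
        logits = h1 @ p["Wf2"] + p["bf2"]
        return logits, cache

    def shape_report(self) -> dict[str, tuple[int, ...]]:
        """Actual per-stage tensor shapes from a dummy forward pass
        (excluding the batch axis) — the framework-reported counterpart of
        :meth:`CNNArchitecture.layer_sizes`."""
        a = self.arch
        X = np.zeros((1, 1, *a.input_hw), dtype=self.dtype)
        p = self.params
        report = {"input": X.shape[1:]}
        out, _ = _conv_forward(X, p["W1"], p["b1"], a.stride, a.padding)
        report["conv1"] = out.shape[1:]
        out, _ = _pool_forward(out, a.pool, a.pool_stride)
        report["pool1"] = out.shape[1:]
        out, _ = _conv_forward(out, p["W2"], p["b2"], a.stride, a.padding)
        report["conv2"] = out.shape[1:]
        out, _ = _pool_forward(out, a.pool, a.pool_stride)
        report["pool2"] = out.shape[1:]
        report["flatten"] = (out[0].size,)
        report["fc1"] = (a.hidden_units,)
        report["fc2"] = (a.n_classes,)
        return report

    # ------------------------------------------------------------------ #

    def loss_and_gradients(self, X, y, training: bool = True):
        """Mean cross-entropy and analytic parameter gradients for a batch."""
        X = self._as_batch(X)
        y = np.asarray(y, dtype=int)
        logits, cache = self._forward(X, training=training)
        probs = _softmax(logits.astype(np.float64))
        n = X.shape[0]
        loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits = (dlogits / n).astype(self.dtype)

        p = self.params
        grads = {}
        grads["Wf2"] = cache["h1"].T @ dlogits
        grads["bf2"] = dlogits.sum(axis=0)
        dh1 = dlogits @ p["Wf2"].T
        dh1 = dh1 * cache["relu_fc"]
        grads["Wf1"] = cache["flat"].T @ dh1
        grads["bf1"] = dh1.sum(axis=0)
        dflat = dh1 @ p["Wf1"].T
        dout = dflat.reshape(cache["flat_shape"])
        if cache["drop2"] is not None:
            dout = dout * cache["drop2"]
        dout = _pool_backward(dout, cache["pool2"])
        dout = dout * cache["relu2"]
        dout, grads["W2"], grads["b2"] = _conv_backward_full(dout, p["W2"], cache["conv2"])
        if cache["drop1"] is not None:
            dout = dout * cache["drop1"]
        dout = _pool_backward(dout, cache["pool1"])
        dout = dout * cache["relu1"]
        _, grads["W1"], grads["b1"] = _conv_backward_full(dout, p["W1"], cache["conv1"])
        return loss, grads

    def fit(self, X, y, cfg: TrainConfig = TrainConfig()) -> list[float]:
        """Train with Adam on integer class labels; returns the per-epoch
        mean training loss."""
        X = self._as_batch(X)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        if np.any((y < 0) | (y >= self.arch.n_classes)):
            raise ValueError("labels out of range for the configured classes")
        self.input_offset = float(X.mean())

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        step = 0
        history = []
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = self.rng.permutation(n) if cfg.shuffle else np.arange(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, grads = self.loss_and_gradients(X[batch], y[batch], training=True)
                losses.append(loss)
                step += 1
                for key, g in grads.items():
                    m[key] = cfg.beta1 * m[key] + (1 - cfg.beta1) * g
                    v[key] = cfg.beta2 * v[key] + (1 - cfg.beta2) * g * g
                    m_hat = m[key] / (1 - cfg.beta1**step)
                    v_hat = v[key] / (1 - cfg.beta2**step)
                    self.params[key] -= (
                        cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)
                    ).astype(self.dtype)
            history.append(float(np.mean(losses)))
        self._fitted = True
        return history

    def predict_proba(self, X, batch_size: int = 16) -> np.ndarray:
        """Softmax class probabilities in evaluation mode (dropout off)."""
        X = self._as_batch(X)
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits, _ = self._forward(X[start : start + batch_size], training=False)
            out.append(_softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Hard labels: argmax of the softmax (ties break to the lower
        class index)."""
        return self.predict_proba(X).argmax(axis=1)

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Checkpoint weights as ``.npz`` with a JSON architecture sidecar
        (``<path>.json``) for audit."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path, input_offset=self.input_offset, **self.params)
        sidecar = {
            "architecture": {k: list(v) if isinstance(v, tuple) else v
                             for k, v in self.arch.__dict__.items()},
            "n_parameters": self.n_parameters(),
            "layer_sizes": {k: list(v) for k, v in self.arch.layer_sizes().items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "SmallCNN":
        """Restore a checkpoint written by :meth:`save`."""
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = sidecar["architecture"]
        arch = CNNArchitecture(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in raw.items()})
        model = cls(arch, seed=0)
        with np.load(path) as data:
            model.input_offset = float(data["input_offset"])
            for key in model.params:
                model.params[key] = data[key]
        model._fitted = True
        return model
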