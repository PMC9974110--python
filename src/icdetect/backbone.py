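"""A small convolutional feature extractor implemented in NumPy.

The production architecture in this pipeline family is a ResNet50 with its
final fully connected layers removed; that requires a deep-learning
framework and a GPU. ``TinyCNN`` exposes the identical contract — RGB
patch in, fixed-length globally-average-pooled feature vector out, with a
detachable sigmoid classification head — at desk scale, with both
inference and Adam/backprop training in pure NumPy so the package has no
framework dependency. ``build_backbone`` will still hand out a torchvision
ResNet50 when torch is importable.

Layout is NCHW. Three 3x3 conv blocks (stride 1, pad 1, ReLU), 2x2 max
pooling after the first two, global average pooling after the third.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patches of the zero-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * 9)


def _col2im(dcol: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b, c, h, w = shape
    dcol = dcol.reshape(b, h, w, c, 3, 3)
    dx = np.zeros((b, c, h + 2, w + 2), dtype=dcol.dtype)
    for i in range(3):
        for j in range(3):
            dx[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx[:, :, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, *, need_dx: bool = True):
        scale = np.sqrt(2.0 / (c_in * 9))  # He init
        self.w = rng.normal(0.0, scale, size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.need_dx = need_dx

    def forward(self, x):
        b, c, h, w = x.shape
        col = _im2col(x)
        out = col @ self.w + self.b
        self._cache = (col, x.shape)
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        col, xshape = self._cache
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, dout.shape[1])
        self.dw = col.T @ d2
        self.db = d2.sum(axis=0)
        if not self.need_dx:  # first layer: no upstream gradient needed
            return None
        return _col2im(d2 @ self.w.T, xshape)

    params = property(lambda self: {"w": self.w, "b": self.b})


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _maxpool2_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    # break ties so gradients are not duplicated
    norm = mask.sum(axis=(3, 5), keepdims=True)
    return out, ((mask / norm).astype(x.dtype), x.shape)


def _maxpool2_backward(dout, cache):
    mask, shape = cache
    b, c, h, w = shape
    return (mask * dout[:, :, :, None, :, None]).reshape(b, c, h, w)


class TinyCNN:
    """Three-block CNN: features() yields a ``feature_dim``-long vector per
    image; forward()/backward() additionally use a linear sigmoid head."""

    arch = "tiny_cnn"

    def __init__(self, input_size: int = 64, channels=(8, 16, 32), seed: int = 0):
        if input_size % 4 != 0:
            raise ConfigError("input_size must be a multiple of 4")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.input_size = int(input_size)
        self.channels = tuple(channels)
        self.conv1 = _Conv3x3(3, c1, rng, need_dx=False)
        self.conv2 = _Conv3x3(c1, c2, rng)
        self.conv3 = _Conv3x3(c2, c3, rng)
        self.fc_w = rng.normal(0.0, np.sqrt(1.0 / c3), size=(c3, 1)).astype(np.float32)
        self.fc_b = np.zeros(1, dtype=np.float32)

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    # -- input preparation --------------------------------------------------
    def prepare(self, images: np.ndarray) -> np.ndarray:
        """uint8 (B, H, W, 3) -> float NCHW at the network input size,
        scaled to [0, 1]. Square inputs whose side is a multiple of the
        input size are block-averaged; anything else is an error."""
        x = np.asarray(images, dtype=np.float32) / np.float32(255.0)
        if x.ndim == 3:
            x = x[None]
        b, h, w, c = x.shape
        s = self.input_size
        if h != w or h % s != 0:
            raise ConfigError(f"images {h}x{w} not reducible to {s}x{s}")
        k = h // s
        if k > 1:
            x = x.reshape(b, s, k, s, k, c).mean(axis=(2, 4))
        return x.transpose(0, 3, 1, 2)

    # -- forward / backward -------------------------------------------------
    def _features_cached(self, x):
        cache = {}
        a = self.conv1.forward(x)
        a, cache["r1"] = _relu_forward(a)
        a, cache["p1"] = _maxpool2_forward(a)
        a = self.conv2.forward(a)
        a, cache["r2"] = _relu_forward(a)
        a, cache["p2"] = _maxpool2_forward(a)
        a = self.conv3.forward(a)
        a, cache["r3"] = _relu_forward(a)
        cache["gap_hw"] = a.shape[2:]
        feats = a.mean(axis=(2, 3))
        return feats, cache

    def features(self, images: np.ndarray) -> np.ndarray:
        """Feature vectors for a batch of uint8 RGB images."""
        feats, _ = self._features_cached(self.prepare(images))
        return feats

    def forward_logits(self, x_nchw: np.ndarray):
        feats, cache = self._features_cached(x_nchw)
        logits = feats @ self.fc_w + self.fc_b
        cache["feats"] = feats
        return logits[:, 0], cache

    def backward(self, dlogits: np.ndarray, cache) -> None:
        """Backprop from d(loss)/d(logit); leaves gradients on the layers."""
        d = np.asarray(dlogits, dtype=np.float32)[:, None]
        feats = cache["feats"]
        self.dfc_w = feats.T @ d
        self.dfc_b = d.sum(axis=0)
        dfeats = d @ self.fc_w.T
        h, w = cache["gap_hw"]
        da = np.broadcast_to(
            dfeats[:, :, None, None] / (h * w), (len(dfeats), dfeats.shape[1], h, w)
        )
        da = da * cache["r3"]
        da = self.conv3.backward(da)
        da = _maxpool2_backward(da, cache["p2"])
        da = da * cache["r2"]
        da = self.conv2.backward(da)
        da = _maxpool2_backward(da, cache["p1"])
        da = da * cache["r1"]
        self.conv1.backward(da)

    # -- weights ------------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            "conv1_w": self.conv1.w.copy(),
            "conv1_b": self.conv1.b.copy(),
            "conv2_w": self.conv2.w.copy(),
            "conv2_b": self.conv2.b.copy(),
            "conv3_w": self.conv3.w.copy(),
            "conv3_b": self.conv3.b.copy(),
            "fc_w": self.fc_w.copy(),
            "fc_b": self.fc_b.copy(),
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        weights = {k: np.asarray(v, dtype=np.float32) for k, v in weights.items()}
        self.conv1.w = weights["conv1_w"].copy()
        self.conv1.b = weights["conv1_b"].copy()
        self.conv2.w = weights["conv2_w"].copy()
        self.conv2.b = weights["conv2_b"].copy()
        self.conv3.w = weights["conv3_w"].copy()
        self.conv3.b = weights["conv3_b"].copy()
        self.fc_w = weights["fc_w"].copy()
        self.fc_b = weights["fc_b"].copy()

    def _grads(self):
        return {
            "conv1_w": self.conv1.dw,
            "conv1_b": self.conv1.db,
            "conv2_w": self.conv2.dw,
            "conv2_b": self.conv2.db,
            "conv3_w": self.conv3.dw,
            "conv3_b": self.conv3.db,
            "fc_w": self.dfc_w,
            "fc_b": self.dfc_b,
        }

    def _apply(self, updates: dict[str, np.ndarray]) -> None:
        w = self.get_weights()
        self.set_weights({k: w[k] + updates[k] for k in w})


class Adam:
    """Standard Adam over a named parameter dict."""

    def __init__(self, lr: float = 0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, model: TinyCNN) -> None:
        grads = model._grads()
        self.t += 1
        updates = {}
        for k, g in grads.items():
            m = self.m.get(k, np.zeros_like(g))
            v = self.v.get(k, np.zeros_like(g))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            updates[k] = -self.lr * mhat / (np.sqrt(vhat) + self.eps)
        model._apply(updates)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy and its gradient w.r.t. the logits."""
    z, y = np.asarray(logits, float), np.asarray(y, float)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / len(z)
    return float(loss), dz
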