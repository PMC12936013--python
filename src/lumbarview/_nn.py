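"""Minimal CPU conv-net engine used by the segmenter and the CNN baseline.

Pure numpy, float32, manual backprop. Deterministic given a seed: every
random draw goes through a ``numpy.random.Generator`` owned by the caller,
and no threading or atomics are involved, so two runs with the same seed
produce bit-identical weights.

Layers cache whatever their backward pass needs on ``forward`` and release
it on ``backward``; a layer instance therefore handles one minibatch at a
time, which is all the training loops here require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Dense",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "UNet",
    "SmallConvNet",
    "binary_seg_loss",
    "multiclass_seg_loss",
    "softmax_ce_loss",
]

_F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_F32)
        self.grad = np.zeros_like(self.value)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)


class Conv2d:
    """3x3 (same-padded) or 1x1 convolution over (B, C, H, W) tensors.

    The 3x3 kernel is applied as nine shifted channel-mixing matmuls on a
    channels-last view, which is markedly faster than materializing the
    full im2col matrix on a single CPU core.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel))
        self.b = Param(np.zeros(c_out, dtype=_F32))
        self._cache = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = (b, c, h, w)
        if self.kernel == 1:
            xl = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # (B,H,W,C)
            self._cache = xl
            out = xl @ self.w.value[:, :, 0, 0].T + self.b.value
            return np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        xl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (B,H+2,W+2,C)
        self._cache = xl
        out = np.empty((b, h, w, self.c_out), dtype=_F32)
        out[...] = self.b.value
        for i in range(3):
            for j in range(3):
                out += xl[:, i : i + h, j : j + w, :] @ self.w.value[:, :, i, j].T
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (B,H,W,F)
        self.b.grad += gl.reshape(-1, self.c_out).sum(axis=0)
        xl = self._cache
        self._cache = None
        if self.kernel == 1:
            self.w.grad[:, :, 0, 0] += np.tensordot(gl, xl, axes=([0, 1, 2], [0, 1, 2]))
            dx = gl @ self.w.value[:, :, 0, 0]
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        dxp = np.zeros_like(xl)
        for i in range(3):
            for j in range(3):
                sub = xl[:, i : i + h, j : j + w, :]
                self.w.grad[:, :, i, j] += np.tensordot(
                    gl, sub, axes=([0, 1, 2], [0, 1, 2])
                )
                dxp[:, i : i + h, j : j + w, :] += gl @ self.w.value[:, :, i, j]
        dx = dxp[:, 1:-1, 1:-1, :].transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he(rng, (n_out, n_in), n_in))
        self.b = Param(np.zeros(n_out, dtype=_F32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        x = self._x
        self._x = None
        return g @ self.w.value


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, _F32(0))

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, g, _F32(0))
        self._mask = None
        return out


class MaxPool2:
    """2x2 max pooling with stride 2. Ties route gradient to the first max."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (b, c, h, w)
        return flat.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=_F32)
        np.put_along_axis(dflat, self._argmax[..., None], g[..., None], axis=-1)
        self._argmax = None
        dx = dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(b, c, h, w)


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = g.shape
        return g.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [
            Conv2d(c_in, c_out, rng),
            ReLU(),
            Conv2d(c_out, c_out, rng),
            ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet:
    """Symmetric encoder-decoder with skip connections.

    ``depth`` pooling stages; encoder channels ``base * 2**level``; each
    decoder stage upsamples, concatenates the matching encoder features and
    convolves back down. Output is a logit map with ``n_classes`` channels
    (``n_classes=1`` means a single foreground-vs-background logit).
    """

    def __init__(self, depth: int = 4, base_channels: int = 16, n_classes: int = 1, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base = base_channels
        self.n_classes = n_classes
        self.enc = []
        c_in = 1
        for lvl in range(depth):
            c = base_channels * (2 ** lvl)
            self.enc.append(_ConvBlock(c_in, c, rng))
            c_in = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(c_in, c_in * 2, rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        c_up = c_in * 2
        for lvl in reversed(range(depth)):
            c_skip = base_channels * (2 ** lvl)
            self.dec.append(_ConvBlock(c_up + c_skip, c_skip, rng))
            c_up = c_skip
        self.head = Conv2d(c_up, n_classes, rng, kernel=1)
        # bias the logits toward a ~10% foreground prior so the first
        # epochs see a usable overlap gradient instead of the
        # all-background local minimum
        if n_classes == 1:
            self.head.b.value[...] = -2.2
        else:
            self.head.b.value[1:] = -2.2
        self._skip_channels = [base_channels * (2 ** l) for l in reversed(range(depth))]

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def check_input(self, hw):
        h, w = hw
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {hw} must be divisible by 2**depth = {f}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.check_input(x.shape[2:])
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for blk, up in zip(self.dec, self.ups):
            x = up.forward(x)
            skip = skips.pop()
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, g: np.ndarray):
        g = self.head.backward(g)
        skip_grads = []
        for blk, up, c_skip in zip(
            reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)
        ):
            g = blk.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        for blk, pool in zip(reversed(self.enc), reversed(self.pools)):
            g = pool.backward(g)
            g = g + skip_grads.pop()  # deepest skip first, matching reversed(enc)
            g = blk.backward(g)
        return g

    # ---- weight (de)serialization ----------------------------------------
    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        ps = self.params()
        if len(weights) != len(ps):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(ps, weights):
            p.value = np.asarray(w, dtype=_F32).copy()


class SmallConvNet:
    """Plain image classifier used as the end-to-end baseline: three
    conv-pool stages, two further poolings down to a 7x7 map (for 224
    input), then a small dense head. Flattening (rather than global
    average pooling) keeps the coarse spatial layout, which is the signal
    that separates the two views."""

    def __init__(self, n_classes: int = 2, base_channels: int = 8, seed: int = 0, input_size: int = 224):
        if input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        rng = np.random.default_rng(seed)
        c = base_channels
        self.input_size = input_size
        self.blocks = [
            Conv2d(1, c, rng), ReLU(), MaxPool2(),
            Conv2d(c, 2 * c, rng), ReLU(), MaxPool2(),
            Conv2d(2 * c, 4 * c, rng), ReLU(), MaxPool2(),
            MaxPool2(), MaxPool2(),
        ]
        side = input_size // 32
        self.fc1 = Dense(4 * c * side * side, 32, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(32, n_classes, rng)
        self._map_shape = None

    def params(self):
        ps = [p for l in self.blocks for p in l.params()]
        return ps + self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.blocks:
            x = l.forward(x)
        self._map_shape = x.shape
        h = self.fc1.forward(x.reshape(x.shape[0], -1))
        return self.fc2.forward(self.fc_relu.forward(h))

    def backward(self, g: np.ndarray):
        g = self.fc2.backward(g)
        g = self.fc_relu.backward(g)
        g = self.fc1.backward(g)
        g = g.reshape(self._map_shape)
        for l in reversed(self.blocks):
            g = l.backward(g)
        return g

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        ps = self.params()
        if len(weights) != len(ps):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(ps, weights):
            p.value = np.asarray(w, dtype=_F32).copy()


# ---- losses --------------------------------------------------------------

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_seg_loss(logits: np.ndarray, target: np.ndarray, kind: str = "bce+dice"):
    """Loss and logit-gradient for single-foreground segmentation.

    logits, target: (B, 1, H, W); target in {0, 1}. ``kind`` is one of
    bce / dice / bce+dice. Dice is computed as a single soft overlap over
    the whole batch, which keeps its gradient well-scaled for tiny batches.
    """
    p = _sigmoid(logits.astype(np.float64))
    y = target.astype(np.float64)
    n = y.size
    loss = 0.0
    dp = np.zeros_like(p)
    dlogits = np.zeros_like(p)
    if "bce" in kind:
        eps = 1e-12
        loss += float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogits += (p - y) / n  # BCE-with-logits gradient, numerically exact
    if "dice" in kind:
        s = 1.0
        inter = float((p * y).sum())
        union = float(p.sum() + y.sum())
        loss += 1.0 - (2 * inter + s) / (union + s)
        dp += -(2 * y * (union + s) - (2 * inter + s)) / (union + s) ** 2
        dlogits += dp * p * (1 - p)
    return loss, dlogits.astype(_F32)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def multiclass_seg_loss(logits: np.ndarray, target: np.ndarray, kind: str = "bce+dice"):
    """Cross-entropy (+ mean foreground soft-dice) for (B, K, H, W) logits
    against integer targets (B, H, W) in {0..K-1}."""
    b, k, h, w = logits.shape
    p = _softmax(logits.astype(np.float64))
    onehot = np.zeros_like(p)
    idx = np.indices(target.shape)
    onehot[idx[0], target, idx[1], idx[2]] = 1.0
    n = b * h * w
    loss = 0.0
    dp = np.zeros_like(p)
    dlogits = np.zeros_like(p)
    if "bce" in kind:  # cross-entropy in the multi-class variant
        eps = 1e-12
        loss += float(-(onehot * np.log(p + eps)).sum() / n)
        dlogits += (p - onehot) / n
    if "dice" in kind:
        s = 1.0
        fg = range(1, k)
        for c in fg:
            pc, yc = p[:, c], onehot[:, c]
            inter = float((pc * yc).sum())
            union = float(pc.sum() + yc.sum())
            loss += (1.0 - (2 * inter + s) / (union + s)) / len(list(fg))
            dp[:, c] += (
                -(2 * yc * (union + s) - (2 * inter + s)) / (union + s) ** 2
            ) / (k - 1)
        # softmax jacobian: dz_c = p_c * (dp_c - sum_j dp_j p_j)
        dot = (dp * p).sum(axis=1, keepdims=True)
        dlogits += p * (dp - dot)
    return loss, dlogits.astype(_F32)


def softmax_ce_loss(logits: np.ndarray, target: np.ndarray):
    """Cross-entropy for (B, K) classifier logits against integer labels."""
    p = _softmax(logits.astype(np.float64))
    b = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(b), target] + eps).mean())
    d = p.copy()
    d[np.arange(b), target] -= 1.0
    return loss, (d / b).astype(_F32)
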