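"""Minimal CNN engine (numpy, manual backprop).

Just enough machinery to express and train the five decoder
architectures on CPU: 2-D/3-D/depthwise convolutions, batch
normalisation, ELU/square/log nonlinearities, average pooling, dropout,
dense layers, an L2 input normalisation, softmax cross-entropy, and an
Adam loop with early stopping.  Everything is float32 and deterministic
for a fixed seed.

Layers follow a tiny protocol: ``forward(x, training)`` caches what the
matching ``backward(grad)`` needs; parameters and their gradients are
exposed as parallel lists for the optimizer.  ``Sequential`` and
``ParallelSum`` are themselves layers, which is how the multi-branch
model is composed.
"""

from __future__ import annotations

import numpy as np

F = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F)


class Layer:
    """Base: stateless unless it declares params/grads."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.state: list[np.ndarray] = []   # non-trained buffers (BN stats)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class L2Norm(Layer):
    """Scale each sample to unit Euclidean norm over all its elements."""

    def forward(self, x, training=False):
        flat = x.reshape(x.shape[0], -1)
        self._norm = np.linalg.norm(flat, axis=1, keepdims=True).astype(F)
        self._norm[self._norm == 0] = 1.0
        self._y = (flat / self._norm).reshape(x.shape)
        return self._y

    def backward(self, grad):
        g = grad.reshape(grad.shape[0], -1)
        y = self._y.reshape(g.shape)
        proj = np.sum(g * y, axis=1, keepdims=True)
        return ((g - y * proj) / self._norm).reshape(grad.shape)


class AddChannel(Layer):
    """Append a trailing singleton channel axis."""

    def forward(self, x, training=False):
        return x[..., None]

    def backward(self, grad):
        return grad[..., 0]


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=F) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        if self.b is not None:
            self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


def _pad_hw(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))


class Conv2D(Layer):
    """NHWC 2-D convolution, stride 1, 'same' or 'valid' padding (im2col)."""

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator, padding: str = "same", bias: bool = True):
        super().__init__()
        self.kh, self.kw, self.padding = kh, kw, padding
        fan_in = kh * kw * in_ch
        self.w = _glorot(rng, (kh * kw * in_ch, out_ch), fan_in, out_ch)
        self.b = np.zeros(out_ch, dtype=F) if bias else None
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    def _pads(self, h, w):
        if self.padding == "same":
            return (self.kh - 1) // 2, (self.kw - 1) // 2, \
                   self.kh - 1 - (self.kh - 1) // 2, self.kw - 1 - (self.kw - 1) // 2
        return 0, 0, 0, 0

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        pt, pl, pb, pr = self._pads(h, w)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if self.padding == "same" else x
        oh, ow = xp.shape[1] - self.kh + 1, xp.shape[2] - self.kw + 1
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # view: (n, oh, ow, c, kh, kw) -> cols (n*oh*ow, kh*kw*c)
        cols = view.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, -1).astype(F)
        self._cols, self._xshape, self._pads_cache = cols, x.shape, (pt, pl, pb, pr)
        self._out_hw = (oh, ow)
        y = cols @ self.w
        if self.b is not None:
            y = y + self.b
        return y.reshape(n, oh, ow, self.out_ch)

    def backward(self, grad):
        n, h, w, c = self._xshape
        oh, ow = self._out_hw
        g = grad.reshape(n * oh * ow, self.out_ch)
        self.grads[0][...] = self._cols.T @ g
        if self.b is not None:
            self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.w.T).reshape(n, oh, ow, self.kh, self.kw, c)
        pt, pl, pb, pr = self._pads_cache
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=F)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class DepthwiseSpatialConv(Layer):
    """Full-height depthwise conv (kernel H x 1, depth multiplier D).

    Collapses the spatial (electrode) axis: (n, H, T, C) -> (n, 1, T, C*D).
    """

    def __init__(self, height: int, in_ch: int, depth_mult: int,
                 rng: np.random.Generator, bias: bool = False):
        super().__init__()
        self.h, self.c, self.d = height, in_ch, depth_mult
        self.w = _glorot(rng, (height, in_ch, depth_mult), height, depth_mult)
        self.b = np.zeros(in_ch * depth_mult, dtype=F) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        self._x = x
        n, h, t, c = x.shape
        y = np.einsum("nhtc,hcd->ntcd", x, self.w, optimize=True)
        y = y.reshape(n, 1, t, c * self.d)
        if self.b is not None:
            y = y + self.b
        return y.astype(F)

    def backward(self, grad):
        n, _, t, _ = grad.shape
        g = grad.reshape(n, t, self.c, self.d)
        self.grads[0][...] = np.einsum("nhtc,ntcd->hcd", self._x, g, optimize=True)
        if self.b is not None:
            self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        return np.einsum("ntcd,hcd->nhtc", g, self.w, optimize=True).astype(F)


class DepthwiseTemporalConv(Layer):
    """Per-channel temporal conv (1 x k kernel, 'same' padding)."""

    def __init__(self, k: int, in_ch: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.c = k, in_ch
        self.w = _glorot(rng, (k, in_ch), k, 1)
        self.params = [self.w]
        self.grads = [np.zeros_like(self.w)]

    def forward(self, x, training=False):
        n, h, t, c = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        self._xp, self._t = xp, t
        y = np.zeros_like(x)
        for dt in range(self.k):
            y += xp[:, :, dt:dt + t, :] * self.w[dt]
        return y

    def backward(self, grad):
        t = self._t
        for dt in range(self.k):
            self.grads[0][dt] = np.sum(self._xp[:, :, dt:dt + t, :] * grad, axis=(0, 1, 2))
        pl = (self.k - 1) // 2
        dxp = np.zeros_like(self._xp)
        for dt in range(self.k):
            dxp[:, :, dt:dt + t, :] += grad * self.w[dt]
        return dxp[:, :, pl:pl + t, :]


class Conv3D(Layer):
    """N x (D1, D2, T, C) 3-D convolution; 'same' on the two spatial axes,
    'valid' on time.  Implemented as a sum of shifted matmuls, which is
    memory-friendly for small spatial grids."""

    def __init__(self, in_ch: int, out_ch: int, k1: int, k2: int, kt: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.k1, self.k2, self.kt = k1, k2, kt
        fan_in = k1 * k2 * kt * in_ch
        self.w = _glorot(rng, (k1, k2, kt, in_ch, out_ch), fan_in, out_ch)
        self.b = np.zeros(out_ch, dtype=F) if bias else None
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        n, d1, d2, t, c = x.shape
        if t < self.kt:
            raise ValueError(f"time axis ({t}) shorter than temporal kernel ({self.kt})")
        p1, p2 = (self.k1 - 1) // 2, (self.k2 - 1) // 2
        q1, q2 = self.k1 - 1 - p1, self.k2 - 1 - p2
        xp = np.pad(x, ((0, 0), (p1, q1), (p2, q2), (0, 0), (0, 0)))
        ot = t - self.kt + 1
        self._xp, self._xshape, self._ot = xp, x.shape, ot
        y = np.zeros((n, d1, d2, ot, self.out_ch), dtype=F)
        for i in range(self.k1):
            for j in range(self.k2):
                for dt in range(self.kt):
                    seg = xp[:, i:i + d1, j:j + d2, dt:dt + ot, :]
                    y += seg @ self.w[i, j, dt]
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, grad):
        n, d1, d2, t, c = self._xshape
        ot = self._ot
        dxp = np.zeros_like(self._xp)
        for i in range(self.k1):
            for j in range(self.k2):
                for dt in range(self.kt):
                    seg = self._xp[:, i:i + d1, j:j + d2, dt:dt + ot, :]
                    self.grads[0][i, j, dt] = np.tensordot(
                        seg, grad, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                    dxp[:, i:i + d1, j:j + d2, dt:dt + ot, :] += grad @ self.w[i, j, dt].T
        if self.b is not None:
            self.grads[1][...] = grad.sum(axis=(0, 1, 2, 3))
        p1, p2 = (self.k1 - 1) // 2, (self.k2 - 1) // 2
        return dxp[:, p1:p1 + d1, p2:p2 + d2, :, :]


class BatchNorm(Layer):
    """Batch normalisation over the last (channel) axis."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_ch, dtype=F)
        self.beta = np.zeros(n_ch, dtype=F)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(n_ch, dtype=F)
        self.run_var = np.ones(n_ch, dtype=F)
        self.state = [self.run_mean, self.run_var]
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps).astype(F)
        self._xhat = ((x - mean) / self._std).astype(F)
        self._m = x.size // x.shape[-1]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads[0][...] = np.sum(grad * self._xhat, axis=axes)
        self.grads[1][...] = np.sum(grad, axis=axes)
        if not self._training:
            return grad * self.gamma / self._std
        m = self._m
        gx = grad * self.gamma
        return (gx - gx.mean(axis=axes)
                - self._xhat * np.mean(gx * self._xhat, axis=axes)) / self._std


class ELU(Layer):
    def forward(self, x, training=False):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0)), 0.0).astype(F)
        return np.where(self._neg, self._expm1, x)

    def backward(self, grad):
        return np.where(self._neg, grad * (self._expm1 + 1.0), grad)


class Square(Layer):
    def forward(self, x, training=False):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad


class LogAct(Layer):
    """log(max(x, eps)) — used after the squaring/pooling band-power stage."""

    def __init__(self, eps: float = 1e-6):
        super().__init__()
        self.eps = eps

    def forward(self, x, training=False):
        self._xc = np.maximum(x, self.eps)
        return np.log(self._xc)

    def backward(self, grad):
        return grad / self._xc


class AvgPoolTime(Layer):
    """Average pooling along the time axis of (n, H, T, C); may overlap."""

    def __init__(self, width: int, stride: int):
        super().__init__()
        self.width, self.stride = width, stride

    def forward(self, x, training=False):
        n, h, t, c = x.shape
        starts = np.arange(0, t - self.width + 1, self.stride)
        self._starts, self._tin = starts, t
        y = np.empty((n, h, len(starts), c), dtype=F)
        for k, s in enumerate(starts):
            y[:, :, k, :] = x[:, :, s:s + self.width, :].mean(axis=2)
        return y

    def backward(self, grad):
        n, h, _, c = grad.shape
        dx = np.zeros((n, h, self._tin, c), dtype=F)
        for k, s in enumerate(self._starts):
            dx[:, :, s:s + self.width, :] += grad[:, :, k:k + 1, :] / self.width
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate).astype(F) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, _):   # base-class ctor writes []; ignore
        pass

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, _):
        pass

    @property
    def state(self):
        return [s for l in self.layers for s in l.state]

    @state.setter
    def state(self, _):
        pass

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ParallelSum(Layer):
    """Feed the same input through several stacks and sum the outputs."""

    def __init__(self, branches: list[Sequential]):
        super().__init__()
        self.branches = branches

    @property
    def params(self):
        return [p for b in self.branches for p in b.params]

    @params.setter
    def params(self, _):
        pass

    @property
    def grads(self):
        return [g for b in self.branches for g in b.grads]

    @grads.setter
    def grads(self, _):
        pass

    @property
    def state(self):
        return [s for b in self.branches for s in b.state]

    @state.setter
    def state(self, _):
        pass

    def forward(self, x, training=False):
        outs = [b.forward(x, training=training) for b in self.branches]
        return np.sum(outs, axis=0)

    def backward(self, grad):
        dxs = [b.backward(grad) for b in self.branches]
        return np.sum(dxs, axis=0)


# ---------------------------------------------------------------------------
# loss + optimizer + training loop

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y_idx: np.ndarray):
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), y_idx], 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, (grad / n).astype(F)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Network:
    """A root layer plus softmax cross-entropy loss and an Adam fit loop."""

    def __init__(self, root: Layer, n_classes: int):
        self.root = root
        self.n_classes = n_classes
        self.history: dict[str, list] = {"loss": [], "val_loss": [], "val_accuracy": []}

    # --- weights (trained parameters + batch-norm running stats) -----------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.root.params + self.root.state]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.root.params + self.root.state, weights):
            p[...] = w

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.root.params))

    # --- inference ---------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.root.forward(x[i:i + batch_size].astype(F), training=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.vstack(out)

    # --- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y_idx: np.ndarray, epochs: int = 50,
            batch_size: int = 32, lr: float = 1e-3,
            val: tuple[np.ndarray, np.ndarray] | None = None,
            patience: int | None = None, seed: int = 0,
            shuffle: bool = True) -> "Network":
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        if y_idx.min() < 0 or y_idx.max() >= self.n_classes:
            raise ValueError("label outside the class set")
        rng = np.random.default_rng(seed)
        x = x.astype(F)
        opt = Adam(self.root.params, lr=lr)
        best_val = np.inf
        best_weights = None
        since_best = 0
        for _epoch in range(epochs):
            order = rng.permutation(x.shape[0]) if shuffle else np.arange(x.shape[0])
            losses = []
            for i in range(0, len(order), batch_size):
                idx = order[i:i + batch_size]
                logits = self.root.forward(x[idx], training=True)
                loss, dlogits = softmax_xent(logits, y_idx[idx])
                self.root.backward(dlogits)
                opt.step(self.root.grads)
                losses.append(loss)
            self.history["loss"].append(float(np.mean(losses)))
            if val is not None:
                p = self.predict_proba(val[0])
                vl = -np.mean(np.log(np.maximum(
                    p[np.arange(len(val[1])), val[1]], 1e-12)))
                va = float(np.mean(p.argmax(axis=1) == val[1]))
                self.history["val_loss"].append(float(vl))
                self.history["val_accuracy"].append(va)
                if vl < best_val - 1e-6:
                    best_val = vl
                    best_weights = self.get_weights()
                    since_best = 0
                else:
                    since_best += 1
                    if patience is not None and since_best >= patience:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self
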