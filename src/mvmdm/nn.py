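"""A small NumPy neural-network engine for the three classification routes.

Implements exactly the layer vocabulary the route architectures need —
N-dimensional valid convolutions (stride 1), max pooling, batch
normalization, dense layers, dropout, flatten — with explicit
backpropagation, the Adam optimizer and a binary-cross-entropy objective on
a single sigmoid output unit.  Channels-last layout throughout: inputs are
``(batch, *spatial, channels)``.

Everything stochastic (weight initialization, epoch shuffling, dropout
masks) draws from one seeded generator, so a fixed seed reproduces training
bit for bit on a single device.  Convolutions are evaluated by accumulating
BLAS matrix products over kernel offsets, which is memory-lean and fast for
the small (<= 3-tap) kernels used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv",
    "MaxPool",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "Network",
    "bce_with_logits",
]

_DTYPE = np.float32


def _as_tuple(k) -> tuple[int, ...]:
    return (k,) if isinstance(k, int) else tuple(int(v) for v in k)


class Layer:
    """Base layer: parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str = "relu") -> None:
        super().__init__()
        if activation not in ("relu", "none"):
            raise ValueError(f"unsupported dense activation {activation!r}")
        self.n_in, self.n_out, self.activation = n_in, n_out, activation
        self.W = np.zeros((n_in, n_out), dtype=_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def initialize(self, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (self.n_in + self.n_out))
        self.W[...] = rng.uniform(-limit, limit, size=self.W.shape).astype(_DTYPE)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            g = g * self._mask
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Conv(Layer):
    """Valid, stride-1 N-dimensional convolution (N = 1, 2 or 3)."""

    def __init__(self, kernel, c_in: int, c_out: int, activation: str = "relu") -> None:
        super().__init__()
        if activation not in ("relu", "none"):
            raise ValueError(f"unsupported conv activation {activation!r}")
        self.kernel = _as_tuple(kernel)
        self.ndim = len(self.kernel)
        self.c_in, self.c_out, self.activation = c_in, c_out, activation
        self.W = np.zeros(self.kernel + (c_in, c_out), dtype=_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = int(np.prod(self.kernel)) * self.c_in
        fan_out = int(np.prod(self.kernel)) * self.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W[...] = rng.uniform(-limit, limit, size=self.W.shape).astype(_DTYPE)
        self.b[...] = 0.0

    def _offsets(self):
        return np.ndindex(*self.kernel)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        spatial_in = x.shape[1:-1]
        out_sp = tuple(n - k + 1 for n, k in zip(spatial_in, self.kernel))
        if any(n < 1 for n in out_sp):
            raise ValueError(f"input spatial shape {spatial_in} too small for kernel {self.kernel}")
        self._x = x
        self._out_sp = out_sp
        z = np.empty((x.shape[0], *out_sp, self.c_out), dtype=_DTYPE)
        z[...] = self.b
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, out_sp))
            z += self._x[sl] @ self.W[off]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            g = g * self._mask
        axes = tuple(range(g.ndim - 1))  # batch + spatial
        self.grads[1][...] = g.sum(axis=axes)
        dx = np.zeros_like(self._x)
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, self._out_sp))
            xs = self._x[sl]
            self.grads[0][off] = np.tensordot(xs, g, axes=(axes, axes))
            dx[sl] += g @ self.W[off].T
        return dx


class MaxPool(Layer):
    """Non-overlapping N-dimensional max pooling (stride = window)."""

    def __init__(self, pool) -> None:
        super().__init__()
        self.pool = _as_tuple(pool)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = len(self.pool)
        spatial = x.shape[1 : 1 + d]
        out_sp = tuple(n // p for n, p in zip(spatial, self.pool))
        if any(n < 1 for n in out_sp):
            raise ValueError(f"spatial shape {spatial} smaller than pool {self.pool}")
        crop = (slice(None),) + tuple(slice(0, o * p) for o, p in zip(out_sp, self.pool)) + (
            slice(None),
        )
        xc = x[crop]
        inter = [x.shape[0]]
        for o, p in zip(out_sp, self.pool):
            inter += [o, p]
        inter.append(x.shape[-1])
        xr = xc.reshape(inter)
        perm = [0] + [1 + 2 * i for i in range(d)] + [1 + 2 * d] + [2 + 2 * i for i in range(d)]
        xp = xr.transpose(perm)  # (B, *out_sp, C, *pool)
        flat = xp.reshape(xp.shape[: d + 2] + (-1,))
        self._idx = flat.argmax(axis=-1)
        self._x_shape, self._crop, self._inter, self._perm = x.shape, crop, inter, perm
        self._flat_shape, self._xp_shape = flat.shape, xp.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gflat = np.zeros(self._flat_shape, dtype=g.dtype)
        np.put_along_axis(gflat, self._idx[..., None], g[..., None], axis=-1)
        gp = gflat.reshape(self._xp_shape)
        inv = np.argsort(self._perm)
        gr = gp.transpose(inv).reshape(self._inter)
        dx = np.zeros(self._x_shape, dtype=g.dtype)
        dx[self._crop] = gr.reshape(dx[self._crop].shape)
        return dx


class BatchNorm(Layer):
    """Channel-wise batch normalization (channels-last), Keras bookkeeping:
    gamma/beta trainable, running mean/variance non-trainable."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = np.ones(channels, dtype=_DTYPE)
        self.beta = np.zeros(channels, dtype=_DTYPE)
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._axes = axes
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = self._axes
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        if not self._training:
            # running statistics are constants w.r.t. the input
            return (self.gamma * self._inv_std) * g
        gm = g.mean(axis=axes)
        gxm = (g * self._xhat).mean(axis=axes)
        return (self.gamma * self._inv_std) * (g - gm - self._xhat * gxm)


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        assert self.rng is not None, "dropout layer not bound to a network rng"
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask.astype(g.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.ravel().astype(np.float64)
    y = y.ravel().astype(np.float64)
    loss = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class Network:
    """An ordered stack of layers ending in one sigmoid output unit.

    The final dense layer produces a logit; the sigmoid and the
    binary-cross-entropy objective are fused in training for stability.
    """

    def __init__(self, layers: list[Layer], seed: int = 0) -> None:
        self.layers = layers
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(self.rng)
            if isinstance(layer, Dropout):
                layer.rng = self.rng

    # -- inference ---------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out.ravel()

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            z = self.forward_logits(x[i : i + batch_size], training=False).astype(np.float64)
            probs.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- parameter bookkeeping --------------------------------------------
    def _all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def _all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        state = [p.copy() for p in self._all_params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self._all_params()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = state[len(params) :]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2

    def _calibrate_batchnorm(self, x: np.ndarray) -> None:
        """Set batch-normalization running statistics to the exact training
        set activation moments (one full-batch pass; the few momentum-decayed
        updates accumulated during short runs are poor estimates)."""
        if not any(isinstance(layer, BatchNorm) for layer in self.layers):
            return
        out = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                saved = layer.momentum
                layer.momentum = 0.0
                out = layer.forward(out, training=True)
                layer.momentum = saved
            else:
                out = layer.forward(out, training=False)

    # -- training ----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        restore_best: bool = True,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam training; returns the per-epoch history.

        With validation data the weights from the epoch with the lowest
        validation loss are restored at the end (checkpointing).
        """
        x = np.asarray(x, dtype=_DTYPE)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(x) != len(y):
            raise ValueError("feature/label lengths differ")
        if epochs < 0:
            raise ValueError("epochs must be >= 0")
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        has_val = x_val is not None and y_val is not None
        if has_val:
            history["val_loss"] = []
            history["val_accuracy"] = []
        if epochs == 0:
            return history
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        opt = _Adam(self._all_params(), lr=learning_rate)
        best_val, best_state = np.inf, None
        n = len(x)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                out = xb
                for layer in self.layers:
                    out = layer.forward(out, training=True)
                z = out.ravel()
                loss = bce_with_logits(z, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss ({loss}) at step {opt.t + 1}; "
                        f"logit range [{z.min():.3g}, {z.max():.3g}]"
                    )
                p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
                g = ((p - yb) / len(yb)).astype(_DTYPE).reshape(out.shape)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.step(self._all_grads())
                epoch_loss += loss * len(yb)
                epoch_correct += int(((p >= 0.5) == (yb >= 0.5)).sum())
            history["loss"].append(epoch_loss / n)
            history["accuracy"].append(epoch_correct / n)
            if has_val:
                zv = []
                for i in range(0, len(x_val), batch_size):
                    zv.append(self.forward_logits(x_val[i : i + batch_size]))
                zv = np.concatenate(zv)
                vl = bce_with_logits(zv, y_val)
                pv = 1.0 / (1.0 + np.exp(-zv.astype(np.float64)))
                history["val_loss"].append(vl)
                history["val_accuracy"].append(float(((pv >= 0.5) == (y_val >= 0.5)).mean()))
                if vl < best_val:
                    best_val, best_state = vl, self.get_weights()
        if has_val and restore_best and best_state is not None:
            self.set_weights(best_state)
        self._calibrate_batchnorm(x)
        return history
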