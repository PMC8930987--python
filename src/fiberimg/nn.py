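"""Compact numpy neural-network trainer (dense MLPs and a small U-Net).

Everything runs in float32 on the CPU with Adam and mini-batch SGD, and is
deterministic for a fixed seed in a single-threaded BLAS. The scale of the
problems here (4096-sample waveforms, 64x64 images, 1e4 training pairs) is
comfortably within reach of a well-vectorised numpy implementation.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["MLP", "UNet"]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _sigmoid(x):
    # numerically stable in float32 for large |x|
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x):
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Fully connected network with ReLU hidden layers.

    output: 'sigmoid' (with MSE loss), 'linear' (MSE) or 'softmax'
    (cross-entropy with integer labels). He-initialised; trained with Adam.
    """

    def __init__(self, layer_sizes: list[int], output: str = "sigmoid", seed: int = 0):
        if output not in ("sigmoid", "linear", "softmax"):
            raise ValueError(f"unknown output {output!r}")
        self.sizes = list(layer_sizes)
        self.output = output
        rng = np.random.default_rng(seed)
        self.W = [
            (rng.normal(0, math.sqrt(2.0 / n_in), size=(n_in, n_out))).astype(np.float32)
            for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:])
        ]
        self.b = [np.zeros(n, dtype=np.float32) for n in layer_sizes[1:]]
        self.seed = seed

    # forward keeping activations for backprop
    def _forward(self, x):
        acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if i < last:
                h = np.maximum(z, 0.0)
            elif self.output == "sigmoid":
                h = _sigmoid(z)
            elif self.output == "softmax":
                h = _softmax(z)
            else:
                h = z
            acts.append(h)
        return acts

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self._forward(x[i : i + batch_size])[-1] for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 64,
        lr: float | "callable" = 1e-3,
        seed: int | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """Train; returns per-epoch mean loss. Raises on divergent (NaN) loss.

        ``lr`` may be a callable epoch -> learning rate (e.g. step decay).
        """
        x = np.asarray(x, dtype=np.float32)
        if self.output == "softmax":
            y_int = np.asarray(y, dtype=np.int64)
        else:
            y_f = np.asarray(y, dtype=np.float32)
        n = len(x)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        lr_fn = lr if callable(lr) else (lambda _e: lr)
        opt = _Adam(self.W + self.b, lr=lr_fn(0))
        history = []
        last = len(self.W) - 1
        for epoch in range(epochs):
            opt.lr = lr_fn(epoch)
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = x[idx]
                acts = self._forward(xb)
                out = acts[-1]
                m = len(idx)
                if self.output == "softmax":
                    yb = y_int[idx]
                    loss = -np.log(np.maximum(out[np.arange(m), yb], 1e-12)).mean()
                    delta = out.copy()
                    delta[np.arange(m), yb] -= 1.0
                    delta /= m
                else:
                    yb = y_f[idx]
                    diff = out - yb
                    loss = float((diff**2).mean())
                    # dL/dz for MSE: sigmoid output folds in s'(z)
                    delta = 2.0 * diff / diff.size
                    if self.output == "sigmoid":
                        delta = delta * out * (1.0 - out)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {epoch}"
                    )
                total += float(loss) * m
                gW = [None] * len(self.W)
                gb = [None] * len(self.b)
                for i in range(last, -1, -1):
                    a_prev = acts[i]
                    gW[i] = a_prev.T @ delta
                    gb[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.W[i].T
                        delta = delta * (acts[i] > 0)
                opt.step(gW + gb)
            history.append(total / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss {history[-1]:.6g}")
        return history

    def get_weights(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_weights(self, weights: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [np.asarray(w, dtype=np.float32) for w in weights[:k]]
        self.b = [np.asarray(w, dtype=np.float32) for w in weights[k:]]


# --------------------------------------------------------------------------
# U-Net


def _im2col(x: np.ndarray) -> np.ndarray:
    """(n, c, h, w) -> (n*h*w, c*9) patches for 3x3 same-padding conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # cols: (n, c, h, w, 3, 3) -> (n, h, w, c, 3, 3)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter (n*h*w, c*9) gradients back to (n,c,h,w)."""
    n, c, h, w = shape
    grad = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    cols = cols.reshape(n, h, w, c, 3, 3)
    for di in range(3):
        for dj in range(3):
            grad[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return grad[:, :, 1 : 1 + h, 1 : 1 + w]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0, math.sqrt(2.0 / (c_in * 9)), size=(c_in * 9, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x)
        n, _, h, w = x.shape
        out = self.cols @ self.W + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, c_out, h, w = gout.shape
        g = gout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.gW = self.cols.T @ g
        self.gb = g.sum(axis=0)
        gcols = g @ self.W.T
        return _col2im(gcols, self.x_shape)


class UNet:
    """Small 4-level encoder-decoder on (1, 64, 64) inputs with skips.

    Per level one 3x3 conv + ReLU; 2x2 max-pool down, nearest-neighbour up;
    skip connections by channel concatenation; 3x3 conv + sigmoid head.
    Channel widths double per level from ``base_channels``.
    """

    def __init__(self, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.enc = [_Conv3x3(1, c, rng), _Conv3x3(c, 2 * c, rng),
                    _Conv3x3(2 * c, 4 * c, rng), _Conv3x3(4 * c, 8 * c, rng)]
        self.dec = [_Conv3x3(8 * c + 4 * c, 4 * c, rng),
                    _Conv3x3(4 * c + 2 * c, 2 * c, rng),
                    _Conv3x3(2 * c + c, c, rng)]
        self.head = _Conv3x3(c, 1, rng)
        self.seed = seed

    def _layers(self):
        return self.enc + self.dec + [self.head]

    @staticmethod
    def _pool(x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        return out, mask

    @staticmethod
    def _unpool_grad(g, mask):
        n, c, h2, w2 = g.shape
        return (mask * g[:, :, :, None, :, None]).reshape(n, c, h2 * 2, w2 * 2)

    @staticmethod
    def _up(x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    @staticmethod
    def _down_grad(g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def forward(self, x, train=False):
        acts = {}
        skips = []
        h = x
        for i, conv in enumerate(self.enc):
            z = conv.forward(h)
            a = np.maximum(z, 0.0)
            acts[f"enc{i}"] = a
            if i < len(self.enc) - 1:
                skips.append(a)
                a, mask = self._pool(a)
                acts[f"mask{i}"] = mask
            h = a
        for i, conv in enumerate(self.dec):
            up = self._up(h)
            skip = skips[-(i + 1)]
            h = np.concatenate([up, skip], axis=1)
            acts[f"cat{i}"] = h.shape[1] - skip.shape[1]  # channels from up-path
            z = conv.forward(h)
            h = np.maximum(z, 0.0)
            acts[f"dec{i}"] = h
        out = _sigmoid(self.head.forward(h))
        if train:
            self._acts, self._skip_channels = acts, [s.shape[1] for s in skips]
        return out

    def _backward(self, x, out, delta_out):
        acts = self._acts
        delta = delta_out * out * (1.0 - out)
        g = self.head.backward(delta)
        for i in range(len(self.dec) - 1, -1, -1):
            g = g * (acts[f"dec{i}"] > 0)
            gcat = self.dec[i].backward(g)
            c_up = acts[f"cat{i}"]
            g_up, g_skip = gcat[:, :c_up], gcat[:, c_up:]
            g = self._down_grad(g_up)
            self._skip_grads[len(self.dec) - 1 - i] = g_skip
        # encoder: walk back up, adding skip gradients
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                g = self._unpool_grad(g, acts[f"mask{i}"])
                g = g + self._skip_grads[i]
            g = g * (acts[f"enc{i}"] > 0)
            g = self.enc[i].backward(g)
        return g

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    def fit(self, x, y, epochs=10, batch_size=16, lr=1e-3, seed=None, verbose=False):
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        layers = self._layers()
        params = [p for conv in layers for p in (conv.W, conv.b)]
        opt = _Adam(params, lr=lr)
        history = []
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                out = self.forward(xb, train=True)
                diff = out - yb
                loss = float((diff**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                total += loss * len(idx)
                self._skip_grads = [None] * (len(self.enc) - 1)
                self._backward(xb, out, 2.0 * diff / diff.size)
                grads = [g for conv in layers for g in (conv.gW, conv.gb)]
                opt.step(grads)
            history.append(total / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss {history[-1]:.6g}")
        return history

    def get_weights(self) -> list[np.ndarray]:
        return [p for conv in self._layers() for p in (conv.W, conv.b)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for conv in self._layers():
            conv.W = np.asarray(next(it), dtype=np.float32)
            conv.b = np.asarray(next(it), dtype=np.float32)
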