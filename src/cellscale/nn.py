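"""Minimal CPU neural-network engine for the size classifier.

A small, fully deterministic numpy implementation of the pieces the
classifier needs: 3x3 same-padding convolutions (im2col), ReLU, 2x2 max
pooling, global average pooling, a linear head, softmax cross-entropy,
and the AdamW optimizer (decoupled weight decay). Layers are functional
— ``forward`` returns ``(output, cache)`` and ``backward`` consumes the
cache — so the same network can run two forward passes (the
dual-background pair) before a single backward accumulation.

The default backbone, ``tiny_cnn``, is three conv blocks, global
average pooling, and a linear classifier (~25k parameters): small
enough to train from scratch on a desk CPU, and its GAP + linear head
makes class-activation mapping exact.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


class Conv2d:
    """3x3 (or kxk) convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He initialization
        self.w = rng.normal(0.0, scale, (out_ch, in_ch, k, k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def _im2col(self, x: Array) -> Array:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: Array):
        n, _, h, w = x.shape
        cols = self._im2col(x)
        wr = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("of,nfp->nop", wr, cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w), (x.shape, cols)

    def backward(self, dout: Array, cache):
        x_shape, cols = cache
        n, c, h, w = x_shape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(n, dout.shape[1], -1)
        self.gw += np.einsum("nop,nfp->of", dflat, cols).reshape(self.w.shape)
        self.gb += dflat.sum(axis=(0, 2))
        wr = self.w.reshape(self.w.shape[0], -1)
        dcols = np.einsum("of,nop->nfp", wr, dflat).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU:
    def forward(self, x: Array):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout: Array, mask):
        return dout * mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: Array):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        return out, (mask, x.shape)

    def backward(self, dout: Array, cache):
        mask, x_shape = cache
        n, c, h, w = x_shape
        # normalize over ties so the gradient sum is preserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx = mask * (dout[:, :, :, None, :, None] / counts)
        return dx.reshape(n, c, h, w).astype(dout.dtype)

    def params(self):
        return []


class GlobalAvgPool:
    def forward(self, x: Array):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dout: Array, x_shape):
        n, c, h, w = x_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), x_shape).astype(dout.dtype)

    def params(self):
        return []


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_dim)
        self.w = rng.normal(0.0, scale, (out_dim, in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: Array):
        return x @ self.w.T + self.b, x

    def backward(self, dout: Array, x):
        self.gw += dout.T @ x
        self.gb += dout.sum(axis=0)
        return dout @ self.w

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Network:
    """A plain layer stack with functional forward/backward."""

    def __init__(self, layers: list, cam_layer: int | None = None):
        self.layers = layers
        #: index of the activation used for class-activation mapping
        #: (the ReLU output of the last conv block by convention)
        self.cam_layer = cam_layer

    def forward(self, x: Array, keep_caches: bool = True):
        caches = []
        out = x
        for layer in self.layers:
            out, cache = layer.forward(out)
            caches.append(cache if keep_caches else None)
        return out, caches

    def backward(self, dlogits: Array, caches, to_layer: int = -1):
        """Propagate gradients; accumulates parameter grads along the way.

        ``to_layer`` stops early and returns the gradient with respect
        to that layer's *output* (used by Grad-CAM); -1 propagates all
        the way back to the input.
        """
        d = dlogits
        for idx in range(len(self.layers) - 1, -1, -1):
            if idx == to_layer:
                return d
            d = self.layers[idx].backward(d, caches[idx])
        return d

    def predict_logits(self, x: Array) -> Array:
        out, _ = self.forward(x, keep_caches=False)
        return out

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def get_weights(self) -> list[Array]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[Array]) -> None:
        for (w, _), saved in zip(self.params(), weights):
            w[...] = saved


def tiny_cnn(n_classes: int = 3, seed: int = 0, width: int = 16) -> Network:
    """Three conv blocks + GAP + linear, ~25k parameters at width 16."""
    rng = np.random.default_rng(seed)
    layers = [
        Conv2d(3, width, rng=rng),
        ReLU(),
        MaxPool2(),
        Conv2d(width, 2 * width, rng=rng),
        ReLU(),
        MaxPool2(),
        Conv2d(2 * width, 4 * width, rng=rng),
        ReLU(),
        GlobalAvgPool(),
        Linear(4 * width, n_classes, rng=rng),
    ]
    return Network(layers, cam_layer=7)  # ReLU after the last conv block


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Array, targets: Array) -> tuple[float, Array]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-5, weight_decay: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]

    def step(self) -> None:
        self.t += 1
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * w)
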