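"""Minimal deterministic conv-net engine (numpy).

The architecture family used here fixes stride = kernel size with no padding,
so every convolution partitions its input into non-overlapping k×k patches:
forward and backward passes reduce to reshapes plus matrix products, which is
exact, fast on a single CPU, and reproducible bit-for-bit for a fixed seed.

Layers: strided conv + ReLU (×3), an optional skip branch that projects the
first conv layer's channels (1×1 weights) and nearest-neighbour-resamples its
maps onto the third layer's grid before elementwise addition, and a fully
connected softmax classifier.  Optimized with SGD + momentum on cross-entropy.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ArchitectureError


def conv_output_size(n: int, k: int) -> int:
    """Spatial output size of a k-kernel, k-stride, no-padding convolution."""
    if n < k:
        raise ArchitectureError(f"input extent {n} smaller than kernel {k}")
    return (n - k) // k + 1


def _extract_patches(x: np.ndarray, k: int):
    """(B, C, H, W) -> (B, h*w, C*k*k) non-overlapping patches, plus (h, w)."""
    b, c, hh, ww = x.shape
    h, w = conv_output_size(hh, k), conv_output_size(ww, k)
    xc = x[:, :, : h * k, : w * k]
    p = (
        xc.reshape(b, c, h, k, w, k)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(b, h * w, c * k * k)
    )
    return p, h, w


def _scatter_patches(dp: np.ndarray, shape, k: int, h: int, w: int) -> np.ndarray:
    b, c, hh, ww = shape
    dx = np.zeros(shape)
    dx[:, :, : h * k, : w * k] = (
        dp.reshape(b, h, w, c, k, k)
        .transpose(0, 3, 1, 4, 2, 5)
        .reshape(b, c, h * k, w * k)
    )
    return dx


class ConvLayer:
    """k-stride k-kernel convolution with ReLU."""

    def __init__(self, in_channels: int, n_filters: int, kernel: int, rng: np.random.Generator):
        fan_in = in_channels * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters))
        self.b = np.zeros(n_filters)
        self.kernel = kernel
        self.in_channels = in_channels
        self.n_filters = n_filters

    def forward(self, x: np.ndarray, cache: dict | None = None):
        p, h, w = _extract_patches(x, self.kernel)
        z = p @ self.W + self.b  # (B, h*w, F)
        z4 = z.transpose(0, 2, 1).reshape(x.shape[0], self.n_filters, h, w)
        a = np.maximum(z4, 0.0)
        if cache is not None:
            cache.update(p=p, z4=z4, h=h, w=w, x_shape=x.shape)
        return a, z4

    def backward(self, da: np.ndarray, cache: dict):
        p, z4, h, w = cache["p"], cache["z4"], cache["h"], cache["w"]
        dz4 = da * (z4 > 0)
        dz = dz4.reshape(dz4.shape[0], self.n_filters, h * w).transpose(0, 2, 1)
        dW = np.einsum("bpi,bpf->if", p, dz)
        db = dz.sum(axis=(0, 1))
        dp = dz @ self.W.T
        dx = _scatter_patches(dp, cache["x_shape"], self.kernel, h, w)
        return dx, dW, db

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class DenseLayer:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)

    def forward(self, x: np.ndarray, cache: dict | None = None):
        if cache is not None:
            cache["x"] = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray, cache: dict):
        x = cache["x"]
        return dout @ self.W.T, x.T @ dout, dout.sum(axis=0)


def _resample_indices(src: int, dst: int) -> np.ndarray:
    """Nearest-neighbour index map from a dst-length grid into a src-length one."""
    idx = np.floor((np.arange(dst) + 0.5) * src / dst).astype(int)
    return np.clip(idx, 0, src - 1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """Three strided conv+ReLU stages, optional skip-addition, dense softmax head.

    ``dag=True`` adds the skip branch: the first stage's ReLU output passes
    through a learnable 1×1 channel projection to the third stage's channel
    count, is nearest-neighbour resampled to the third stage's spatial grid,
    and is added to the third stage's ReLU output before the classifier.
    """

    def __init__(self, conv_specs, input_shape, rng, n_classes: int = 2, dag: bool = False):
        h, w = input_shape
        self.input_shape = tuple(input_shape)
        self.dag = dag
        self.conv_layers = []
        self.stage_shapes = []  # (F, h, w) after each stage
        in_c = 1
        for li, (n_filters, kernel) in enumerate(conv_specs, start=1):
            if h < kernel or w < kernel:
                raise ArchitectureError(
                    f"layer {li}: kernel {kernel} does not fit {h}x{w} feature maps"
                )
            self.conv_layers.append(ConvLayer(in_c, n_filters, kernel, rng))
            h, w = conv_output_size(h, kernel), conv_output_size(w, kernel)
            self.stage_shapes.append((n_filters, h, w))
            in_c = n_filters
        f1, h1, w1 = self.stage_shapes[0]
        f3, h3, w3 = self.stage_shapes[-1]
        if dag:
            self.Wp = rng.normal(0.0, np.sqrt(2.0 / f1), size=(f1, f3))
            self._ri = _resample_indices(h1, h3)
            self._ci = _resample_indices(w1, w3)
        else:
            self.Wp = None
        self.dense = DenseLayer(f3 * h3 * w3, n_classes, rng)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, caches: list | None = None):
        """x: (B, H, W) -> logits (B, n_classes)."""
        a = x[:, None, :, :]
        a1 = None
        for i, layer in enumerate(self.conv_layers):
            cache = {} if caches is not None else None
            a, _ = layer.forward(a, cache)
            if caches is not None:
                caches.append(cache)
            if i == 0:
                a1 = a
        if self.dag:
            branch = np.einsum("bchw,cf->bfhw", a1, self.Wp)
            branch = branch[:, :, self._ri[:, None], self._ci[None, :]]
            a = a + branch
            if caches is not None:
                caches.append({"a1": a1, "branch_shape": a1.shape})
        b = a.shape[0]
        flat = a.reshape(b, -1)
        cache = {} if caches is not None else None
        logits = self.dense.forward(flat, cache)
        if caches is not None:
            caches.append(cache)
        return logits

    def conv_outputs(self, x: np.ndarray):
        """Per-stage pre-ReLU conv outputs (the activation maps), plus the
        post-addition maps for skip models."""
        a = x[:, None, :, :]
        zs = []
        a1 = None
        for i, layer in enumerate(self.conv_layers):
            a, z = layer.forward(a)
            zs.append(z)
            if i == 0:
                a1 = a
        addition = None
        if self.dag:
            branch = np.einsum("bchw,cf->bfhw", a1, self.Wp)
            branch = branch[:, :, self._ri[:, None], self._ci[None, :]]
            addition = a + branch
        return zs, addition

    # -- parameters / gradients -------------------------------------------

    def get_params(self):
        params = []
        for layer in self.conv_layers:
            params += [layer.W, layer.b]
        if self.dag:
            params.append(self.Wp)
        params += [self.dense.W, self.dense.b]
        return params

    def set_params(self, params):
        i = 0
        for layer in self.conv_layers:
            layer.W, layer.b = params[i], params[i + 1]
            i += 2
        if self.dag:
            self.Wp = params[i]
            i += 1
        self.dense.W, self.dense.b = params[i], params[i + 1]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.get_params()))

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients in get_params() order.

        The skip branch adds a second gradient path into the first stage's
        output (scatter-added back through the nearest-neighbour resample),
        combined with the conv-chain path before layer 1's backward step.
        """
        caches: list = []
        logits = self.forward(x, caches)
        probs = softmax(logits)
        b = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(b), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b

        dense_cache = caches.pop()
        dflat, dWd, dbd = self.dense.backward(dlogits, dense_cache)
        f3, h3, w3 = self.stage_shapes[-1]
        da = dflat.reshape(b, f3, h3, w3)

        dWp = None
        da1_branch = None
        if self.dag:
            add_cache = caches.pop()
            a1 = add_cache["a1"]
            dbranch = np.zeros((b, f3) + a1.shape[2:])
            np.add.at(
                dbranch,
                (slice(None), slice(None), self._ri[:, None], self._ci[None, :]),
                da,
            )
            dWp = np.einsum("bchw,bfhw->cf", a1, dbranch)
            da1_branch = np.einsum("bfhw,cf->bchw", dbranch, self.Wp)

        conv_grads = [None] * len(self.conv_layers)
        for i in range(len(self.conv_layers) - 1, -1, -1):
            cache = caches.pop()
            if i == 0 and da1_branch is not None:
                da = da + da1_branch
            da, dW, db = self.conv_layers[i].backward(da, cache)
            conv_grads[i] = (dW, db)

        grads = []
        for dW, db in conv_grads:
            grads += [dW, db]
        if self.dag:
            grads.append(dWp)
        grads += [dWd, dbd]
        return loss, grads


class SGDMomentum:
    def __init__(self, params, learning_rate: float, momentum: float = 0.9):
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        for p, g, v in zip(params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v
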