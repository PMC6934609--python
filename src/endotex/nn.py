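"""A small, deterministic CPU neural-network framework on numpy.

Implements exactly the pieces the frame classifiers need: 3x3 'same'
convolution (im2col + BLAS matmul), 2x2 max pooling, ReLU, dropout, dense
layers, softmax cross-entropy, and the Adam optimizer, with per-layer
freezing for transfer learning.  All randomness flows through a single
``numpy.random.Generator``, so training runs are bit-reproducible given a
seed.  float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward/backward plus named trainable parameters."""

    frozen = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero padding 1 ('same')."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        fan_in = in_channels * 9
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.W = (rng.standard_normal((fan_in, out_channels)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.in_channels = in_channels
        self.out_channels = out_channels

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * h * w, c * 9)
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)
                                    ).reshape(-1, self.out_channels)
        if not self.frozen:
            self.dW = self._cols.T @ gmat
            self.db = gmat.sum(axis=0)
        dcols = (gmat @ self.W.T).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += (
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2))
        self._cols = None
        return dxp[:, :, 1:1 + h, 1:1 + w]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._shape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(d4, self._arg[..., None], grad[..., None], axis=-1)
        return (d4.reshape(n, c, h // 2, w // 2, 2, 2)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h, w))


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training without an rng")
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * self._mask / (1.0 - self.p)

    def backward(self, grad):
        return grad * self._mask / (1.0 - self.p)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = (rng.standard_normal((in_features, out_features)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        if not self.frozen:
            self.dW = self._x.T @ grad
            self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Sequential:
    """A layer stack ending in class logits (softmax applied separately)."""

    def __init__(self, layers: list[Layer], feature_index: int | None = None):
        self.layers = layers
        #: index such that layers[:feature_index] maps inputs to the
        #: penultimate ("last feature") representation.
        self.feature_index = feature_index

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return softmax(self.predict_logits(x, batch_size))

    def features(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Penultimate-layer activations in eval mode (dropout off)."""
        if self.feature_index is None:
            raise ValueError("network has no designated feature layer")
        outs = []
        for i in range(0, len(x), batch_size):
            h = x[i:i + batch_size]
            for layer in self.layers[: self.feature_index]:
                h = layer.forward(h, train=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    # -- state handling for best-weights checkpointing / serialization --
    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params().items()}
                for layer in self.layers]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, state):
            for k, v in params.items():
                layer.params()[k][...] = v

    def conv_layers(self) -> list[Conv2D]:
        return [l for l in self.layers if isinstance(l, Conv2D)]

    def n_trainable_params(self) -> int:
        return sum(sum(p.size for p in l.params().values())
                   for l in self.layers if not l.frozen)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    grad = probs
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    """Adam over all non-frozen parameters of a Sequential."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, layer in enumerate(self.net.layers):
            if layer.frozen:
                continue
            grads = layer.grads()
            for key, param in layer.params().items():
                g = grads[key]
                sk = (i, key)
                if sk not in self._m:
                    self._m[sk] = np.zeros_like(param)
                    self._v[sk] = np.zeros_like(param)
                m, v = self._m[sk], self._v[sk]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                param -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
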