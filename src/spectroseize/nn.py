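"""Minimal CNN engine on numpy: layers, backprop, Adam/Nadam.

Implements exactly what the classifier harness needs — 3x3 same-padding
convolutions (im2col via stride tricks), 2x2 max pooling (odd trailing
rows/columns cropped), dense layers, ReLU, softmax cross-entropy — with
full backpropagation including the gradient with respect to the *input*
image, which drives the saliency maps. Arrays are NHWC float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


def _windows3(xp: np.ndarray) -> np.ndarray:
    """All 3x3 windows of a padded NHWC array -> (N, H, W, 3, 3, C)."""
    w = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    return w.transpose(0, 1, 2, 4, 5, 3)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, with bias."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan_in = 9 * in_ch
        w = rng.standard_normal((3, 3, in_ch, out_ch)) * np.sqrt(2.0 / fan_in)
        self.W = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _windows3(xp).reshape(n * h * w, 9 * c)
        self._cols = cols
        out = cols @ self.W.reshape(9 * c, self.out_ch) + self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._x_shape
        dflat = dout.reshape(n * h * w, self.out_ch)
        self.grads[0][...] = (self._cols.T @ dflat).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        # dx = full correlation of dout with the spatially flipped, channel-swapped kernel
        w_rot = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,out_ch,in_ch)
        dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _windows3(dp).reshape(n * h * w, 9 * self.out_ch)
        dx = cols @ w_rot.reshape(9 * self.out_ch, self.in_ch)
        return dx.reshape(n, h, w, self.in_ch).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"feature map {h}x{w} too small to pool")
        self._in_shape = x.shape
        xc = x[:, :2 * h2, :2 * w2, :]
        blocks = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = blocks.argmax(axis=4)
        return blocks.max(axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, self._argmax[..., None], dout[..., None], axis=4)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :2 * h2, :2 * w2, :] = (
            dblocks.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * h2, 2 * w2, c))
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.W = w.astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    """A feed-forward stack with softmax cross-entropy loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean cross-entropy on integer labels ``y``; fills layer grads and
        returns the gradient w.r.t. the input batch."""
        logits = self.forward(x)
        p = softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dx = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return loss, dx

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size]))
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """Gradient of the target-class score (pre-softmax logit) w.r.t. the
        input; the basis of the saliency maps."""
        logits = self.forward(x)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dx = dlogits
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return dx

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class Nadam(Adam):
    """Adam with Nesterov momentum (Dozat 2016)."""

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            m_hat = (self.b1 * m / (1 - self.b1 ** (self.t + 1))
                     + (1 - self.b1) * g / (1 - self.b1 ** self.t))
            v_hat = v / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


OPTIMIZERS = {"adam": Adam, "nadam": Nadam}
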