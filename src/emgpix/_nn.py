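"""Minimal CNN engine on numpy.

Implements exactly the layer vocabulary the gesture CNNs need — 2-D
convolution, batch normalization, ReLU, non-overlapping max pooling, dense
layers, softmax — with reverse-mode gradients and an Adam optimizer.
Convolutions are lowered to a single BLAS GEMM per batch via im2col, which
is fast enough to train the small architectures on one CPU core.

Conventions: activations are ``float32`` arrays of shape ``(N, C, H, W)``;
pooling uses stride = window with floor division (trailing rows/columns that
do not fill a window are dropped and receive zero gradient).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DimensionError

F32 = np.float32


class Layer:
    """A differentiable stage with static shape inference."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """3x3-style convolution via im2col + GEMM, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_ch:
            raise DimensionError(f"conv expects {self.in_ch} input channels, got {c}")
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        if ho < 1 or wo < 1:
            raise DimensionError(
                f"conv output would be {ho}x{wo} for input {h}x{w} "
                f"(kernel {self.k}, pad {self.pad})"
            )
        return (self.out_ch, ho, wo)

    def _im2col(self, xp, n, c, ho, wo):
        """Lower patches to (n, c*k*k, ho*wo) via k*k contiguous slice copies."""
        k, s = self.k, self.stride
        cols = np.empty((n, c * k * k, ho * wo), dtype=F32)
        view = cols.reshape(n, c, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                view[:, :, i, j] = xp[:, :, i:i + ho * s:s, j:j + wo * s:s]
        return cols

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        _, ho, wo = self.out_shape((c, h, w))
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, n, c, ho, wo)
        out = np.matmul(self.W[None], cols)  # batched GEMM -> (n, F, ho*wo)
        out += self.b[None, :, None]
        if train:
            self._cache = (x.shape, cols)
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, grad):
        (xn, xc, xh, xw), cols = self._cache
        n, f, ho, wo = grad.shape
        p, s, k = self.pad, self.stride, self.k
        gmat = np.ascontiguousarray(grad).reshape(n, f, ho * wo)
        self.dW = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = np.einsum("nfp->f", gmat)
        dcols = np.matmul(self.W.T[None], gmat)  # (n, c*k*k, ho*wo)
        dview = dcols.reshape(n, xc, k, k, ho, wo)
        dxp = np.zeros((xn, xc, xh + 2 * p, xw + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dview[:, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + xh, p:p + xw] if p else dxp

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm2d(Layer):
    """Per-feature-map normalization with learned scale/shift."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=F32)
        self.beta = np.zeros(n_ch, dtype=F32)
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        if train:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            mean = np.einsum("nchw->c", x) / m
            xc = x - mean[None, :, None, None]
            var = np.einsum("nchw,nchw->c", xc, xc) / m
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
            xc = x - mean[None, :, None, None]
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = xc
        xhat *= inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        out = xhat * self.gamma[None, :, None, None]
        out += self.beta[None, :, None, None]
        return out

    def backward(self, grad):
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = np.einsum("nchw,nchw->c", grad, xhat)
        self.dbeta = np.einsum("nchw->c", grad)
        # dx = gamma*inv_std/m * (m*grad - dbeta - xhat*dgamma), in place on
        # grad (an owned intermediate) to avoid a full-size temporary
        grad *= np.float32(m)
        grad -= self.dbeta[None, :, None, None]
        xhat *= self.dgamma[None, :, None, None]
        grad -= xhat
        grad *= (self.gamma * inv_std / m)[None, :, None, None]
        self._cache = None
        return grad.astype(F32, copy=False)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0, out=x)  # x is always an owned intermediate

    def backward(self, grad):
        grad *= self._mask
        self._mask = None
        return grad


class MaxPool2d(Layer):
    """Non-overlapping max pooling; window = (rows, cols), stride = window."""

    def __init__(self, window: tuple[int, int]):
        self.ph, self.pw = window

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise DimensionError(
                f"pool {self.ph}x{self.pw} output would be {ho}x{wo} for input {h}x{w}"
            )
        return (c, ho, wo)

    def _windows(self, x, ho, wo):
        """Strided views of each in-window offset, in row-major offset order."""
        return [
            x[:, :, i:ho * self.ph:self.ph, j:wo * self.pw:self.pw]
            for i in range(self.ph)
            for j in range(self.pw)
        ]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        views = self._windows(x, ho, wo)
        out = views[0].copy()
        if train:
            idx = np.zeros(out.shape, dtype=np.uint8)
        for code, v in enumerate(views[1:], start=1):
            bigger = v > out  # strict: ties keep the earliest offset
            if train:
                idx[bigger] = code
            np.maximum(out, v, out=out)
        if train:
            self._cache = ((n, c, h, w), idx)
        return out

    def backward(self, grad):
        shape, idx = self._cache
        ho, wo = shape[2] // self.ph, shape[3] // self.pw
        dx = np.zeros(shape, dtype=F32)
        for code, dview in enumerate(self._windows(dx, ho, wo)):
            np.copyto(dview, grad.astype(F32, copy=False), where=(idx == code))
        self._cache = None
        return dx


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.n_in, self.n_out = n_in, n_out
        self.W = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)

    def out_shape(self, in_shape):
        if int(np.prod(in_shape)) != self.n_in:
            raise DimensionError(
                f"linear layer expects {self.n_in} inputs, got {int(np.prod(in_shape))}"
            )
        return (self.n_out,)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        self._x = None
        return grad @ self.W

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Softmax(Layer):
    """Output normalization; training uses the fused cross-entropy gradient."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, grad):  # pragma: no cover - bypassed by the fused loss
        raise NotImplementedError("train on logits with softmax_cross_entropy")


class Sequential:
    """An ordered layer stack with shape tracing and (de)serialization."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int]):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.shape_trace_ = self._trace()  # validates the chain at build time

    def _trace(self) -> list[tuple[str, tuple]]:
        shape = self.input_shape
        trace = [("input", shape)]
        for layer in self.layers:
            try:
                shape = layer.out_shape(shape)
            except DimensionError as err:
                lines = ", ".join(f"{n}->{s}" for n, s in trace)
                raise DimensionError(
                    f"{type(layer).__name__}: {err} [trace: {lines}]"
                ) from err
            trace.append((type(layer).__name__, shape))
        return trace

    def forward(self, x: np.ndarray, train: bool = False, logits: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        if x.shape[1:] != self.input_shape:
            raise DimensionError(
                f"expected input of shape (N, {self.input_shape}), got {x.shape}"
            )
        for layer in self.layers:
            if logits and isinstance(layer, Softmax):
                continue
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            if isinstance(layer, Softmax):
                continue
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params().values())

    def parameter_counts(self) -> list[tuple[str, int]]:
        """Per-layer trainable parameter counts, in layer order."""
        return [
            (type(layer).__name__, sum(int(p.size) for p in layer.params().values()))
            for layer in self.layers
        ]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                state[f"{i}.{name}"] = p
            if isinstance(layer, BatchNorm2d):
                for name, p in layer.state().items():
                    state[f"{i}.{name}"] = p
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            setattr(self.layers[int(idx)], name, np.asarray(value, dtype=F32))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.shape[0]
    loss = -log_probs[np.arange(n), labels].mean()
    grad = np.exp(log_probs)
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(F32)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for i, layer in enumerate(self.net.layers):
            grads = layer.grads()
            for name, p in layer.params().items():
                g = grads[name].astype(F32)
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
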