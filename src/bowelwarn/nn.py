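"""Minimal 1-D neural-network layers with explicit backpropagation.

Implements exactly the layer vocabulary the bowel-sound GAN needs — dense,
strided 1-D convolution, nearest-neighbour upsampling, batch normalization,
ReLU/LeakyReLU/Tanh — plus the Adam optimizer.  Arrays are channels-last:
convolutional activations have shape ``(batch, length, channels)``, dense
activations ``(batch, features)``.  Channels-last keeps the im2col gather
and scatter cache-friendly on a single core, which is what makes CPU
training of the GAN practical.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward`` while accumulating parameter
gradients in ``.grads``.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _he_std(fan_in: int) -> float:
    """He/Kaiming weight scale: keeps activation variance stable through
    ReLU-family layers, which matters here because the classifier trunk is
    trained from scratch in few epochs."""
    return float(np.sqrt(2.0 / fan_in))


class Layer:
    """Base class: parameter-free, shape-preserving identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Dense(Layer):
    """Fully connected layer: ``(B, n_in) -> (B, n_out)``."""

    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator,
                 dtype=DTYPE) -> None:
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, _he_std(n_in), (n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Reshape(Layer):
    """Fixed per-sample reshape, e.g. flat FC output -> (channels, length)."""

    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Flatten(Reshape):
    def __init__(self) -> None:
        Layer.__init__(self)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)


class Conv1d(Layer):
    """Strided cross-correlation, ``(B, L, C_in) -> (B, L_out, C_out)``.

    ``L_out = floor((L + 2*padding - kernel) / stride) + 1``; implemented as
    an im2col gather followed by a single GEMM.  Weights are stored
    ``(C_out, C_in, kernel)``; in channels-last layout the im2col block for
    one output position is ``k`` contiguous rows of length ``C_in``, so the
    gather order is (kernel tap, channel) and the weight matrix is flattened
    to match.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, *, rng: np.random.Generator,
                 dtype=DTYPE) -> None:
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.params = {
            "W": rng.normal(0.0, _he_std(in_ch * kernel),
                            (out_ch, in_ch, kernel)).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _w2d(self) -> np.ndarray:
        # (F, C, k) -> (k*C, F) matching the (tap, channel) im2col order
        return np.ascontiguousarray(
            self.params["W"].transpose(2, 1, 0)).reshape(
                self.kernel * self.params["W"].shape[1], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp_shape = x.shape
        b, lp, c = x.shape
        if lp < k:
            raise ValueError("kernel larger than padded input")
        # windows[b, o, c, j] = x[b, o + j, c]; subsample positions by s
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        sub = windows[:, ::s]  # (B, O, C, k)
        n_out = sub.shape[1]
        # gather in (tap, channel) order: contiguous k*C rows per position
        cols = np.ascontiguousarray(sub.transpose(0, 1, 3, 2))
        self._cols2d = cols.reshape(b * n_out, k * c)
        self._n_out = n_out
        out = self._cols2d @ self._w2d()
        return out.reshape(b, n_out, -1) + self.params["b"]

    def backward(self, dout: np.ndarray, *, need_input_grad: bool = True):
        k, s, p = self.kernel, self.stride, self.padding
        b, n_out, f = dout.shape
        dout2d = dout.reshape(b * n_out, f)
        c = self._xp_shape[2]
        dw2d = self._cols2d.T @ dout2d  # (k*C, F)
        self.grads["W"] += dw2d.reshape(k, c, f).transpose(2, 1, 0)
        self.grads["b"] += dout2d.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = (dout2d @ self._w2d().T).reshape(b, n_out, k, c)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for j in range(k):  # k is small (3 or 8); scatter-add per tap
            dxp[:, j:j + s * n_out:s, :] += dcols[:, :, j, :]
        return dxp[:, p:dxp.shape[1] - p, :] if p else dxp


class UpsampleNearest1d(Layer):
    """Nearest-neighbour length upsampling by an integer factor."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, lr, c = dout.shape
        return dout.reshape(b, lr // self.factor, self.factor, c).sum(axis=2)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    ``momentum`` is the weight given to the *current* batch statistic when
    updating the running estimates: ``running = (1-m)*running + m*batch``.
    """

    def __init__(self, channels: int, momentum: float = 0.8, eps: float = 1e-5,
                 *, dtype=DTYPE) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            n = x.shape[0] * x.shape[1]
            mean = np.einsum("blc->c", x) / n
            # E[x^2] - mean^2 in one fused reduction
            var = np.einsum("blc,blc->c", x, x) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = np.subtract(x, mean)
        xhat *= self._inv_std
        self._xhat = xhat
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = dout.shape[0] * dout.shape[1]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dout.sum(axis=(0, 1))
        dxhat = dout * self.params["gamma"]
        if not self.training:
            return dxhat * inv_std
        sum_dxhat = dxhat.sum(axis=(0, 1), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1), keepdims=True)
        return (inv_std / n) * (
            n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        np.multiply(dout, self._mask, out=dout)
        return dout


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        # per-element slope (1 or alpha), reused by the backward pass
        self._slope = np.where(x > 0, x.dtype.type(1.0),
                               x.dtype.type(self.alpha))
        return x * self._slope

    def backward(self, dout: np.ndarray) -> np.ndarray:
        np.multiply(dout, self._slope, out=dout)
        return dout


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y ** 2)


class Sequential:
    """Ordered layer container with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray, *, need_input_grad: bool = True):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            if isinstance(layer, Conv1d):
                dout = layer.backward(
                    dout, need_input_grad=need_input_grad or not last)
            else:
                dout = layer.backward(dout)
        return dout

    def train(self) -> None:
        for layer in self.layers:
            layer.training = True

    def eval(self) -> None:
        for layer in self.layers:
            layer.training = False

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (param, grad) array pairs, in layer order."""
        for layer in self.layers:
            for name in layer.params:
                yield layer.params[name], layer.grads[name]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"{i}.{name}"] = value
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam with the (0.5, 0.999) betas conventional for adversarial training."""

    def __init__(self, model: Sequential, lr: float = 0.002,
                 beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in model.parameters()]
        self._v = [np.zeros_like(p) for p, _ in model.parameters()]
        self._tmp = [np.empty_like(p) for p, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        scale = self.lr / bias1
        for (p, g), m, v, tmp in zip(self.model.parameters(), self._m,
                                     self._v, self._tmp):
            m += (1 - b1) * (g - m)
            np.multiply(g, g, out=tmp)
            v += (1 - b2) * (tmp - v)
            np.divide(v, bias2, out=tmp)
            np.sqrt(tmp, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= scale
            p -= tmp


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax; stable under large logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
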