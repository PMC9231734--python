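"""Layer primitives: convolution (strided / dilated / grouped), instance
normalisation, pooling, upsampling, and dense layers.

Convolutions use an im2col lowering; ``backward(grad_out)`` consumes the
cache left by the most recent ``forward`` and returns the gradient with
respect to the input while accumulating parameter gradients in-place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "Linear",
    "UpsampleNearest",
    "Residual",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: a layer or a container of layers."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def children(self):
        return iter(())

    def parameters(self) -> list[Parameter]:
        out = []
        for child in self.children():
            out.extend(child.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.size for p in self.parameters() if p.trainable or not trainable_only
        )

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {}
        for i, child in enumerate(self.children()):
            state.update(child.state_dict(prefix=f"{prefix}{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, child in enumerate(self.children()):
            child.load_state_dict(state, prefix=f"{prefix}{i}.")


class _Leaf(Module):
    """Module with its own parameters and no children."""

    def parameters(self) -> list[Parameter]:
        return list(getattr(self, "_params", ()))

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {f"{prefix}{p.name}": p.data for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for p in self.parameters():
            key = f"{prefix}{p.name}"
            src = np.asarray(state[key], dtype=float)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.data[...] = src


class Sequential(Module):
    def __init__(self, *modules: Module):
        self._modules = list(modules)

    def children(self):
        return iter(self._modules)

    def __getitem__(self, idx):
        return self._modules[idx]

    def __len__(self) -> int:
        return len(self._modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self._modules:
            x = m.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for m in reversed(self._modules):
            grad_out = m.backward(grad_out)
        return grad_out


# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, dilation: int):
    n, c, h, w = x.shape
    span = dilation * (k - 1) + 1
    h_out = (h + 2 * pad - span) // stride + 1
    w_out = (w + 2 * pad - span) // stride + 1
    if h_out < 1 or w_out < 1:
        raise ValueError("input too small for kernel/stride/dilation")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, h_out, w_out), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[
                :,
                :,
                i * dilation : i * dilation + stride * h_out : stride,
                j * dilation : j * dilation + stride * w_out : stride,
            ]
    return cols, (h_out, w_out)


def _col2im(g_cols: np.ndarray, x_shape, k: int, stride: int, pad: int, dilation: int):
    n, c, h, w = x_shape
    h_out, w_out = g_cols.shape[-2:]
    gxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=g_cols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[
                :,
                :,
                i * dilation : i * dilation + stride * h_out : stride,
                j * dilation : j * dilation + stride * w_out : stride,
            ] += g_cols[:, :, i, j]
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp


class Conv2d(_Leaf):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size**2
        weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels // groups, kernel_size, kernel_size))
        self._params = [Parameter(weight, "weight")]
        self.bias = Parameter(np.zeros(out_channels), "bias") if bias else None
        if self.bias is not None:
            self._params.append(self.bias)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.groups
        cols, (h_out, w_out) = _im2col(x, self.k, self.stride, self.padding, self.dilation)
        n = x.shape[0]
        cig = self.in_channels // g
        cols_g = cols.reshape(n, g, cig * self.k * self.k, h_out * w_out)
        w_g = self._params[0].data.reshape(g, self.out_channels // g, cig * self.k * self.k)
        out = np.einsum("gok,ngkl->ngol", w_g, cols_g, optimize=True)
        out = out.reshape(n, self.out_channels, h_out, w_out)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x.shape, cols_g)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_shape, cols_g = self._cache
        n = grad_out.shape[0]
        g = self.groups
        cig = self.in_channels // g
        h_out, w_out = grad_out.shape[-2:]
        go = grad_out.reshape(n, g, self.out_channels // g, h_out * w_out)
        w_param = self._params[0]
        g_w = np.einsum("ngol,ngkl->gok", go, cols_g, optimize=True)
        w_param.grad += g_w.reshape(w_param.data.shape)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        w_g = w_param.data.reshape(g, self.out_channels // g, cig * self.k * self.k)
        g_cols = np.einsum("gok,ngol->ngkl", w_g, go, optimize=True)
        g_cols = g_cols.reshape(n, self.in_channels, self.k, self.k, h_out, w_out)
        return _col2im(g_cols, x_shape, self.k, self.stride, self.padding, self.dilation)


class InstanceNorm2d(_Leaf):
    """Per-sample, per-channel normalisation over the spatial dimensions.

    Unlike batch normalisation this makes each sample's activations
    independent of the rest of the batch, so small batches and gradient
    accumulation behave identically to large batches.
    """

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self._params = []
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(channels), "gamma")
            self.beta = Parameter(np.zeros(channels), "beta")
            self._params = [self.gamma, self.beta]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu) * inv_std
        self._cache = (x_hat, inv_std)
        if self.affine:
            return self.gamma.data[None, :, None, None] * x_hat + self.beta.data[None, :, None, None]
        return x_hat

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_hat, inv_std = self._cache
        if self.affine:
            self.gamma.grad += (grad_out * x_hat).sum(axis=(0, 2, 3))
            self.beta.grad += grad_out.sum(axis=(0, 2, 3))
            g_hat = grad_out * self.gamma.data[None, :, None, None]
        else:
            g_hat = grad_out
        m1 = g_hat.mean(axis=(2, 3), keepdims=True)
        m2 = (g_hat * x_hat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (g_hat - m1 - x_hat * m2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0.0)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int | None = None, padding: int = 0):
        self.k = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2), constant_values=-np.inf)
        cols, (h_out, w_out) = _im2col(x, self.k, self.stride, 0, 1)
        n, c = x.shape[:2]
        cols = cols.reshape(n, c, self.k * self.k, h_out, w_out)
        self._argmax = cols.argmax(axis=2)
        self._x_shape = x.shape
        return cols.max(axis=2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h_out, w_out = grad_out.shape
        g_cols = np.zeros((n, c, self.k * self.k, h_out, w_out), dtype=grad_out.dtype)
        idx = self._argmax
        nn_, cc, yy, xx = np.ogrid[:n, :c, :h_out, :w_out]
        g_cols[nn_, cc, idx, yy, xx] = grad_out
        g_cols = g_cols.reshape(n, c, self.k, self.k, h_out, w_out)
        gx = _col2im(g_cols, self._x_shape, self.k, self.stride, 0, 1)
        if self.padding:
            gx = gx[:, :, self.padding : -self.padding, self.padding : -self.padding]
        return gx


class GlobalAvgPool2d(Module):
    """Spatial mean, yielding (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Linear(_Leaf):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        weight = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self._params = [Parameter(weight, "weight")]
        self.bias = Parameter(np.zeros(out_features), "bias") if bias else None
        if self.bias is not None:
            self._params.append(self.bias)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self._params[0].data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self._params[0].grad += grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self._params[0].data


class UpsampleNearest(Module):
    def __init__(self, scale: int = 2):
        self.scale = scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.scale
        return x.repeat(s, axis=2).repeat(s, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        s = self.scale
        n, c, h, w = grad_out.shape
        return grad_out.reshape(n, c, h // s, s, w // s, s).sum(axis=(3, 5))


class Residual(Module):
    """Post-activation residual block: ``relu(body(x) + shortcut(x))``."""

    def __init__(self, body: Module, shortcut: Module | None = None):
        self.body = body
        self.shortcut = shortcut

    def children(self):
        yield self.body
        if self.shortcut is not None:
            yield self.shortcut

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.body.forward(x)
        skip = self.shortcut.forward(x) if self.shortcut is not None else x
        out = y + skip
        self._mask = out > 0
        return np.where(self._mask, out, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, grad_out, 0.0)
        gx = self.body.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx
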