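"""Minimal numpy neural-network layers with hand-written backprop.

Only what the temporal-shift classifier needs: 2-D convolution (im2col),
batch normalization, ReLU, max/global-average pooling and a linear head.
Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; gradients accumulate into
``Parameter.grad`` and are consumed by the SGD loop in ``training``.

Layers are dtype-polymorphic: float64 inputs give float64 arithmetic,
which the finite-difference gradient checks in the test suite rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "global_avg_pool",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    def __init__(self, value: np.ndarray, regularized: bool = True):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        # conv/linear weights enter the L2 penalty; BN affine and biases do not
        self.regularized = regularized

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: named parameters, forward/backward contract."""

    def parameters(self) -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                out.append((name, attr))
            elif isinstance(attr, Module):
                out.extend((f"{name}.{sub}", p) for sub, p in attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for k, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{k}.{sub}", p) for sub, p in item.parameters()
                        )
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, out_h, out_w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[
                :, :, i : i + out_h * stride : stride, j : j + out_w * stride : stride
            ]
    return cols.reshape(n, c * k * k, out_h * out_w), out_h, out_w


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    out_h: int,
    out_w: int,
) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, out_h, out_w)
    for i in range(k):
        for j in range(k):
            dxp[
                :, :, i : i + out_h * stride : stride, j : j + out_w * stride : stride
            ] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """k x k convolution via im2col + GEMM. He-initialized, no bias by default
    (a BatchNorm follows every convolution in the classifier)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        if pad is None:
            pad = kernel // 2
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), regularized=False) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"Conv2d expects (N,{self.in_ch},H,W), got {x.shape}"
            )
        cols, out_h, out_w = _im2col(x, self.kernel, self.stride, self.pad)
        out = np.matmul(self.weight.value, cols)  # (N, out_ch, L)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cache = (cols, x.shape, out_h, out_w)
        return out.reshape(x.shape[0], self.out_ch, out_h, out_w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, out_h, out_w = self._cache
        n = x_shape[0]
        d2 = dout.reshape(n, self.out_ch, out_h * out_w)
        self.weight.grad += np.einsum("nol,nkl->ok", d2, cols)
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, d2)
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad, out_h, out_w)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Parameter(np.ones(ch, dtype=dtype), regularized=False)
        self.beta = Parameter(np.zeros(ch, dtype=dtype), regularized=False)
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.astype(np.float64)
            self.running_var = (1 - m) * self.running_var + m * var.astype(np.float64)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        if train:
            self._cache = (x_hat, inv_sd)
        return self.gamma.value[None, :, None, None] * x_hat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_sd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dg = (dout * x_hat).sum(axis=(0, 2, 3))
        db = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dg
        self.beta.grad += db
        g = self.gamma.value * inv_sd / m
        return g[None, :, None, None] * (
            m * dout - db[None, :, None, None] - x_hat * dg[None, :, None, None]
        )


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Module):
    """Non-overlapping 2x2 max pooling (the only variant the backbone uses)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {x.shape}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype), regularized=False)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C) spatial mean; backward is uniform spreading."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(dout: np.ndarray, spatial: tuple[int, int]) -> np.ndarray:
    h, w = spatial
    return np.broadcast_to(dout[:, :, None, None], dout.shape + (h, w)).copy() / (h * w)
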