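"""A compact 3D neural-network engine on numpy arrays.

Layers operate on float32 tensors shaped ``(B, C, D, H, W)`` and implement
explicit ``forward``/``backward`` passes; convolutions are evaluated as
im2col + GEMM, chunked along the output depth axis so large inference
volumes never materialize a full column matrix.  The engine exists because
this package has no deep-learning framework dependency: the model it serves
is small (under a million parameters) and the patch sizes modest, so BLAS
matrix products are entirely adequate.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Cap on the number of float32 elements in one im2col chunk (~128 MB).
_COL_CHUNK_ELEMS = 32_000_000


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Layer):
    """3D convolution, kernel k, stride s, symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if padding is None:
            padding = kernel // 2 if stride == 1 else 0
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        self.weight = Param(
            _he_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in),
            f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self._x: np.ndarray | None = None
        self._cols: list | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_len(self, n: int) -> int:
        return (n + 2 * self.p - self.k) // self.s + 1

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        sw = sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        return sw[:, :, :: self.s, :: self.s, :: self.s]

    def _chunks(self, b: int, do: int, ho: int, wo: int) -> list[tuple[int, int]]:
        per_slice = self.cin * self.k**3 * b * ho * wo
        step = max(1, _COL_CHUNK_ELEMS // max(per_slice, 1))
        return [(z0, min(z0 + step, do)) for z0 in range(0, do, step)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        if self.s == 1:
            return self._forward_slab(x, training)
        xp = np.pad(
            x, ((0, 0), (0, 0)) + ((self.p, self.p),) * 3
        ) if self.p else x
        do, ho, wo = self._out_len(d), self._out_len(h), self._out_len(w)
        sw = self._windows(xp)
        w_t = self.weight.value.reshape(self.cout, -1).T  # (C*k^3, cout)
        out = np.empty((b, self.cout, do, ho, wo), dtype=np.float32)
        for z0, z1 in self._chunks(b, do, ho, wo):
            # (B, C, zc, Ho, Wo, k, k, k) -> (B*zc*Ho*Wo, C*k^3)
            col = (
                sw[:, :, z0:z1]
                .transpose(0, 2, 3, 4, 1, 5, 6, 7)
                .reshape(-1, self.cin * self.k**3)
            )
            res = col @ w_t  # (N, cout)
            out[:, :, z0:z1] = np.moveaxis(
                res.reshape(b, z1 - z0, ho, wo, self.cout), -1, 1
            )
        out += self.bias.value[None, :, None, None, None]
        if training:
            self._x = x
        return out

    # -- stride-1 fast path: channel-major slab im2col -----------------------
    # The column matrix is assembled from k^3 contiguous slice copies of the
    # channel-first padded tensor, which runs at memcpy speed; the generic
    # 8-axis window reshape is an order of magnitude slower.

    def _slab_col(self, xt: np.ndarray, z0: int, zc: int, ho: int, wo: int
                  ) -> np.ndarray:
        c = xt.shape[0]
        b = xt.shape[1]
        k = self.k
        col = np.empty((c, k, k, k, b, zc, ho, wo), dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    col[:, dz, dy, dx] = xt[
                        :, :, z0 + dz : z0 + dz + zc, dy : dy + ho, dx : dx + wo
                    ]
        return col.reshape(c * k**3, -1)

    def _zchunks(self, do: int, per_slice: int) -> list[tuple[int, int]]:
        step = max(1, _COL_CHUNK_ELEMS // max(per_slice, 1))
        return [(z0, min(z0 + step, do)) for z0 in range(0, do, step)]

    def _forward_slab(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, _, d, h, w = x.shape
        pad = ((0, 0), (0, 0)) + ((self.p, self.p),) * 3
        xp = np.pad(x, pad) if self.p else x
        xt = np.ascontiguousarray(xp.transpose(1, 0, 2, 3, 4))
        do, ho, wo = self._out_len(d), self._out_len(h), self._out_len(w)
        w_mat = self.weight.value.reshape(self.cout, -1)
        out = np.empty((b, self.cout, do, ho, wo), dtype=np.float32)
        per_slice = self.cin * self.k**3 * b * ho * wo
        cols = [] if training else None
        for z0, z1 in self._zchunks(do, per_slice):
            col = self._slab_col(xt, z0, z1 - z0, ho, wo)
            res = (w_mat @ col).reshape(self.cout, b, z1 - z0, ho, wo)
            out[:, :, z0:z1] = res.transpose(1, 0, 2, 3, 4)
            if cols is not None:
                cols.append((z0, z1, col))
        out += self.bias.value[None, :, None, None, None]
        if training:
            self._x = xt  # padded, channel-first
            self._cols = cols  # reused for the weight-gradient GEMM
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before a training-mode forward")
        if self.s == 1:
            return self._backward_slab(dout)
        x = self._x
        self._x = None
        xp = np.pad(
            x, ((0, 0), (0, 0)) + ((self.p, self.p),) * 3
        ) if self.p else x
        b, _, do, ho, wo = dout.shape
        sw = self._windows(xp)
        kcube = self.k**3
        dw = np.zeros((self.cout, self.cin * kcube), dtype=np.float32)
        for z0, z1 in self._chunks(b, do, ho, wo):
            col = (
                sw[:, :, z0:z1]
                .transpose(0, 2, 3, 4, 1, 5, 6, 7)
                .reshape(-1, self.cin * kcube)
            )
            dmat = (
                dout[:, :, z0:z1]
                .transpose(0, 2, 3, 4, 1)
                .reshape(-1, self.cout)
            )
            dw += dmat.T @ col
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        return self._backward_input_scatter(dout, xp.shape)

    def _backward_slab(self, dout: np.ndarray) -> np.ndarray:
        xt = self._x  # padded, channel-first (C, B, Dp, Hp, Wp)
        self._x = None
        b, _, do, ho, wo = dout.shape
        kcube = self.k**3

        # weight gradient: dW = dout_mat @ col^T, chunked over output depth
        dt_out = np.ascontiguousarray(dout.transpose(1, 0, 2, 3, 4))
        dw = np.zeros((self.cout, self.cin * kcube), dtype=np.float32)
        cols = self._cols or []
        self._cols = None
        for z0, z1, col in cols:
            dmat = dt_out[:, :, z0:z1].reshape(self.cout, -1)
            dw += dmat @ col.T
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))

        # input gradient: correlation of dout with the flipped kernel
        q = self.k - 1 - self.p
        dp = np.pad(dt_out, ((0, 0), (0, 0)) + ((q, q),) * 3) if q else dt_out
        w_back = (
            self.weight.value[:, :, ::-1, ::-1, ::-1]
            .transpose(1, 0, 2, 3, 4)
            .reshape(self.cin, -1)
            .copy()  # (cin, cout*k^3)
        )
        d = do + 2 * q - self.k + 1
        h = ho + 2 * q - self.k + 1
        w = wo + 2 * q - self.k + 1
        dx = np.empty((b, self.cin, d, h, w), dtype=np.float32)
        per_slice = self.cout * kcube * b * h * w
        for z0, z1 in self._zchunks(d, per_slice):
            col = self._slab_col(dp, z0, z1 - z0, h, w)
            res = (w_back @ col).reshape(self.cin, b, z1 - z0, h, w)
            dx[:, :, z0:z1] = res.transpose(1, 0, 2, 3, 4)
        return dx

    def _backward_input_scatter(self, dout: np.ndarray, xp_shape) -> np.ndarray:
        """dL/dx for strided convolutions via per-offset scatter-add; only
        used at the coarse resolutions where this stays cheap."""
        b, _, do, ho, wo = dout.shape
        w_mat = self.weight.value.reshape(self.cout, -1)
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout)
        dcol = (dmat @ w_mat).reshape(
            b, do, ho, wo, self.cin, self.k, self.k, self.k
        )
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for dz in range(self.k):
            zsl = slice(dz, dz + do * self.s, self.s)
            for dy in range(self.k):
                ysl = slice(dy, dy + ho * self.s, self.s)
                for dx_ in range(self.k):
                    xsl = slice(dx_, dx_ + wo * self.s, self.s)
                    dxp[:, :, zsl, ysl, xsl] += np.moveaxis(
                        dcol[:, :, :, :, :, dz, dy, dx_], -1, 1
                    )
        if self.p:
            return dxp[:, :, self.p : -self.p, self.p : -self.p, self.p : -self.p]
        return dxp


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator | None = None,
        name: str = "deconv",
    ) -> None:
        self.cin, self.cout = in_channels, out_channels
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            _he_init(rng, (in_channels, out_channels, 2, 2, 2), in_channels),
            f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, d, h, w = x.shape
        out = np.empty((b, self.cout, 2 * d, 2 * h, 2 * w), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    res = np.tensordot(
                        x, self.weight.value[:, :, i, j, l], axes=([1], [0])
                    )  # (B, D, H, W, cout)
                    out[:, :, i::2, j::2, l::2] = np.moveaxis(res, -1, 1)
        out += self.bias.value[None, :, None, None, None]
        if training:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called before a training-mode forward")
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    d_off = dout[:, :, i::2, j::2, l::2]  # (B, cout, D, H, W)
                    dx += np.moveaxis(
                        np.tensordot(
                            d_off, self.weight.value[:, :, i, j, l], axes=([1], [1])
                        ),
                        -1,
                        1,
                    )
                    self.weight.grad[:, :, i, j, l] += np.tensordot(
                        x, d_off, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        self._x = None
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[
            None, :, None, None, None
        ]
        out = self.gamma.value[None, :, None, None, None] * xhat
        out += self.beta.value[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        n = dout.size // self.c
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None, None]
        term = (
            n * dout
            - dbeta[None, :, None, None, None]
            - xhat * dgamma[None, :, None, None, None]
        )
        dx = (g * inv_std[None, :, None, None, None] / n) * term
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # numerically stable in both tails
        out = np.empty_like(x, dtype=np.float32)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        if training:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = self._out
        self._out = None
        return (dout * out * (1.0 - out)).astype(np.float32)


def nearest_upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor 2x upsampling along the three spatial axes."""
    return np.repeat(np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), 2, axis=4)


def nearest_upsample2_backward(dout: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`nearest_upsample2`: sum over each 2x2x2 block."""
    b, c, d, h, w = dout.shape
    return (
        dout.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
    ).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimizer with bias-corrected first/second moments."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
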