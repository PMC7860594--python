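"""The multi-task 3D U-shaped FCN with spatial attention gates.

Architecture: an encoder of 3x3x3 conv blocks (each conv followed by batch
normalization and ReLU) whose resolution is halved by stride-2 convolutions
that double the feature count; a bottleneck block; a decoder of stride-2
transposed convolutions that halve the feature count, each merged with the
corresponding encoder features through an attention gate and channel
concatenation; and two 1x1x1 sigmoid heads sharing the final feature maps —
one predicting the soma mask, one the boundary mask.  The root feature count
is 24 and there are two down/up levels, keeping the model under a million
parameters: the somata being only ~10 voxels in radius, deeper pyramids
would erase them spatially.

The attention gate computes, at the gating (coarser) resolution,

    alpha = sigmoid(psi(relu(Wx * skip_down + Wg * gating)))

with 1x1x1 transforms that preserve the gating channel count and a final
single-channel psi, upsamples alpha by nearest interpolation and multiplies
it into the skip features, suppressing irrelevant regions before the merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somaseg.nn.layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Layer,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    nearest_upsample2,
    nearest_upsample2_backward,
)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters; defaults follow the reference design."""

    root_features: int = 24
    levels: int = 2
    convs_per_block: int = 2
    in_channels: int = 1
    use_attention: bool = True
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.root_features < 1:
            raise ValueError("root_features must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")

    def features_at(self, depth: int) -> int:
        return self.root_features * 2**depth

    def to_dict(self) -> dict:
        return {
            "root_features": self.root_features,
            "levels": self.levels,
            "convs_per_block": self.convs_per_block,
            "in_channels": self.in_channels,
            "use_attention": self.use_attention,
            "use_batchnorm": self.use_batchnorm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def _conv_block(
    cin: int, cout: int, n_convs: int, use_bn: bool, rng, name: str
) -> Sequential:
    layers: list[Layer] = []
    for i in range(n_convs):
        layers.append(Conv3d(cin if i == 0 else cout, cout, kernel=3, stride=1,
                             rng=rng, name=f"{name}.conv{i}"))
        if use_bn:
            layers.append(BatchNorm3d(cout, name=f"{name}.bn{i}"))
        layers.append(ReLU())
    return Sequential(*layers)


def _down(cin: int, cout: int, use_bn: bool, rng, name: str) -> Sequential:
    layers: list[Layer] = [
        Conv3d(cin, cout, kernel=2, stride=2, padding=0, rng=rng, name=name)
    ]
    if use_bn:
        layers.append(BatchNorm3d(cout, name=f"{name}.bn"))
    layers.append(ReLU())
    return Sequential(*layers)


def _up(cin: int, cout: int, use_bn: bool, rng, name: str) -> Sequential:
    layers: list[Layer] = [ConvTranspose3d(cin, cout, rng=rng, name=name)]
    if use_bn:
        layers.append(BatchNorm3d(cout, name=f"{name}.bn"))
    layers.append(ReLU())
    return Sequential(*layers)


class AttentionGate(Layer):
    """Additive spatial attention over skip features, gated by deeper features.

    ``skip`` has shape (B, C, 2d, 2h, 2w) and ``gating`` (B, 2C, d, h, w).
    The skip tensor is brought to gating resolution by a stride-2 1x1x1
    transform; the coefficient is computed there and upsampled by nearest
    interpolation.
    """

    def __init__(self, skip_channels: int, gate_channels: int, rng,
                 name: str = "att") -> None:
        self.wx = Conv3d(skip_channels, gate_channels, kernel=1, stride=2,
                         padding=0, rng=rng, name=f"{name}.wx")
        self.wg = Conv3d(gate_channels, gate_channels, kernel=1, stride=1,
                         padding=0, rng=rng, name=f"{name}.wg")
        self.psi = Conv3d(gate_channels, 1, kernel=1, stride=1, padding=0,
                          rng=rng, name=f"{name}.psi")
        self.relu = ReLU()
        self.sigmoid = Sigmoid()
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return self.wx.params() + self.wg.params() + self.psi.params()

    def forward_pair(self, skip: np.ndarray, gating: np.ndarray,
                     training: bool = False) -> np.ndarray:
        if skip.shape[2] != 2 * gating.shape[2]:
            raise ValueError(
                f"gating must be at half the skip resolution: "
                f"skip {skip.shape}, gating {gating.shape}"
            )
        merged = self.wx.forward(skip, training) + self.wg.forward(gating, training)
        a = self.relu.forward(merged, training)
        alpha_low = self.sigmoid.forward(self.psi.forward(a, training), training)
        alpha = nearest_upsample2(alpha_low)
        out = skip * alpha
        if training:
            self._cache = (skip, alpha)
        return out

    # Layer API (used by tests on synthetic tensors)
    def forward(self, x, training: bool = False):  # pragma: no cover
        raise TypeError("AttentionGate.forward_pair(skip, gating) is the entry point")

    def backward_pair(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        skip, alpha = self._cache
        dskip = dout * alpha
        dalpha = (dout * skip).sum(axis=1, keepdims=True)
        dalpha_low = nearest_upsample2_backward(dalpha)
        da = self.psi.backward(self.sigmoid.backward(dalpha_low))
        dmerged = self.relu.backward(da)
        dskip += self.wx.backward(dmerged)
        dgating = self.wg.backward(dmerged)
        self._cache = None
        return dskip, dgating


class MultiTaskUNet3D:
    """Two-headed attention U-shaped FCN mapping a patch to (soma, boundary)
    probability volumes of the same spatial shape."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        f, bn = config.features_at, config.use_batchnorm
        n = config.convs_per_block

        self.enc = [
            _conv_block(config.in_channels if d == 0 else f(d), f(d), n, bn, rng,
                        f"enc{d}")
            for d in range(config.levels)
        ]
        self.down = [
            _down(f(d), f(d + 1), bn, rng, f"down{d}") for d in range(config.levels)
        ]
        self.bottleneck = _conv_block(
            f(config.levels), f(config.levels), n, bn, rng, "bottleneck"
        )
        self.up = [
            _up(f(d + 1), f(d), bn, rng, f"up{d}") for d in range(config.levels)
        ]
        self.att = (
            [
                AttentionGate(f(d), f(d + 1), rng, f"att{d}")
                for d in range(config.levels)
            ]
            if config.use_attention
            else [None] * config.levels
        )
        self.dec = [
            _conv_block(2 * f(d), f(d), n, bn, rng, f"dec{d}")
            for d in range(config.levels)
        ]
        self.head_soma = Conv3d(f(0), 1, kernel=1, stride=1, padding=0, rng=rng,
                                name="head_soma")
        self.head_boundary = Conv3d(f(0), 1, kernel=1, stride=1, padding=0,
                                    rng=rng, name="head_boundary")
        self.sig_soma = Sigmoid()
        self.sig_boundary = Sigmoid()
        self._skip_channels: list[int] | None = None

    # -- parameter access ---------------------------------------------------
    def param_groups(self) -> dict[str, list[Param]]:
        groups: dict[str, list[Param]] = {}
        for d in range(self.config.levels):
            groups[f"enc{d}"] = self.enc[d].params()
            groups[f"down{d}"] = self.down[d].params()
            groups[f"up{d}"] = self.up[d].params()
            groups[f"dec{d}"] = self.dec[d].params()
            if self.att[d] is not None:
                groups[f"att{d}"] = self.att[d].params()
        groups["bottleneck"] = self.bottleneck.params()
        groups["head_soma"] = self.head_soma.params()
        groups["head_boundary"] = self.head_boundary.params()
        return groups

    def params(self) -> list[Param]:
        return [p for ps in self.param_groups().values() for p in ps]

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        div = 2**self.config.levels
        for axis_len in x.shape[2:]:
            if axis_len % div != 0:
                raise ValueError(
                    f"spatial dims must be divisible by {div}, got {x.shape[2:]}"
                )

    def forward(self, patch: np.ndarray, training: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """Run a batch of patches; returns (soma_prob, boundary_prob).

        ``patch`` may be (D, H, W), (B, D, H, W) or (B, C, D, H, W); the
        output matches the spatial shape of the input.
        """
        x = np.asarray(patch, dtype=np.float32)
        squeeze = x.ndim
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        self._check_shape(x)

        skips = []
        for d in range(self.config.levels):
            x = self.enc[d].forward(x, training)
            skips.append(x)
            x = self.down[d].forward(x, training)
        x = self.bottleneck.forward(x, training)
        for d in reversed(range(self.config.levels)):
            gating = x
            u = self.up[d].forward(x, training)
            if self.att[d] is not None:
                g = self.att[d].forward_pair(skips[d], gating, training)
            else:
                g = skips[d]
            x = self.dec[d].forward(
                np.concatenate([g, u], axis=1), training
            )
        soma = self.sig_soma.forward(self.head_soma.forward(x, training), training)
        bou = self.sig_boundary.forward(
            self.head_boundary.forward(x, training), training
        )
        if squeeze == 3:
            return soma[0, 0], bou[0, 0]
        if squeeze == 4:
            return soma[:, 0], bou[:, 0]
        return soma, bou

    def backward(self, dsoma: np.ndarray, dboundary: np.ndarray) -> None:
        """Backpropagate gradients w.r.t. the two probability outputs."""
        dsoma = np.asarray(dsoma, dtype=np.float32)
        dboundary = np.asarray(dboundary, dtype=np.float32)
        if dsoma.ndim == 3:
            dsoma, dboundary = dsoma[None, None], dboundary[None, None]
        elif dsoma.ndim == 4:
            dsoma, dboundary = dsoma[:, None], dboundary[:, None]
        dx = self.head_soma.backward(self.sig_soma.backward(dsoma))
        dx += self.head_boundary.backward(self.sig_boundary.backward(dboundary))

        f = self.config.features_at
        dskips: list[np.ndarray | None] = [None] * self.config.levels
        for d in range(self.config.levels):
            dcat = self.dec[d].backward(dx)
            dg, du = dcat[:, : f(d)], dcat[:, f(d) :]
            dx = self.up[d].backward(np.ascontiguousarray(du))
            if self.att[d] is not None:
                dskip, dgating = self.att[d].backward_pair(
                    np.ascontiguousarray(dg)
                )
                dx += dgating
            else:
                dskip = np.ascontiguousarray(dg)
            dskips[d] = dskip
        dx = self.bottleneck.backward(dx)
        for d in reversed(range(self.config.levels)):
            dx = self.down[d].backward(dx)
            dx += dskips[d]
            dx = self.enc[d].backward(dx)

    # -- weight (de)serialization -------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for group, params in self.param_groups().items():
            for i, p in enumerate(params):
                state[f"{group}.{i}.{p.name}"] = p.value
        for key, bn in self._batchnorms():
            state[f"{key}.running_mean"] = bn.running_mean
            state[f"{key}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for group, params in self.param_groups().items():
            for i, p in enumerate(params):
                key = f"{group}.{i}.{p.name}"
                if key not in state:
                    raise KeyError(f"checkpoint missing parameter {key}")
                if state[key].shape != p.value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.value = np.ascontiguousarray(state[key], dtype=np.float32)
        for key, bn in self._batchnorms():
            bn.running_mean = np.ascontiguousarray(
                state[f"{key}.running_mean"], dtype=np.float32
            )
            bn.running_var = np.ascontiguousarray(
                state[f"{key}.running_var"], dtype=np.float32
            )

    def _batchnorms(self) -> list[tuple[str, BatchNorm3d]]:
        out = []
        blocks: list[tuple[str, Sequential]] = []
        for d in range(self.config.levels):
            blocks += [
                (f"enc{d}", self.enc[d]),
                (f"down{d}", self.down[d]),
                (f"up{d}", self.up[d]),
                (f"dec{d}", self.dec[d]),
            ]
        blocks.append(("bottleneck", self.bottleneck))
        for name, seq in blocks:
            for i, layer in enumerate(seq.layers):
                if isinstance(layer, BatchNorm3d):
                    out.append((f"{name}.{i}", layer))
        return out

    def make_optimizer(self, lr: float = 0.001) -> Adam:
        return Adam(self.params(), lr=lr)


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0
                  ) -> MultiTaskUNet3D:
    """Construct the network; raises on an invalid configuration."""
    return MultiTaskUNet3D(config, seed=seed)


def count_parameters(network: MultiTaskUNet3D) -> int:
    """Total trainable scalars, including BN affine parameters and biases."""
    return int(sum(p.value.size for p in network.params()))
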