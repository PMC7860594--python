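"""Intensity normalization, training-target generation and patch cropping.

Instance labels are converted into two complementary binary targets: a
*boundary* mask (voxels at the interface between an instance and anything
with a different label, dilated by the radius-1 Euclidean ball) and a *soma*
mask (the remaining foreground).  Because the boundary shell is removed, the
soma targets of distinct instances are spatially disconnected, which is what
lets the downstream watershed split touching cell bodies.

Axis order is (z, y, x), 0-based, with half-open patch extents
``[origin, origin + patch_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# Euclidean ball of radius 1 voxel = the 7-voxel, 6-connected cross.
BALL_R1 = ndimage.generate_binary_structure(3, 1)


class DegenerateInputError(ValueError):
    """Raised when pooled training voxels carry no intensity variation."""


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled mean/std of all training-set voxels (population std)."""

    mean: float
    std: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise DegenerateInputError(
                f"standard deviation must be positive, got {self.std}"
            )


@dataclass(frozen=True)
class TargetMasks:
    """Paired binary training targets derived from instance labels."""

    soma: np.ndarray
    boundary: np.ndarray

    def __post_init__(self) -> None:
        if self.soma.shape != self.boundary.shape:
            raise ValueError("soma and boundary masks must share a shape")


@dataclass(frozen=True)
class Patch:
    """A cropped sub-volume and its corner in the (padded) source frame.

    ``pad_before`` records how much symmetric zero-padding was prepended to
    each axis of the source volume before cropping; origins are expressed in
    the padded frame.
    """

    data: np.ndarray
    origin: tuple[int, int, int]
    pad_before: tuple[int, int, int] = field(default=(0, 0, 0))


def compute_stats(volumes: list[np.ndarray]) -> NormalizationStats:
    """Pooled mean and population standard deviation over all voxels.

    Raises
    ------
    ValueError
        If no voxels are supplied.
    DegenerateInputError
        If the pooled voxel population is constant (std = 0).
    """
    arrays = [np.asarray(v, dtype=np.float64).ravel() for v in volumes]
    n = int(sum(a.size for a in arrays))
    if n == 0:
        raise ValueError("compute_stats requires at least one non-empty volume")
    pooled = np.concatenate(arrays)
    mean = float(pooled.mean())
    std = float(pooled.std())  # population std, denominator N
    if std == 0.0:
        raise DegenerateInputError("all pooled voxels are identical (std = 0)")
    return NormalizationStats(mean=mean, std=std, n_voxels=n)


def zscore_normalize(volume: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Return ``(volume - mean) / std`` as float32."""
    out = (np.asarray(volume, dtype=np.float32) - np.float32(stats.mean))
    out /= np.float32(stats.std)
    return out


def make_training_targets(labels: np.ndarray) -> TargetMasks:
    """Transform instance labels into complementary soma/boundary targets.

    A foreground voxel belongs to the raw boundary when any of its six
    face-neighbors carries a different label value (another instance or
    background).  The boundary target is the raw boundary dilated by the
    radius-1 ball, clipped to the foreground; the soma target is the
    remaining foreground.  The two targets partition the foreground (their
    "complementary spatial arrangement"), and distinct instances never share
    a 26-connected soma component.  A 5x5x5 cube instance, for example,
    yields a 2-voxel-thick boundary shell around a single-voxel soma core.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"labels must be 3D, got shape {labels.shape}")
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be non-negative")
    foreground = labels > 0

    raw_boundary = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            neighbor = _shifted(labels, axis, shift)
            raw_boundary |= foreground & (neighbor != labels)

    boundary = ndimage.binary_dilation(raw_boundary, structure=BALL_R1) & foreground
    soma = foreground & ~boundary
    return TargetMasks(soma=soma, boundary=boundary)


def _shifted(labels: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Neighbor values along ``axis``; out-of-volume neighbors read as 0."""
    out = np.zeros_like(labels)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = labels[tuple(src)]
    return out


def patch_origins(axis_len: int, patch_size: int, stride: int) -> list[int]:
    """Sliding-window origins: 0, stride, 2*stride, ... with the last origin
    clamped to ``axis_len - patch_size`` so the final patch abuts the border."""
    if axis_len < patch_size:
        raise ValueError("axis shorter than patch; pad first")
    last = axis_len - patch_size
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def crop_patches(
    volume: np.ndarray, patch_size: int = 80, stride: int = 48
) -> list[Patch]:
    """Crop a volume into overlapping cubic patches.

    Adjacent regular origins overlap by ``patch_size - stride`` voxels
    (32 at the defaults).  Axes shorter than ``patch_size`` are symmetrically
    zero-padded up to it; the padding is recorded in each patch's
    ``pad_before`` so downstream assembly can return to the original frame.
    """
    if not (patch_size > stride > 0):
        raise ValueError("need patch_size > stride > 0")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {volume.shape}")

    pad_before = [0, 0, 0]
    pad_width = []
    for ax, length in enumerate(volume.shape):
        if length < patch_size:
            deficit = patch_size - length
            before = deficit // 2
            after = deficit - before
            pad_before[ax] = before
            pad_width.append((before, after))
        else:
            pad_width.append((0, 0))
    if any(b or a for b, a in pad_width):
        logger.info("padding volume %s by %s to fit patch size %d",
                    volume.shape, pad_width, patch_size)
        volume = np.pad(volume, pad_width, mode="constant")

    axes_origins = [patch_origins(n, patch_size, stride) for n in volume.shape]
    patches = []
    for z0 in axes_origins[0]:
        for y0 in axes_origins[1]:
            for x0 in axes_origins[2]:
                data = volume[
                    z0 : z0 + patch_size,
                    y0 : y0 + patch_size,
                    x0 : x0 + patch_size,
                ]
                patches.append(
                    Patch(
                        data=data,
                        origin=(z0, y0, x0),
                        pad_before=tuple(pad_before),
                    )
                )
    return patches
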