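"""Patch assembly and watershed-based instance splitting.

Patch predictions are mosaicked back into a whole-volume probability pair:
each voxel is taken from the one patch whose *center region* owns it, since
voxels near patch borders lack context.  Both probability maps are then
thresholded at 0.5, the boundary mask is subtracted from the soma mask to
disconnect touching instances, small specks are removed by a radius-1
opening, and a marker-controlled watershed on the negated soma probability
re-absorbs the subtracted boundary shell into its nearest instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from somaseg.preprocess import BALL_R1, Patch

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class AssembledPrediction:
    """Whole-volume probability maps assembled from patch center regions."""

    soma_prob: np.ndarray
    boundary_prob: np.ndarray
    owner: np.ndarray | None = None  # per-voxel source-patch index, optional


@dataclass(frozen=True)
class SegmentationResult:
    """Final labeled instances with their centroids (z, y, x, voxel units)."""

    instances: np.ndarray
    centers: list[tuple[float, float, float]]


def _ownership_slices(
    origins: list[int], axis_len: int, patch_size: int, margin: int
) -> list[tuple[int, int]]:
    """Per-axis ownership interval for each origin: the patch center region,
    extended outward to the volume border for border patches."""
    out = []
    for o in origins:
        start = 0 if o == origins[0] else o + margin
        end = axis_len if o == origins[-1] else o + patch_size - margin
        out.append((start, end))
    return out


def assemble_patches(
    patch_preds: list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]],
    volume_shape: tuple[int, int, int],
    patch_size: int = 80,
    stride: int = 48,
    keep_owner: bool = False,
) -> AssembledPrediction:
    """Assemble per-patch (soma_prob, boundary_prob, origin) into one volume.

    A patch owns the sub-block ``[origin + m, origin + patch - m)`` per axis,
    with margin ``m = (patch_size - stride) // 2`` (16 at the defaults); the
    first/last patch along an axis extends its ownership to the border.
    Where ownership intervals overlap (odd ``patch_size - stride``, or the
    clamped final origin) the later patch wins.

    Raises on incomplete coverage (internal consistency check).
    """
    margin = (patch_size - stride) // 2
    soma = np.full(volume_shape, np.nan, dtype=np.float32)
    boundary = np.full(volume_shape, np.nan, dtype=np.float32)
    owner = np.full(volume_shape, -1, dtype=np.int32) if keep_owner else None

    origins_by_axis = [
        sorted({o[ax] for *_p, o in patch_preds}) for ax in range(3)
    ]
    slices_by_axis = [
        dict(
            zip(
                origins_by_axis[ax],
                _ownership_slices(
                    origins_by_axis[ax], volume_shape[ax], patch_size, margin
                ),
            )
        )
        for ax in range(3)
    ]

    for idx, (soma_p, bou_p, origin) in enumerate(patch_preds):
        if soma_p.shape != (patch_size,) * 3:
            raise ValueError(
                f"patch at {origin} has shape {soma_p.shape}, "
                f"expected {(patch_size,) * 3}"
            )
        vol_sl = []
        pat_sl = []
        for ax in range(3):
            start, end = slices_by_axis[ax][origin[ax]]
            vol_sl.append(slice(start, end))
            pat_sl.append(slice(start - origin[ax], end - origin[ax]))
        vol_sl, pat_sl = tuple(vol_sl), tuple(pat_sl)
        soma[vol_sl] = soma_p[pat_sl]
        boundary[vol_sl] = bou_p[pat_sl]
        if owner is not None:
            owner[vol_sl] = idx

    if np.isnan(soma).any():
        raise RuntimeError("assembly left uncovered voxels; patch set inconsistent")
    return AssembledPrediction(soma_prob=soma, boundary_prob=boundary, owner=owner)


def binarize(prob_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) are foreground."""
    return np.asarray(prob_volume) >= threshold


def split_instances(
    soma_mask: np.ndarray,
    boundary_mask: np.ndarray,
    soma_prob: np.ndarray,
    min_marker_voxels: int = 27,
    elevation: str = "probability",
) -> np.ndarray:
    """Split touching somata: boundary subtraction + marker-controlled watershed.

    Markers are the 26-connected components (of at least ``min_marker_voxels``
    voxels) of the radius-1 opening of ``soma_mask & ~boundary_mask``.  The
    watershed floods ``-soma_prob`` (or the negated distance transform of the
    soma mask when ``elevation="distance"``) from the markers over
    ``soma_mask | boundary_mask`` — the object region together with the
    subtracted boundary gap it must re-fill.  Labels are consecutive 1..K;
    an empty marker set yields an all-zero labeling.
    """
    soma_mask = np.asarray(soma_mask, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if soma_mask.shape != boundary_mask.shape or soma_mask.shape != np.shape(soma_prob):
        raise ValueError("soma_mask, boundary_mask and soma_prob must align")

    core = soma_mask & ~boundary_mask
    core = ndimage.binary_opening(core, structure=BALL_R1)
    markers, n = ndimage.label(core, structure=_STRUCT26)
    if n == 0:
        return np.zeros(soma_mask.shape, dtype=np.uint16)
    if min_marker_voxels > 1:
        sizes = ndimage.sum_labels(core, markers, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_marker_voxels) + 1
        if small.size:
            markers[np.isin(markers, small)] = 0
    if not markers.any():
        return np.zeros(soma_mask.shape, dtype=np.uint16)

    if elevation == "probability":
        landscape = -np.asarray(soma_prob, dtype=np.float32)
    elif elevation == "distance":
        landscape = -ndimage.distance_transform_edt(soma_mask).astype(np.float32)
    else:
        raise ValueError(f"unknown elevation mode {elevation!r}")

    labels = watershed(landscape, markers=markers, mask=soma_mask | boundary_mask)
    return _relabel_consecutive(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    values = np.unique(labels)
    values = values[values > 0]
    out = np.zeros(labels.shape, dtype=np.uint16 if values.size < 65535 else np.uint32)
    for new, old in enumerate(values, start=1):
        out[labels == old] = new
    return out


def extract_result(instances: np.ndarray) -> SegmentationResult:
    """Relabel 1..K and report each instance's unweighted voxel centroid."""
    instances = np.asarray(instances)
    relabeled = _relabel_consecutive(instances)
    values = np.unique(relabeled)
    values = values[values > 0]
    centers = []
    if values.size:
        coms = ndimage.center_of_mass(
            np.ones(relabeled.shape), relabeled, index=values
        )
        centers = [tuple(float(c) for c in com) for com in coms]
    return SegmentationResult(instances=relabeled, centers=centers)


def patches_to_preds(
    patches: list[Patch],
    probs: list[tuple[np.ndarray, np.ndarray]],
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]:
    """Pair network outputs with their patch origins for assembly."""
    return [
        (soma, bou, patch.origin)
        for patch, (soma, bou) in zip(patches, probs, strict=True)
    ]
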