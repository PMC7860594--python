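"""End-to-end prediction: normalize -> crop -> forward -> assemble -> split.

This is the full inference flow: the volume is z-score normalized with the
persisted training statistics, cropped into overlapping patches, each patch
is pushed through the network, the patch center regions are mosaicked back
into whole-volume probability maps, both maps are thresholded, the boundary
is subtracted from the soma mask and the marker-controlled watershed labels
the instances, whose centroids are the localization result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somaseg.nn.model import MultiTaskUNet3D
from somaseg.postprocess import (
    AssembledPrediction,
    SegmentationResult,
    assemble_patches,
    binarize,
    extract_result,
    split_instances,
)
from somaseg.preprocess import NormalizationStats, crop_patches, zscore_normalize


@dataclass(frozen=True)
class PredictConfig:
    patch_size: int = 80
    stride: int = 48
    threshold: float = 0.5
    min_marker_voxels: int = 27
    elevation: str = "probability"


def predict_probabilities(
    network: MultiTaskUNet3D,
    volume: np.ndarray,
    stats: NormalizationStats,
    config: PredictConfig = PredictConfig(),
) -> AssembledPrediction:
    """Whole-volume soma/boundary probability maps for one intensity stack."""
    normalized = zscore_normalize(volume, stats)
    patches = crop_patches(normalized, config.patch_size, config.stride)
    pad = patches[0].pad_before
    padded_shape = tuple(
        max(s, config.patch_size) for s in normalized.shape
    )
    preds = []
    for patch in patches:
        soma_p, bou_p = network.forward(patch.data, training=False)
        preds.append((soma_p, bou_p, patch.origin))
    assembled = assemble_patches(
        preds, padded_shape, config.patch_size, config.stride
    )
    if padded_shape != normalized.shape:
        sl = tuple(
            slice(p, p + s) for p, s in zip(pad, normalized.shape)
        )
        assembled = AssembledPrediction(
            soma_prob=assembled.soma_prob[sl],
            boundary_prob=assembled.boundary_prob[sl],
        )
    return assembled


def predict_volume(
    network: MultiTaskUNet3D,
    volume: np.ndarray,
    stats: NormalizationStats,
    config: PredictConfig = PredictConfig(),
) -> tuple[SegmentationResult, AssembledPrediction]:
    """Full inference for one stack: labeled instances plus their centroids."""
    assembled = predict_probabilities(network, volume, stats, config)
    soma_mask = binarize(assembled.soma_prob, config.threshold)
    boundary_mask = binarize(assembled.boundary_prob, config.threshold)
    instances = split_instances(
        soma_mask,
        boundary_mask,
        assembled.soma_prob,
        min_marker_voxels=config.min_marker_voxels,
        elevation=config.elevation,
    )
    return extract_result(instances), assembled
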