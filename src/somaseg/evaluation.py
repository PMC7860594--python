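"""Detection matching and segmentation scoring.

Localization is scored by matching predicted soma centers to ground-truth
centers: a pair is matched when its Euclidean distance is strictly below the
mean soma radius ``rc`` (11 voxels for the Nissl-stained stacks, 13 for the
GFP stacks).  Matching is one-to-one, greedy in ascending distance.  From the
match counts, precision = N_tp / (N_tp + N_fp), recall = N_tp / (N_tp + N_fn)
and F1 is their harmonic mean.  Segmentation quality is the Dice coefficient
2|A∩B| / (|A| + |B|) of each *matched* instance pair only; fold-level results
are aggregated by arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DetectionMatch:
    """One-to-one center assignment within radius ``rc``."""

    pairs: list[tuple[int, int, float]]  # (pred_index, gt_index, distance)
    n_tp: int
    n_fp: int
    n_fn: int
    rc: float


@dataclass(frozen=True)
class MetricsReport:
    """Localization and per-instance segmentation scores."""

    recall: float
    precision: float
    f1: float
    mean_dice: float
    dice_per_instance: list[float] = field(default_factory=list)


def match_detections(
    pred_centers: np.ndarray, gt_centers: np.ndarray, rc: float
) -> DetectionMatch:
    """Greedily match predicted to ground-truth centers within radius ``rc``.

    Candidate pairs with distance strictly below ``rc`` are accepted in
    ascending distance (ties broken by (pred_index, gt_index)); each center
    is used at most once.
    """
    if rc <= 0:
        raise ValueError("rc must be positive")
    pred = np.atleast_2d(np.asarray(pred_centers, dtype=np.float64))
    gt = np.atleast_2d(np.asarray(gt_centers, dtype=np.float64))
    n_pred = 0 if pred.size == 0 else pred.shape[0]
    n_gt = 0 if gt.size == 0 else gt.shape[0]

    candidates = []
    if n_pred and n_gt:
        d = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=-1)
        for i in range(n_pred):
            for j in range(n_gt):
                if d[i, j] < rc:
                    candidates.append((d[i, j], i, j))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    used_pred: set[int] = set()
    used_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for dist, i, j in candidates:
        if i in used_pred or j in used_gt:
            continue
        used_pred.add(i)
        used_gt.add(j)
        pairs.append((i, j, float(dist)))

    n_tp = len(pairs)
    return DetectionMatch(
        pairs=pairs, n_tp=n_tp, n_fp=n_pred - n_tp, n_fn=n_gt - n_tp, rc=float(rc)
    )


def precision_recall_f1(match: DetectionMatch) -> tuple[float, float, float]:
    """(precision, recall, f1); each 0 by convention on a zero denominator."""
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def instance_dice(
    pred_instances: np.ndarray,
    gt_instances: np.ndarray,
    match: DetectionMatch,
    pred_ids: list[int] | None = None,
    gt_ids: list[int] | None = None,
) -> list[float]:
    """Dice 2|A∩B|/(|A|+|B|) for every matched (pred, gt) instance pair.

    ``pred_ids``/``gt_ids`` map center indices to label values; by default
    center index k corresponds to label k+1 (the ``extract_result`` order).
    """
    pred_instances = np.asarray(pred_instances)
    gt_instances = np.asarray(gt_instances)
    scores = []
    for pi, gi, _dist in match.pairs:
        p_label = pred_ids[pi] if pred_ids is not None else pi + 1
        g_label = gt_ids[gi] if gt_ids is not None else gi + 1
        a = pred_instances == p_label
        b = gt_instances == g_label
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 or nb == 0:
            raise ValueError(
                f"matched instance with zero voxels (pred {p_label}, gt {g_label})"
            )
        scores.append(2.0 * int(np.sum(a & b)) / (na + nb))
    return scores


def evaluate_labeling(
    pred_instances: np.ndarray, gt_instances: np.ndarray, rc: float
) -> MetricsReport:
    """Full report for one volume: centroid matching then matched-pair Dice."""
    from somaseg.postprocess import extract_result

    pred_res = extract_result(pred_instances)
    gt_res = extract_result(gt_instances)
    match = match_detections(np.array(pred_res.centers), np.array(gt_res.centers), rc)
    precision, recall, f1 = precision_recall_f1(match)
    dice = instance_dice(pred_res.instances, gt_res.instances, match)
    return MetricsReport(
        recall=recall,
        precision=precision,
        f1=f1,
        mean_dice=float(np.mean(dice)) if dice else 0.0,
        dice_per_instance=dice,
    )


def aggregate_folds(per_fold: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each metric across folds.

    Localization metrics are reported at 2 decimals and Dice at 4, mirroring
    the usual table precision.
    """
    if not per_fold:
        raise ValueError("aggregate_folds needs at least one fold")
    return MetricsReport(
        recall=round(float(np.mean([m.recall for m in per_fold])), 2),
        precision=round(float(np.mean([m.precision for m in per_fold])), 2),
        f1=round(float(np.mean([m.f1 for m in per_fold])), 2),
        mean_dice=round(float(np.mean([m.mean_dice for m in per_fold])), 4),
    )


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def touching_pairs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Ground-truth instance pairs adjacent within 1 voxel (26-neighborhood)."""
    labels = np.asarray(labels)
    pairs: set[tuple[int, int]] = set()
    for k in np.unique(labels):
        if k == 0:
            continue
        grown = ndimage.binary_dilation(labels == k, structure=_STRUCT26)
        neighbors = np.unique(labels[grown])
        for j in neighbors:
            if j > 0 and j != k:
                pairs.add((min(int(k), int(j)), max(int(k), int(j))))
    return sorted(pairs)


def _majority_label(region: np.ndarray, reference: np.ndarray) -> int:
    """Most frequent reference label (incl. 0) inside a boolean region."""
    vals, counts = np.unique(reference[region], return_counts=True)
    return int(vals[np.argmax(counts)]) if vals.size else 0


def touching_pair_separation(
    gt_labels: np.ndarray,
    object_mask: np.ndarray,
    pred_instances: np.ndarray,
) -> tuple[int, int]:
    """How many CC-merged touching pairs the instance splitting separates.

    ``object_mask`` is the binarized object region before any boundary
    subtraction (the full predicted foreground); plain 26-connected component
    labeling of it is the baseline a boundary-unaware segmenter would
    produce.  For every pair of adjacent ground-truth instances that this
    baseline merges into one component, check whether the final instance
    labeling assigns the two instances to different predicted instances.
    Returns ``(n_separated, n_merged_by_cc)``.
    """
    cc, _ = ndimage.label(np.asarray(object_mask, dtype=bool), structure=_STRUCT26)
    merged = []
    for a, b in touching_pairs(gt_labels):
        ca = _majority_label(gt_labels == a, cc)
        cb = _majority_label(gt_labels == b, cc)
        if ca != 0 and ca == cb:
            merged.append((a, b))
    separated = 0
    for a, b in merged:
        pa = _majority_label(gt_labels == a, pred_instances)
        pb = _majority_label(gt_labels == b, pred_instances)
        if pa != 0 and pb != 0 and pa != pb:
            separated += 1
    return separated, len(merged)
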