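"""Augmentation, the Adam optimization loop and early stopping.

Training samples mini-batches with replacement from the pool of cropped
patches, applying on-the-fly random flips (all three axes independently,
image and targets together) and random brightness (affine intensity jitter
on the normalized image).  After each epoch the validation set is scored in
evaluation mode without augmentation; training stops once the validation
total loss has not improved for ``patience`` epochs and the checkpoint of
the best epoch is returned.  Because the boundary between *touching*
instances is the hard part of the task — it is a small minority of all
boundary voxels — the recall of the predicted boundary over ground-truth
touching-boundary voxels is logged every epoch and used as the tie-breaker
when two epochs reach the same validation loss.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from somaseg.losses import branch_loss_grad, total_loss
from somaseg.nn.model import MultiTaskUNet3D
from somaseg.preprocess import BALL_R1, TargetMasks, make_training_targets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters; defaults follow the reference recipe
    (Adam, lr 0.001, batch 4, 100 iterations per epoch)."""

    learning_rate: float = 0.001
    batch_size: int = 4
    iterations_per_epoch: int = 100
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    augment_flip: bool = True
    augment_brightness: bool = True
    brightness_factor_range: tuple[float, float] = (0.9, 1.1)
    brightness_offset_range: tuple[float, float] = (-0.1, 0.1)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.iterations_per_epoch < 1:
            raise ValueError("iterations_per_epoch must be >= 1")


@dataclass
class PatchSample:
    """One training/validation sample: normalized image patch, its targets
    and (for validation metrics) the instance labels it came from."""

    image: np.ndarray
    soma: np.ndarray
    boundary: np.ndarray
    labels: np.ndarray | None = None

    @classmethod
    def from_labels(cls, image: np.ndarray, labels: np.ndarray) -> "PatchSample":
        t = make_training_targets(labels)
        return cls(image=image, soma=t.soma, boundary=t.boundary, labels=labels)


@dataclass
class EpochRecord:
    epoch: int
    train_total: float
    val_total: float
    val_ce_soma: float
    val_dice_soma: float
    val_ce_boundary: float
    val_dice_boundary: float
    val_touching_recall: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    selected_epoch: int = -1

    def to_rows(self) -> list[dict]:
        return [vars(r) for r in self.records]


def augment(
    patch: np.ndarray,
    targets: TargetMasks,
    rng: np.random.Generator,
    config: TrainConfig = TrainConfig(),
    labels: np.ndarray | None = None,
):
    """Random flips and brightness jitter; masks stay binary and aligned.

    Each spatial axis is flipped independently with probability 0.5 (image
    and masks identically); the image then gets ``x -> a*x + b`` with
    ``a ~ U(brightness_factor_range)``, ``b ~ U(brightness_offset_range)``.
    Deterministic for a given generator state.
    """
    img = np.asarray(patch)
    soma, boundary = targets.soma, targets.boundary
    if config.augment_flip:
        for axis in range(3):
            if rng.random() < 0.5:
                img = np.flip(img, axis=axis)
                soma = np.flip(soma, axis=axis)
                boundary = np.flip(boundary, axis=axis)
                if labels is not None:
                    labels = np.flip(labels, axis=axis)
    if config.augment_brightness:
        a = rng.uniform(*config.brightness_factor_range)
        b = rng.uniform(*config.brightness_offset_range)
        img = (a * img + b).astype(np.float32)
    out_targets = TargetMasks(soma=np.ascontiguousarray(soma),
                              boundary=np.ascontiguousarray(boundary))
    if labels is None:
        return np.ascontiguousarray(img), out_targets
    return np.ascontiguousarray(img), out_targets, np.ascontiguousarray(labels)


def touching_boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels at interfaces between two *instances* (not background), dilated
    by the radius-1 ball; the minority class the boundary branch must hit."""
    labels = np.asarray(labels)
    fg = labels > 0
    touching = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.zeros_like(labels)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift > 0:
                src[axis], dst[axis] = slice(1, None), slice(None, -1)
            else:
                src[axis], dst[axis] = slice(None, -1), slice(1, None)
            rolled[tuple(dst)] = labels[tuple(src)]
            touching |= fg & (rolled > 0) & (rolled != labels)
    return ndimage.binary_dilation(touching, structure=BALL_R1)


def touching_boundary_recall(
    pred_boundary: np.ndarray, labels: np.ndarray
) -> float:
    """Fraction of ground-truth touching-boundary voxels covered by the
    predicted (binary) boundary; 1.0 by convention when none exist."""
    pred = np.asarray(pred_boundary, dtype=bool)
    if pred.shape != np.shape(labels):
        raise ValueError("pred_boundary and labels must share a shape")
    touching = touching_boundary_mask(labels)
    n = int(touching.sum())
    if n == 0:
        return 1.0
    return float((pred & touching).sum()) / n


class NonFiniteLossError(RuntimeError):
    pass


def _validate(network: MultiTaskUNet3D, samples: list[PatchSample]):
    totals = np.zeros(5)
    recalls = []
    for s in samples:
        soma_p, bou_p = network.forward(s.image, training=False)
        terms = total_loss(soma_p, bou_p, s.soma, s.boundary)
        totals += [terms.total, terms.ce_soma, terms.dice_soma,
                   terms.ce_boundary, terms.dice_boundary]
        if s.labels is not None:
            recalls.append(touching_boundary_recall(bou_p >= 0.5, s.labels))
    totals /= len(samples)
    recall = float(np.mean(recalls)) if recalls else 1.0
    return totals, recall


def train(
    network: MultiTaskUNet3D,
    train_samples: list[PatchSample],
    val_samples: list[PatchSample],
    config: TrainConfig = TrainConfig(),
) -> tuple[dict, TrainHistory]:
    """Optimize the network; returns (best checkpoint state, history).

    The checkpoint is the ``state_dict`` of the epoch minimizing validation
    total loss (ties broken by higher touching-boundary recall, then by the
    earlier epoch).
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = network.make_optimizer(lr=config.learning_rate)
    history = TrainHistory()

    best_loss = np.inf
    best_recall = -1.0
    best_state: dict | None = None
    epochs_since_improvement = 0

    for epoch in range(config.max_epochs):
        epoch_losses = []
        for it in range(config.iterations_per_epoch):
            idx = rng.integers(0, len(train_samples), size=config.batch_size)
            imgs, somas, bous = [], [], []
            for i in idx:
                s = train_samples[i]
                img, t = augment(
                    s.image, TargetMasks(s.soma, s.boundary), rng, config
                )
                imgs.append(img)
                somas.append(t.soma)
                bous.append(t.boundary)
            batch = np.stack(imgs).astype(np.float32)
            soma_t = np.stack(somas).astype(np.float32)
            bou_t = np.stack(bous).astype(np.float32)

            soma_p, bou_p = network.forward(batch, training=True)
            # per-sample losses averaged over the batch: the soft-Dice term
            # is defined over one sample's image space, so a patch with a
            # sparse boundary keeps its full gradient weight
            n = len(idx)
            batch_total = 0.0
            dsoma = np.empty_like(soma_p)
            dbou = np.empty_like(bou_p)
            for j in range(n):
                terms = total_loss(soma_p[j], bou_p[j], soma_t[j], bou_t[j])
                batch_total += terms.total / n
                dsoma[j] = branch_loss_grad(soma_p[j], soma_t[j]) / n
                dbou[j] = branch_loss_grad(bou_p[j], bou_t[j]) / n
            if not np.isfinite(batch_total):
                raise NonFiniteLossError(
                    f"non-finite loss at epoch {epoch}, iteration {it}"
                )
            optimizer.zero_grad()
            network.backward(dsoma, dbou)
            optimizer.step()
            epoch_losses.append(batch_total)

        val, recall = _validate(network, val_samples)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                train_total=float(np.mean(epoch_losses)),
                val_total=val[0],
                val_ce_soma=val[1],
                val_dice_soma=val[2],
                val_ce_boundary=val[3],
                val_dice_boundary=val[4],
                val_touching_recall=recall,
            )
        )
        logger.info(
            "epoch %d: train %.4f val %.4f touching-recall %.3f",
            epoch, history.records[-1].train_total, val[0], recall,
        )

        improved = val[0] < best_loss or (
            val[0] == best_loss and recall > best_recall
        )
        if improved:
            best_loss, best_recall = val[0], recall
            best_state = copy.deepcopy(network.state_dict())
            history.selected_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
        if epochs_since_improvement >= config.patience:
            logger.info("early stop at epoch %d", epoch)
            break

    assert best_state is not None
    network.load_state_dict(best_state)
    return best_state, history
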