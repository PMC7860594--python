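"""Training losses: per-branch cross-entropy + soft-Dice, summed over branches.

Each output branch (soma, boundary) is trained with

    L_branch = L_ce + (1 - D_soft)

where ``D_soft`` is the smoothed soft-Dice coefficient.  The soft-Dice term
counteracts the heavy foreground/background imbalance of the thin boundary
target.  The total loss is the sum of the two branch losses.

Values are computed in float64.  ``branch_loss_grad`` supplies the analytic
gradient with respect to the probabilities for the numpy training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7          # probability clamp for the log terms
DICE_SMOOTH = 1e-6  # smoothing in numerator and denominator


@dataclass(frozen=True)
class LossTerms:
    """All reported terms for one prediction pair (for logging)."""

    ce_soma: float
    dice_soma: float
    ce_boundary: float
    dice_boundary: float

    @property
    def branch_soma(self) -> float:
        return self.ce_soma + (1.0 - self.dice_soma)

    @property
    def branch_boundary(self) -> float:
        return self.ce_boundary + (1.0 - self.dice_boundary)

    @property
    def total(self) -> float:
        return self.branch_soma + self.branch_boundary


def _check_shapes(probs: np.ndarray, targets: np.ndarray) -> None:
    if probs.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs targets {targets.shape}"
        )


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all voxels.

    ``-(1/M) sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` with the
    probabilities clamped to ``[EPS, 1 - EPS]``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    _check_shapes(probs, targets)
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-np.mean(targets * np.log(p) + (1.0 - targets) * np.log1p(-p)))


def soft_dice_coefficient(probs: np.ndarray, targets: np.ndarray) -> float:
    """Smoothed soft-Dice overlap in [0, 1]; 1 for two empty masks."""
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    _check_shapes(probs, targets)
    num = 2.0 * float(np.sum(targets * probs)) + DICE_SMOOTH
    den = float(np.sum(probs) + np.sum(targets)) + DICE_SMOOTH
    return num / den


def branch_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Cross-entropy plus soft-Dice loss (1 - coefficient) for one branch."""
    return cross_entropy(probs, targets) + (
        1.0 - soft_dice_coefficient(probs, targets)
    )


def total_loss(
    soma_prob: np.ndarray,
    boundary_prob: np.ndarray,
    soma_target: np.ndarray,
    boundary_target: np.ndarray,
) -> LossTerms:
    """Both branch losses; ``.total`` is their sum."""
    return LossTerms(
        ce_soma=cross_entropy(soma_prob, soma_target),
        dice_soma=soft_dice_coefficient(soma_prob, soma_target),
        ce_boundary=cross_entropy(boundary_prob, boundary_target),
        dice_boundary=soft_dice_coefficient(boundary_prob, boundary_target),
    )


def branch_loss_grad(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Analytic d(branch_loss)/d(probs), same shape as ``probs``.

    Where the clamp is active the cross-entropy term is flat, matching the
    clamped forward value.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    _check_shapes(probs, targets)
    p = np.clip(probs, EPS, 1.0 - EPS)
    m = probs.size
    grad_ce = (-targets / p + (1.0 - targets) / (1.0 - p)) / m
    active = (probs > EPS) & (probs < 1.0 - EPS)
    grad_ce = np.where(active, grad_ce, 0.0)

    num = 2.0 * float(np.sum(targets * probs)) + DICE_SMOOTH
    den = float(np.sum(probs) + np.sum(targets)) + DICE_SMOOTH
    # d(1 - num/den)/dp_i = -(2 y_i den - num) / den^2
    grad_dice = -(2.0 * targets * den - num) / (den * den)
    return grad_ce + grad_dice
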