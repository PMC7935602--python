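"""Loss algebra for adversarial segmentation training.

The segmenter minimises ``J = J_CE + alpha * J_adv``: voxel-wise
cross-entropy against the one-hot annotation plus an alpha-weighted
non-saturating generator term ``-ln D(x, S(x))``.  The discriminator
minimises the standard binary cross-entropy
``-ln D(x, y) - ln(1 - D(x, S(x)))``.  All probabilities are clamped to
``[eps, 1 - eps]`` before any logarithm, so every loss is finite.
Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7


def _clamp(p: np.ndarray | float) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


@dataclass(frozen=True)
class LossBreakdown:
    """The components of one segmenter update's objective."""

    j_ce: float
    j_adv_gen: float
    alpha: float

    @property
    def j_total(self) -> float:
        return self.j_ce + self.alpha * self.j_adv_gen


def cross_entropy(prob: np.ndarray, target_onehot: np.ndarray) -> float:
    """Mean over voxels of ``-ln`` (probability assigned to the true class).

    ``prob`` and ``target_onehot`` are channel-first arrays of equal
    shape, with channels on the simplex and targets one-hot.  ``N`` in
    the average is the total voxel count (all axes except the channel
    axis), so the value is the per-voxel expected surprisal.
    """
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target_onehot, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")
    channel_axis = 0 if prob.ndim == 4 else 1
    n_voxels = prob.size // prob.shape[channel_axis]
    return float(-(target * np.log(_clamp(prob))).sum() / n_voxels)


def cross_entropy_grad(prob: np.ndarray, target_onehot: np.ndarray) -> np.ndarray:
    """Gradient of :func:`cross_entropy` w.r.t. ``prob``."""
    prob = np.asarray(prob, dtype=np.float32)
    target = np.asarray(target_onehot, dtype=np.float32)
    channel_axis = 0 if prob.ndim == 4 else 1
    n_voxels = prob.size // prob.shape[channel_axis]
    g = np.where(target > 0, -1.0 / _clamp(prob), 0.0) / n_voxels
    return g.astype(np.float32)


def cross_entropy_logit_grad(prob: np.ndarray, target_onehot: np.ndarray) -> np.ndarray:
    """Gradient of :func:`cross_entropy` w.r.t. the softmax *logits*.

    The fused softmax/cross-entropy form ``(p - g) / N`` is bounded by
    ``1/N`` even where a softmax output has underflowed to exactly 0 —
    whereas chaining the probability-space gradient through the softmax
    Jacobian silently zeroes such voxels, so a class squeezed out of a
    region could never recover.  Training uses this form.
    """
    prob = np.asarray(prob, dtype=np.float32)
    target = np.asarray(target_onehot, dtype=np.float32)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")
    channel_axis = 0 if prob.ndim == 4 else 1
    n_voxels = prob.size // prob.shape[channel_axis]
    return ((prob - target) / n_voxels).astype(np.float32)


def discriminator_loss(d_real: np.ndarray | float, d_fake: np.ndarray | float) -> float:
    """Binary cross-entropy for the discriminator, averaged over the batch.

    ``-ln d_real - ln(1 - d_fake)``: minimised when real (image, manual
    annotation) pairs score near 1 and generated pairs near 0.
    """
    d_real = _clamp(np.atleast_1d(np.asarray(d_real, dtype=np.float64)))
    d_fake = _clamp(np.atleast_1d(np.asarray(d_fake, dtype=np.float64)))
    return float(np.mean(-np.log(d_real) - np.log(1.0 - d_fake)))


def discriminator_loss_grads(d_real, d_fake) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`discriminator_loss` w.r.t. its two inputs."""
    d_real = _clamp(np.atleast_1d(np.asarray(d_real, dtype=np.float64)))
    d_fake = _clamp(np.atleast_1d(np.asarray(d_fake, dtype=np.float64)))
    n = d_real.size
    return (-1.0 / (n * d_real)), (1.0 / (n * (1.0 - d_fake)))


def generator_adversarial_loss(d_fake: np.ndarray | float) -> float:
    """Non-saturating generator term ``-ln d_fake``, batch-averaged.

    Decreases as the discriminator is fooled into scoring generated
    segmentations as manual annotations.
    """
    d_fake = _clamp(np.atleast_1d(np.asarray(d_fake, dtype=np.float64)))
    return float(np.mean(-np.log(d_fake)))


def generator_adversarial_loss_grad(d_fake) -> np.ndarray:
    """Gradient of :func:`generator_adversarial_loss` w.r.t. ``d_fake``."""
    d_fake = _clamp(np.atleast_1d(np.asarray(d_fake, dtype=np.float64)))
    return -1.0 / (d_fake.size * d_fake)


def total_loss(j_ce: float, j_adv_gen: float, alpha: float) -> LossBreakdown:
    """Combine the segmenter's two objectives; ``alpha = 0`` is the
    pure cross-entropy baseline."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    return LossBreakdown(j_ce=float(j_ce), j_adv_gen=float(j_adv_gen), alpha=float(alpha))
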