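"""Training objectives: β-mixed cross-entropy, temperature-scaled
contrastive loss, and their α-blend.

The objective has three parts. A two-class cross-entropy is computed per
classification head and mixed by β:

    L_CE = -(1-β) Σ_i log p̂_{i,1}[y_i]  -  β Σ_i log p̂_{i,2}[y_i]

β=0 trains on head 1 alone, β=1 on head 2 alone, β=0.5 on both equally.
The contrastive term pulls the two projections of the same peptide
together and pushes projections of different peptides apart:

    L_CL = -Σ_i log[ exp(z_{i,1}·z_{i,2}/τ) / Σ_{j≠i} exp(z_{i,1}·z_{j,2}/τ) ]

Note the denominator runs over j≠i only — the positive pair is excluded,
so unlike standard InfoNCE the loss can go negative. A config switch
restores the conventional denominator for comparison. The final
objective is the affine blend

    L_final = (1-α) L_CE + α L_CL

with α=0 recovering the cross-entropy-only baseline.

All functions accept autodiff Tensors (gradients flow) or plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, ensure_tensor

#: Probability clamp bounds keeping log() finite under saturated softmax.
_PROB_EPS = 1e-12


class LossConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LossWeights:
    """α blends CE vs contrastive; β mixes the heads' CE; τ is temperature."""

    alpha: float = 0.0
    beta: float = 0.5
    tau: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise LossConfigError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise LossConfigError(f"beta must be in [0,1], got {self.beta}")
        if self.tau <= 0.0:
            raise LossConfigError(f"tau must be > 0, got {self.tau}")


def _true_class_log_prob(probs: Tensor, onehot: np.ndarray) -> Tensor:
    picked = (probs * onehot).sum(axis=-1)
    return picked.clip(_PROB_EPS, 1.0 - _PROB_EPS).log()


def mixed_cross_entropy(labels, probs_1, probs_2, beta: float,
                        reduction: str = "sum") -> Tensor:
    """β-mixed two-class cross-entropy over both classification heads."""
    if not 0.0 <= beta <= 1.0:
        raise LossConfigError(f"beta must be in [0,1], got {beta}")
    if reduction not in ("sum", "mean"):
        raise LossConfigError(f"unknown reduction {reduction!r}")
    labels = np.asarray(labels, dtype=np.int64)
    probs_1 = ensure_tensor(probs_1)
    probs_2 = ensure_tensor(probs_2)
    n = labels.shape[0]
    if probs_1.shape[0] != n or probs_2.shape[0] != n:
        raise ValueError(
            f"length mismatch: {n} labels vs {probs_1.shape[0]}/"
            f"{probs_2.shape[0]} probability rows"
        )
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), labels] = 1.0
    ll_1 = _true_class_log_prob(probs_1, onehot).sum()
    ll_2 = _true_class_log_prob(probs_2, onehot).sum()
    loss = -(1.0 - beta) * ll_1 - beta * ll_2
    if reduction == "mean":
        loss = loss * (1.0 / n)
    return loss


def contrastive_loss(z_1, z_2, tau: float,
                     include_positive_in_denominator: bool = False,
                     symmetric: bool = False,
                     reduction: str = "sum") -> Tensor:
    """Temperature-scaled contrastive loss over aligned projection rows.

    Row i of ``z_1`` and ``z_2`` must be the two views of the same
    peptide. By default the loss is one-directional (anchors from tower
    1, negatives from tower 2) with the positive pair excluded from the
    denominator, exactly as the objective is defined; ``symmetric=True``
    averages both directions and ``include_positive_in_denominator=True``
    switches to the standard InfoNCE denominator.
    """
    if tau <= 0.0:
        raise LossConfigError(f"tau must be > 0, got {tau}")
    if reduction not in ("sum", "mean"):
        raise LossConfigError(f"unknown reduction {reduction!r}")
    z_1 = ensure_tensor(z_1)
    z_2 = ensure_tensor(z_2)
    if z_1.shape != z_2.shape:
        raise ValueError(f"shape mismatch: {z_1.shape} vs {z_2.shape}")
    n = z_1.shape[0]
    if n < 2:
        raise ValueError(
            f"contrastive loss needs a batch of >= 2, got {n} "
            "(the denominator needs at least one j != i)"
        )

    def one_direction(za: Tensor, zb: Tensor) -> Tensor:
        sim = (za @ zb.swapaxes(-1, -2)) * (1.0 / tau)  # (n, n)
        shift = Tensor(sim.data.max(axis=1, keepdims=True))
        sim_s = sim - shift
        eye = np.eye(n)
        pos = (sim_s * eye).sum(axis=1)
        denom_mask = np.ones((n, n)) if include_positive_in_denominator \
            else 1.0 - eye
        log_denom = ((sim_s.exp() * denom_mask).sum(axis=1)).log()
        return -(pos - log_denom).sum()

    loss = one_direction(z_1, z_2)
    if symmetric:
        loss = (loss + one_direction(z_2, z_1)) * 0.5
    if reduction == "mean":
        loss = loss * (1.0 / n)
    return loss


def combined_loss(l_ce, l_cl, alpha: float) -> Tensor:
    """L_final = (1-α)·L_CE + α·L_CL; α=0 is the baseline objective."""
    if not 0.0 <= alpha <= 1.0:
        raise LossConfigError(f"alpha must be in [0,1], got {alpha}")
    return (1.0 - alpha) * ensure_tensor(l_ce) + alpha * ensure_tensor(l_cl)
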