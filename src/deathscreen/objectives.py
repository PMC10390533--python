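"""Training objectives: supervised contrastive loss + cross-entropy.

The supervised contrastive loss over a batch of embeddings z_i with class
labels y_i is

    L_sup = sum_i (-1 / |P(i)|) * sum_{p in P(i)}
            log[ exp(z_i . z_p / tau) / sum_{a in A(i)} exp(z_i . z_a / tau) ]

where A(i) is the batch without the anchor i, P(i) = {p in A(i) : y_p = y_i}
are the anchor's positives and tau is the temperature. Anchors with no
positives contribute zero (the 0/0 convention that keeps skewed batches and
the no-contrastive ablation well defined). Same-class embeddings are pulled
together and different-class embeddings pushed apart; embeddings are
L2-normalised upstream so the inner products are cosine similarities.

The total objective is L = lambda1 * L_sup + lambda2 * L_ce with a
categorical cross-entropy classification term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossConfig:
    tau: float = 0.1
    lambda1: float = 0.5
    lambda2: float = 0.5
    reduction: str = "sum"  # over anchors: "sum" (as the equation) or "mean"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.reduction not in ("sum", "mean"):
            raise ValueError(f"reduction must be sum|mean, got {self.reduction}")


@dataclass
class EmbeddingBatch:
    """Embeddings + labels + plate ids for one sampled batch."""

    z: np.ndarray  # (N, d)
    y: np.ndarray  # (N,) integer or string labels
    plate: np.ndarray | None = None  # (N,) plate ids

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        self.y = np.asarray(self.y)
        if self.z.ndim != 2 or self.z.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"z {self.z.shape} and y {self.y.shape} are inconsistent"
            )
        if self.z.shape[0] < 2:
            raise ValueError("a contrastive batch needs at least 2 samples")


def _positive_mask(y: np.ndarray) -> np.ndarray:
    pos = y[:, None] == y[None, :]
    np.fill_diagonal(pos, False)
    return pos


def supcon_loss(
    batch: EmbeddingBatch, tau: float = 0.1, reduction: str = "sum"
) -> float:
    """Supervised contrastive loss of a batch (non-negative scalar)."""
    loss, _ = supcon_loss_and_grad(batch, tau=tau, reduction=reduction)
    return loss


def supcon_loss_and_grad(
    batch: EmbeddingBatch, tau: float = 0.1, reduction: str = "sum"
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the embeddings.

    Vectorised with max-subtraction inside the log-sum-exp for stability.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    z = np.asarray(batch.z, dtype=np.float64)
    n = z.shape[0]
    s = (z @ z.T) / tau
    np.fill_diagonal(s, -np.inf)  # exclude the anchor from A(i)
    row_max = s.max(axis=1, keepdims=True)
    exp_s = np.exp(s - row_max)
    denom = exp_s.sum(axis=1, keepdims=True)
    log_prob = (s - row_max) - np.log(denom)  # log softmax over A(i)
    p_soft = exp_s / denom  # softmax probabilities, diagonal 0

    pos = _positive_mask(batch.y)
    n_pos = pos.sum(axis=1)
    has_pos = n_pos > 0
    per_anchor = np.zeros(n)
    if has_pos.any():
        sums = np.where(pos, log_prob, 0.0).sum(axis=1)
        per_anchor[has_pos] = -sums[has_pos] / n_pos[has_pos]
    loss = float(per_anchor.sum())

    # dL/ds_ij = -1{j in P(i)}/|P(i)| + p_ij, for anchors with positives
    g = np.zeros_like(s)
    if has_pos.any():
        inv = np.zeros(n)
        inv[has_pos] = 1.0 / n_pos[has_pos]
        g[has_pos] = p_soft[has_pos] - pos[has_pos] * inv[has_pos, None]
    np.fill_diagonal(g, 0.0)
    grad = ((g + g.T) @ z) / tau

    if reduction == "mean":
        loss /= n
        grad /= n
    return loss, grad.astype(batch.z.dtype if hasattr(batch.z, "dtype") else np.float64)


def supcon_loss_reference(batch: EmbeddingBatch, tau: float = 0.1) -> float:
    """Brute-force double-loop reference implementation (test oracle).

    Follows the defining formula term by term; O(N^2 d) per anchor pair and
    deliberately independent of the vectorised path.
    """
    z = np.asarray(batch.z, dtype=np.float64)
    y = batch.y
    n = z.shape[0]
    total = 0.0
    for i in range(n):
        others = [a for a in range(n) if a != i]
        positives = [p for p in others if y[p] == y[i]]
        if not positives:
            continue
        denom = sum(np.exp(float(z[i] @ z[a]) / tau) for a in others)
        acc = 0.0
        for p in positives:
            acc += np.log(np.exp(float(z[i] @ z[p]) / tau) / denom)
        total += -acc / len(positives)
    return float(total)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape[0] != n:
        raise ValueError("labels/logits length mismatch")
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    loss = float(-log_probs[np.arange(n), labels].mean())
    grad = np.exp(log_probs)
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad


def total_loss(supcon: float, ce: float, cfg: LossConfig | None = None) -> float:
    """Weighted combination lambda1 * L_sup + lambda2 * L_ce."""
    cfg = cfg or LossConfig()
    if not (np.isfinite(supcon) and np.isfinite(ce)):
        raise ValueError(f"non-finite loss inputs: supcon={supcon}, ce={ce}")
    return cfg.lambda1 * supcon + cfg.lambda2 * ce
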