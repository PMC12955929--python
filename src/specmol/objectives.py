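"""Training objectives: masked-node pre-training loss, dynamic task
weighting, class-balanced weighting, weighted cross-entropy, supervised
contrastive loss, and their combination.

Multi-task losses are combined with *dynamic task weighting* (DTW): each
task's raw weight is multiplied by ``1 + gamma * (L_t - Lbar) / (Lbar + eps)``
every update, so tasks currently losing ground get more weight, then the
weights are normalized to sum to one.  Class imbalance is handled with
effective-number class weights ``w_c = (1 - beta) / (1 - beta^{N_c})``
normalized to sum to the class count.  A supervised contrastive term with
temperature-scaled cosine similarity pulls same-label graph embeddings
together.

All differentiable losses accept either plain arrays (returning plain
values) or :class:`~specmol.autograd.Tensor` inputs (joining the tape).
Note: the class-balance hyperparameter ``beta_cb`` and the contrastive
weight ``lambda_contrastive`` are unrelated to the attention parameters of
the same Greek letters in :mod:`specmol.network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, as_tensor, concat

logger = logging.getLogger(__name__)

__all__ = ["TaskState", "ClassWeights", "LossReport", "pretrain_loss",
           "update_task_weights", "normalize_task_weights", "class_weights",
           "weighted_bce", "masked_mse", "classification_loss", "supcon_loss",
           "total_loss"]

WEIGHT_FLOOR = 1e-4
_P_EPS = 1e-7


@dataclass
class TaskState:
    """Per-task dynamic weights and their loss-history state."""

    lambda_raw: np.ndarray                  # [T], all > 0
    loss_history_mean: np.ndarray | None = None   # EMA of per-task losses
    gamma: float = 0.1
    epsilon: float = 1e-8
    ema_momentum: float = 0.9
    t: int = 0

    @classmethod
    def initial(cls, n_tasks: int, gamma: float = 0.1,
                epsilon: float = 1e-8, ema_momentum: float = 0.9) -> "TaskState":
        return cls(lambda_raw=np.ones(n_tasks), gamma=gamma, epsilon=epsilon,
                   ema_momentum=ema_momentum)


def update_task_weights(state: TaskState,
                        current_losses: np.ndarray) -> TaskState:
    """One DTW step: scale each weight by the relative deviation of its
    task's loss from the historical mean, then floor at 1e-4.

    The history is an exponential moving average initialized to the first
    observed loss (so the first update leaves the weights unchanged).
    """
    L = np.asarray(current_losses, dtype=np.float64)
    if np.any(~np.isfinite(L)):
        bad = int(np.flatnonzero(~np.isfinite(L))[0])
        raise FloatingPointError(f"non-finite loss for task index {bad}")
    if L.shape != state.lambda_raw.shape:
        raise ValueError("loss vector length != task count")
    hist = L.copy() if state.loss_history_mean is None \
        else state.loss_history_mean
    lam = state.lambda_raw * (1.0 + state.gamma * (L - hist)
                              / (hist + state.epsilon))
    lam = np.maximum(lam, WEIGHT_FLOOR)
    m = state.ema_momentum
    new_hist = m * hist + (1.0 - m) * L
    return replace(state, lambda_raw=lam, loss_history_mean=new_hist,
                   t=state.t + 1)


def normalize_task_weights(state: TaskState) -> np.ndarray:
    """Weights normalized to sum to one."""
    lam = state.lambda_raw
    return lam / lam.sum()


@dataclass
class ClassWeights:
    """Effective-number class weights, normalized to sum to C."""

    beta_cb: float
    counts: np.ndarray
    w: np.ndarray
    w_norm: np.ndarray


def class_weights(counts, beta_cb: float = 0.99) -> ClassWeights:
    """``w_c = (1 - beta) / (1 - beta^{N_c})``, then scaled so the included
    classes' weights sum to their number.  Classes with zero observed
    samples are excluded (weight 0) with a warning."""
    counts = np.asarray(counts, dtype=np.float64)
    if not 0.0 < beta_cb < 1.0:
        raise ValueError("beta_cb must be in (0, 1)")
    observed = counts > 0
    if not observed.all():
        logger.warning("classes with zero samples excluded from weighting: "
                       "%s", np.flatnonzero(~observed).tolist())
    w = np.zeros_like(counts)
    w[observed] = (1.0 - beta_cb) / (1.0 - beta_cb ** counts[observed])
    C = int(observed.sum())
    w_norm = np.zeros_like(w)
    if C:
        w_norm[observed] = w[observed] / w[observed].sum() * C
    return ClassWeights(beta_cb=beta_cb, counts=counts, w=w, w_norm=w_norm)


def pretrain_loss(node_pred, node_target, masked: np.ndarray,
                  global_pred=None, global_target=None):
    """Masked-node reconstruction objective.

    Sum of squared errors between predicted and true feature vectors over
    the masked atoms, plus the squared error on the global-node descriptor.
    """
    masked = np.asarray(masked, dtype=bool)
    if not masked.any() and global_target is None:
        raise ValueError("pretrain loss needs masked atoms or a global target")
    total = None
    if masked.any():
        pred = as_tensor(node_pred)[masked]
        diff = pred - np.asarray(node_target, dtype=np.float64)[masked]
        total = (diff * diff).sum()
    if global_target is not None:
        gdiff = as_tensor(global_pred) - np.asarray(global_target,
                                                    dtype=np.float64)
        gterm = (gdiff * gdiff).sum()
        total = gterm if total is None else total + gterm
    return total


def weighted_bce(p, y, w1: float = 1.0, w0: float = 1.0):
    """Class-weighted binary cross-entropy for one task.

    ``-w1 y log p - w0 (1-y) log(1-p)`` per observed sample; NaN labels are
    excluded.  Returns ``(per_sample, task_mean)``; a task with no observed
    labels contributes zero (logged).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    obs = ~np.isnan(y)
    if not obs.any():
        logger.warning("task batch has no observed labels; contributing 0")
        return Tensor(np.zeros(0)), Tensor(0.0)
    p = as_tensor(p).reshape(-1)[obs].clip(_P_EPS, 1.0 - _P_EPS)
    yo = y[obs]
    per_sample = -(w1 * yo) * p.log() - (w0 * (1.0 - yo)) * (1.0 - p).log()
    return per_sample, per_sample.mean()


def masked_mse(pred, y):
    """Mean squared error over observed (non-NaN) labels for one task."""
    y = np.asarray(y, dtype=np.float64).ravel()
    obs = ~np.isnan(y)
    if not obs.any():
        logger.warning("task batch has no observed labels; contributing 0")
        return Tensor(0.0)
    diff = as_tensor(pred).reshape(-1)[obs] - y[obs]
    return (diff * diff).mean()


def classification_loss(per_task_losses, weights):
    """Normalized-weight combination of per-task losses."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(per_task_losses) != weights.shape[0]:
        raise ValueError("per-task loss count != weight count")
    terms = [as_tensor(l).reshape(1) * float(w)
             for l, w in zip(per_task_losses, weights)]
    return concat(terms).sum()


def supcon_loss(embeddings, labels, tau: float = 0.1):
    """Supervised contrastive loss with temperature-scaled cosine similarity.

    Positives P(i) are the other samples sharing sample i's label; self-pairs
    are excluded from numerator and denominator; anchors without positives
    are dropped and the average runs over the remaining anchors.  By
    construction the numerator set is a subset of the denominator set, so
    the loss is non-negative.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    H = as_tensor(embeddings)
    n = H.shape[0]
    if n < 2:
        raise ValueError("supcon needs at least 2 samples")
    labels = np.asarray(labels).ravel()
    same = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(n, dtype=bool)
    pos_mask = (same & offdiag).astype(np.float64)
    valid = pos_mask.any(axis=1)
    if not valid.any():
        logger.warning("supcon batch has no anchors with positives; loss 0")
        return Tensor(0.0)

    norms = (H * H).sum(axis=1, keepdims=True).sqrt()
    Hn = H / (norms + 1e-12)
    sim = Hn @ Hn.T
    E = (sim * (1.0 / tau)).exp() * offdiag.astype(np.float64)
    num = (E * pos_mask).sum(axis=1)[valid]
    den = E.sum(axis=1)[valid]
    return -((num / den).log()).mean()


def total_loss(classification, contrastive, lambda_contrastive: float = 0.1):
    """Total objective: task loss plus weighted contrastive term."""
    return as_tensor(classification) + lambda_contrastive * as_tensor(contrastive)


@dataclass
class LossReport:
    """Per-component loss values for one batch (plain floats)."""

    pretrain: float = float("nan")
    per_task: np.ndarray = field(default_factory=lambda: np.zeros(0))
    classification: float = float("nan")
    contrastive: float = float("nan")
    total: float = float("nan")
    lambda_contrastive: float = 0.1

    def __post_init__(self):
        # fine-tuning mode: components must reassemble into the total
        if np.isfinite(self.total) and np.isfinite(self.classification):
            expected = self.classification \
                + self.lambda_contrastive * self.contrastive
            if abs(self.total - expected) > 1e-9:
                raise ValueError("total != classification + lambda*contrastive")
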