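"""Task heads, the weighted cross-entropy, and the uncertainty-weighted joint loss.

The per-task loss is, with y_t the predicted probability of the true class,

    L(y_t) = -alpha * (1 - y_t)^gamma * log(y_t) + beta * H(y_t)

where the regularizer H(y_t) = -y_t log y_t - (1 - y_t) log(1 - y_t) is the
printed entropy form; ``form="conventional"`` swaps it for the standard
-log(y_t) cross-entropy. alpha is the class-ratio scaling factor (negative
count / positive count on the training split), gamma the focusing exponent
(default 2), beta the regularization factor.

The joint loss combines the two task losses with trainable positive weights
gamma_i (initialized at 1, parameterized as log gamma_i for positivity):

    L_joint = sum_i L_i / (2 gamma_i^2) + sum_i log gamma_i
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)

TASKS = ("idh", "grade")


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 1.0
    gamma: float = 2.0
    beta: float = 1.0
    epsilon: float = 1e-7
    form: str = "as_printed"  # or "conventional"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.form not in ("as_printed", "conventional"):
            raise ValueError(f"unknown loss form {self.form!r}")


def alpha_from_labels(labels: np.ndarray) -> float:
    """Class-ratio scaling factor: negative count / positive count."""
    labels = np.asarray(labels)
    pos = int((labels == 1).sum())
    neg = int((labels == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present to compute alpha")
    return neg / pos


def weighted_ce(y_t, cfg: LossConfig):
    """Weighted cross-entropy of the true-class probability.

    Accepts a float or a Tensor (autograd flows through Tensors); returns the
    same kind. Probabilities outside (0, 1) are clamped to
    [epsilon, 1 - epsilon] with a logged warning.
    """
    lo, hi = cfg.epsilon, 1.0 - cfg.epsilon
    if not isinstance(y_t, Tensor):
        # scalar/array path in float64
        y = np.asarray(y_t, dtype=np.float64)
        if np.any(y < 0) or np.any(y > 1):
            logger.warning("probability outside (0, 1) clamped to [%g, %g]", lo, hi)
        y = np.clip(y, lo, hi)
        focal = -cfg.alpha * (1.0 - y) ** cfg.gamma * np.log(y)
        if cfg.form == "as_printed":
            reg = -y * np.log(y) - (1.0 - y) * np.log(1.0 - y)
        else:
            reg = -np.log(y)
        out = focal + cfg.beta * reg
        return float(out) if out.ndim == 0 else out
    y = y_t
    if np.any(y.data < lo) or np.any(y.data > hi):
        if np.any(y.data < 0) or np.any(y.data > 1):
            logger.warning("probability outside (0, 1) clamped to [%g, %g]", lo, hi)
        y = y.clamp(lo, hi)
    focal = -cfg.alpha * ((1.0 - y) ** cfg.gamma) * y.log()
    if cfg.form == "as_printed":
        reg = -(y * y.log()) - (1.0 - y) * (1.0 - y).log()
    else:
        reg = -y.log()
    return focal + cfg.beta * reg


class UncertaintyWeights(nn.Module):
    """Trainable per-task weights gamma_i, stored as log gamma_i (positivity)."""

    def __init__(self, n_tasks: int = 2):
        super().__init__()
        self.log_gamma = nn.Parameter(np.zeros(n_tasks, dtype=nn.DTYPE))

    @property
    def gammas(self) -> np.ndarray:
        return np.exp(self.log_gamma.data)

    def forward(self, losses: list) -> Tensor:
        if len(losses) != self.log_gamma.shape[0]:
            raise ValueError(
                f"expected {self.log_gamma.shape[0]} losses, got {len(losses)}")
        total = None
        for i, L in enumerate(losses):
            if not isinstance(L, Tensor):
                L = Tensor(np.asarray(L, dtype=np.float64))
            lg = self.log_gamma[i]
            term = 0.5 * L * (-2.0 * lg).exp() + lg
            total = term if total is None else total + term
        return total


def joint_loss(l1, l2, weights: "UncertaintyWeights | np.ndarray | tuple"):
    """Uncertainty-weighted sum of two task losses.

    ``weights`` may be an UncertaintyWeights module (trainable path) or a
    sequence of two positive gamma values (functional path).
    """
    if isinstance(weights, UncertaintyWeights):
        return weights([l1, l2])
    g = np.asarray(weights, dtype=np.float64)
    if np.any(g <= 0):
        raise ValueError(f"gamma weights must be positive, got {g}")
    l = np.asarray([float(l1), float(l2)])
    return float((l / (2.0 * g ** 2)).sum() + np.log(g).sum())


class TaskHeads(nn.Module):
    """Two independent affine heads with a 2-way softmax each."""

    def __init__(self, in_features: int, rng: np.random.Generator):
        super().__init__()
        self.idh = nn.Linear(in_features, 2, rng)
        self.grade = nn.Linear(in_features, 2, rng)

    def forward(self, feature: Tensor) -> dict[str, Tensor]:
        return {"idh": self.idh(feature).softmax(axis=-1),
                "grade": self.grade(feature).softmax(axis=-1)}

    def logits(self, feature: Tensor) -> dict[str, Tensor]:
        return {"idh": self.idh(feature), "grade": self.grade(feature)}


def true_class_prob(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Select the predicted probability of each sample's true class."""
    n = probs.shape[0]
    return probs[np.arange(n), np.asarray(labels, dtype=np.int64)]


def task_losses(probs: dict[str, Tensor], labels: dict[str, np.ndarray],
                configs: dict[str, LossConfig]) -> dict[str, Tensor]:
    """Mean weighted cross-entropy per task, with alpha applied to the
    positive (label-1) samples only, so minority-class samples are upweighted
    by the neg/pos ratio while the other class keeps weight 1."""
    out = {}
    for task in TASKS:
        cfg = configs[task]
        y = true_class_prob(probs[task], labels[task])
        pos_cfg = cfg
        neg_cfg = replace(cfg, alpha=1.0)
        l_pos = weighted_ce(y, pos_cfg)
        l_neg = weighted_ce(y, neg_cfg)
        is_pos = Tensor(np.asarray(labels[task], dtype=np.float64))
        per_sample = is_pos * l_pos + (1.0 - is_pos) * l_neg
        out[task] = per_sample.mean()
    return out
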