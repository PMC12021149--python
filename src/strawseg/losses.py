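"""The joint training objective: weighted CE + Dice + domain-confusion MMD.

Segmentation is supervised on the synthetic source domain with a mix of
class-weighted cross-entropy and soft Dice loss; domain adaptation follows
the Deep Domain Confusion recipe — a squared maximum-mean-discrepancy (MMD)
penalty between pooled source and target features, weighted by lambda:

    L = (1 - alpha) * CE_w + alpha * Dice + lambda * MMD^2

All terms are autograd-traceable numpy, so the total differentiates through
the network.  MMD uses the biased V-statistic (diagonal included), which is
stable for the small batches of CPU-scale training; the RBF kernel sums over
a bandwidth list, by default the {0.5, 1, 2} multiples of the median pairwise
distance (the classic median heuristic, computed outside the gradient tape).
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from .errors import ConfigurationError

EPS_DICE = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the joint objective.

    ``class_weights`` order is (background, ripe, unripe); the background
    default 0.5 keeps the (rarer) fruit classes dominant.  ``dice_mix`` is
    alpha, ``domain_weight`` is lambda.
    """

    class_weights: tuple[float, float, float] = (0.5, 1.0, 1.0)
    dice_mix: float = 0.5
    domain_weight: float = 0.25
    mmd_kernel: str = "rbf"
    rbf_bandwidths: tuple[float, ...] | None = None  # None -> median heuristic
    bandwidth_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.class_weights) or not any(self.class_weights):
            raise ConfigurationError("class_weights must be >= 0 with at least one > 0")
        if not 0.0 <= self.dice_mix <= 1.0:
            raise ConfigurationError(f"dice_mix {self.dice_mix} outside [0, 1]")
        if self.domain_weight < 0:
            raise ConfigurationError("domain_weight must be >= 0")
        if self.mmd_kernel not in ("linear", "rbf"):
            raise ConfigurationError(f"unknown MMD kernel {self.mmd_kernel!r}")
        if self.rbf_bandwidths is not None and any(b <= 0 for b in self.rbf_bandwidths):
            raise ConfigurationError("rbf_bandwidths must be positive")


def softmax_probs(logits):
    z = logits - anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def log_softmax(logits):
    z = logits - anp.max(logits, axis=-1, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=-1, keepdims=True))


def weighted_cross_entropy(logits, targets, class_weights):
    """Per-pixel NLL weighted by the true class, normalized by the realized
    weight mass: sum_i w_{t_i} * nll_i / sum_i w_{t_i}.

    With equal weights this is the plain mean cross-entropy (uniform logits
    over 3 classes give exactly ln 3).
    """
    targets = np.asarray(targets)
    n_classes = getval(logits).shape[-1]
    if targets.min() < 0 or targets.max() >= n_classes:
        raise ValueError(
            f"targets contain indices outside [0, {n_classes - 1}]")
    onehot = np.eye(n_classes, dtype=np.float32)[targets]
    w = np.asarray(class_weights, dtype=np.float32)[targets]
    logp = log_softmax(logits)
    nll = -anp.sum(onehot * logp, axis=-1)
    return anp.sum(w * nll) / np.sum(w)


def dice_loss(probs, onehot, eps: float = EPS_DICE):
    """1 - mean over classes of soft Dice, pixel sums pooled over the batch:
    dice_c = (2 sum p_c t_c + eps) / (sum p_c + sum t_c + eps)."""
    axes = tuple(range(getval(probs).ndim - 1))
    inter = anp.sum(probs * onehot, axis=axes)
    denom = anp.sum(probs, axis=axes) + anp.sum(onehot, axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - anp.mean(dice)


def median_heuristic_bandwidths(source, target,
                                multipliers=(0.5, 1.0, 2.0)) -> tuple[float, ...]:
    """Multiples of the median pairwise distance over the pooled feature set.

    Computed on detached values — the bandwidth is treated as a constant of
    the kernel, not a differentiable quantity.
    """
    z = np.concatenate([np.asarray(getval(source)), np.asarray(getval(target))])
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
    med = float(np.sqrt(np.median(d2[np.triu_indices_from(d2, k=1)])))
    if not np.isfinite(med) or med <= 0:
        med = 1.0
    return tuple(m * med for m in multipliers)


def _mean_kernel(a, b, kernel, bandwidths):
    if kernel == "linear":
        return anp.mean(anp.matmul(a, anp.transpose(b)))
    d2 = anp.sum(a * a, axis=1)[:, None] + anp.sum(b * b, axis=1)[None, :] \
        - 2.0 * anp.matmul(a, anp.transpose(b))
    d2 = anp.maximum(d2, 0.0)
    total = 0.0
    for sigma in bandwidths:
        total = total + anp.mean(anp.exp(-d2 / (2.0 * sigma ** 2)))
    return total


def mmd_squared(source_features, target_features, kernel: str = "rbf",
                bandwidths=None):
    """Biased V-statistic estimate of squared maximum mean discrepancy.

    mean k(S,S) + mean k(T,T) - 2 mean k(S,T).  The linear kernel reduces to
    the squared distance between domain means (the original Deep Domain
    Confusion formulation); the RBF kernel sums over the bandwidth list.
    """
    s_shape, t_shape = getval(source_features).shape, getval(target_features).shape
    if len(s_shape) != 2 or len(t_shape) != 2 or s_shape[1] != t_shape[1]:
        raise ValueError(f"feature shapes {s_shape} and {t_shape} are incompatible")
    if s_shape[0] < 1 or t_shape[0] < 1:
        raise ValueError("need at least one feature vector per domain")
    if kernel not in ("linear", "rbf"):
        raise ConfigurationError(f"unknown MMD kernel {kernel!r}")
    if kernel == "rbf" and bandwidths is None:
        bandwidths = median_heuristic_bandwidths(source_features, target_features)
    s, t = source_features, target_features
    return (_mean_kernel(s, s, kernel, bandwidths)
            + _mean_kernel(t, t, kernel, bandwidths)
            - 2.0 * _mean_kernel(s, t, kernel, bandwidths))


def joint_loss(logits, targets, src_feats=None, tgt_feats=None,
               weights: LossWeights = LossWeights()):
    """Total objective plus a float breakdown for logging.

    Returns (total, {"ce", "dice", "mmd", "total"}); the breakdown holds
    detached floats, the total stays on the gradient tape.  With
    ``domain_weight`` 0 (or missing features) the MMD term is skipped and
    logged as 0.
    """
    alpha, lam = weights.dice_mix, weights.domain_weight
    ce = weighted_cross_entropy(logits, targets, weights.class_weights)
    onehot = np.eye(getval(logits).shape[-1], dtype=np.float32)[np.asarray(targets)]
    dce = dice_loss(softmax_probs(logits), onehot)
    total = (1.0 - alpha) * ce + alpha * dce
    mmd_val = 0.0
    if lam > 0.0 and src_feats is not None and tgt_feats is not None:
        mmd_val = mmd_squared(src_feats, tgt_feats, weights.mmd_kernel,
                              weights.rbf_bandwidths)
        total = total + lam * mmd_val
    breakdown = {"ce": float(getval(ce)), "dice": float(getval(dce)),
                 "mmd": float(getval(mmd_val)), "total": float(getval(total))}
    return total, breakdown
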