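"""Trilevel domain-adaptation objective.

Three alignment mechanisms act on the pooled encoder embedding g:

1. *Adversarial*: a domain discriminator D(g) is trained to tell the two
   acquisition domains apart (binary cross-entropy), while the encoder
   minimizes a symmetric confusion loss whose unique minimum is at
   predicted domain probability 1/2.  The gradient-reversal formulation
   is available behind a flag and is update-equivalent to the confusion
   loss at the symmetric target.
2. *Contrastive*: temperature-scaled cosine similarities pull
   anatomically paired cross-domain embeddings together (InfoNCE form)
   while pushing unrelated ones apart.
3. *Covariance*: the squared Frobenius distance between the two domains'
   feature covariance matrices aligns second-order statistics.

The combined objective is
``L_DA = lambda_adv * L_adv + lambda_con * L_con + lambda_cov * L_cov``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concatenate
from .model import EPS_LOG, Linear, Module


@dataclass(frozen=True)
class AdaptationWeights:
    """Loss weights; defaults follow the model's standard configuration."""

    lambda_adv: float = 0.5
    lambda_con: float = 1.0
    lambda_cov: float = 0.1
    temperature: float = 0.1
    grl_enabled: bool = False

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("lambda_adv", "lambda_con", "lambda_cov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


class Discriminator(Module):
    """2-layer perceptron C -> C/2 (ReLU) -> 1 (sigmoid)."""

    def __init__(self, in_dim: int, hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = hidden or max(in_dim // 2, 1)
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def __call__(self, g: Tensor) -> Tensor:
        """Predicted probability that g comes from domain 1, in (0, 1)."""
        return self.fc2(self.fc1(g).relu()).sigmoid()


def discriminator_loss(y_hat: Tensor, y_domain: np.ndarray) -> Tensor:
    """Binary cross-entropy of the domain prediction."""
    y = Tensor(np.asarray(y_domain, dtype=np.float64).reshape(y_hat.shape))
    p = y_hat.clip_min(EPS_LOG)
    q = (1.0 - y_hat).clip_min(EPS_LOG)
    per = -(y * p.log() + (1.0 - y) * q.log())
    return per.mean()


def adversarial_confusion_loss(y_hat: Tensor) -> Tensor:
    """L_adv = -1/2 [log yhat + log(1 - yhat)]; minimum ln 2 at yhat = 1/2."""
    p = y_hat.clip_min(EPS_LOG)
    q = (1.0 - y_hat).clip_min(EPS_LOG)
    per = -0.5 * (p.log() + q.log())
    return per.mean()


def _normalize_rows(z: Tensor) -> Tensor:
    norm = (z * z).sum(axis=-1, keepdims=True).sqrt().clip_min(1e-12)
    return z / norm


def similarity(z_i: Tensor, z_j: Tensor, temperature: float) -> Tensor:
    """Temperature-scaled cosine similarity of (defensively normalized) rows."""
    zi, zj = _normalize_rows(z_i), _normalize_rows(z_j)
    return (zi * zj).sum(axis=-1) * (1.0 / temperature)


def contrastive_loss(anchors: Tensor, positives: Tensor,
                     temperature: float = 0.1,
                     symmetric: bool = True) -> Tensor:
    """InfoNCE over cross-domain anatomical pairs.

    Row i of `anchors` is paired with row i of `positives`; all other
    rows of `positives` act as its negatives.  The loss is averaged over
    anchors and, when `symmetric`, over both directions
    (source -> target and target -> source).
    """
    n = anchors.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least one negative pair")

    def one_direction(a: Tensor, p: Tensor) -> Tensor:
        an, pn = _normalize_rows(a), _normalize_rows(p)
        sims = (an @ pn.transpose(1, 0)) * (1.0 / temperature)  # (n, n)
        logprob = sims.log_softmax(axis=-1)                      # log-sum-exp form
        diag = logprob[np.arange(n), np.arange(n)]
        return -diag.mean()

    loss = one_direction(anchors, positives)
    if symmetric:
        loss = 0.5 * (loss + one_direction(positives, anchors))
    return loss


def contrastive_loss_single(anchor: Tensor, positive: Tensor,
                            negatives: Tensor, temperature: float = 0.1) -> Tensor:
    """Single-anchor InfoNCE: -log exp(s+) / (exp(s+) + sum_n exp(s_n))."""
    if negatives.shape[0] < 1:
        raise ValueError("at least one negative is required")
    a = _normalize_rows(anchor.reshape(1, -1))
    p = _normalize_rows(positive.reshape(1, -1))
    ns = _normalize_rows(negatives)
    s_pos = (a * p).sum(axis=-1) * (1.0 / temperature)          # (1,)
    s_neg = (a @ ns.transpose(1, 0)) * (1.0 / temperature)      # (1, n)
    all_s = concatenate([s_pos.reshape(1, 1), s_neg], axis=1)
    return (all_s.log_softmax(axis=-1)[0, 0] * -1.0)


def covariance(features: Tensor) -> Tensor:
    """Unbiased (n-1) sample covariance of an (n, C) feature batch."""
    n = features.shape[0]
    if n < 2:
        raise ValueError("covariance needs at least 2 samples per domain")
    mu = features.mean(axis=0, keepdims=True)
    centered = features - mu
    return (centered.transpose(1, 0) @ centered) * (1.0 / (n - 1))


def covariance_loss(features_src: Tensor, features_tgt: Tensor) -> Tensor:
    """L_cov = || Sigma_src - Sigma_tgt ||_F^2."""
    diff = covariance(features_src) - covariance(features_tgt)
    return (diff * diff).sum()


def combine_domain_losses(l_adv: Tensor | float, l_con: Tensor | float,
                          l_cov: Tensor | float,
                          weights: AdaptationWeights) -> Tensor:
    """L_DA = lambda_adv L_adv + lambda_con L_con + lambda_cov L_cov."""
    def lift(x):
        return x if isinstance(x, Tensor) else Tensor(float(x))
    return (weights.lambda_adv * lift(l_adv)
            + weights.lambda_con * lift(l_con)
            + weights.lambda_cov * lift(l_cov))


def grl_encoder_loss(y_hat: Tensor) -> Tensor:
    """Gradient-reversal path: discriminator BCE against the symmetric target.

    The reversal rule routes the discriminator's objective into the
    encoder with the domain target symmetrized to 1/2; algebraically
    BCE(p, 1/2) = -1/2 [log p + log(1-p)], identical to the explicit
    confusion loss, so both formulations produce equal encoder updates
    at matched weight.  Pinned by an equivalence test.
    """
    half = np.full(tuple(y_hat.shape), 0.5)
    return discriminator_loss(y_hat, half)
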