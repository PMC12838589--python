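"""End-to-end optimization: mixed-domain batching, augmentation, AdamW
with a cosine floor schedule, joint batch statistics, loss assembly,
early stopping and stratified splits.

Training alternates, at every step, (a) a discriminator update on its
binary cross-entropy and (b) a joint update of encoder, classifier and
(optionally) segmentation decoder on

``L_total = L_cls + lambda_seg * L_seg + lambda_DA * L_DA``.

The two players never share gradients: the discriminator step sees a
detached embedding, and the joint step's confusion-loss gradients are
discarded on the discriminator's parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autograd import Tensor
from . import adaptation as da
from .model import DAMLM, classification_loss, dice_loss
from .phantom import _elastic_displacement, _warp


# ------------------------------------------------------------------- splits
@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def stratified_split(labels, spec: SplitSpec):
    """Per-class largest-remainder allocation into (train, val, test).

    Returns three disjoint, exhaustive index arrays; deterministic given
    the spec seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        quotas = [r * n for r in spec.ratios]
        counts = [int(math.floor(q)) for q in quotas]
        rem = n - sum(counts)
        order = sorted(range(3), key=lambda p: (-(quotas[p] - counts[p]), p))
        for p in order[:rem]:
            counts[p] += 1
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start:start + c].tolist())
            start += c
    return tuple(np.array(sorted(p), dtype=int) for p in parts)


# ------------------------------------------------------------------ batching
def make_mixed_batch(source_pool, target_pool, batch_size: int,
                     rng: np.random.Generator):
    """One half-half mixed batch sampled without replacement."""
    if batch_size % 2:
        raise ValueError("batch_size must be even for half-half mixing")
    half = batch_size // 2
    if len(source_pool) < half or len(target_pool) < half:
        raise ValueError("pools too small for one mixed batch")
    src = rng.choice(len(source_pool), size=half, replace=False)
    tgt = rng.choice(len(target_pool), size=half, replace=False)
    return [source_pool[i] for i in src], [target_pool[j] for j in tgt]


def epoch_pair_batches(n_pairs: int, batch_size: int, rng: np.random.Generator):
    """Shuffle anatomy-pair ids and yield batches of batch_size/2 pairs.

    Each pair contributes its source and target rendering, so every
    batch is exactly half-half mixed and carries its own cross-domain
    positives for the contrastive term.
    """
    if batch_size % 2:
        raise ValueError("batch_size must be even for half-half mixing")
    half = batch_size // 2
    order = rng.permutation(n_pairs)
    for start in range(0, n_pairs - half + 1, half):
        yield order[start:start + half]


# -------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class AugmentConfig:
    elastic: bool = True
    intensity: bool = True
    rotation: bool = True
    patch_dropout: bool = True
    intensity_bound: float = 0.10    # |scale - 1| <= 0.10
    rotation_bound_deg: float = 15.0
    elastic_max_disp: float = 1.0
    apply_prob: float = 0.5

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(elastic=False, intensity=False, rotation=False, patch_dropout=False)


def augment(patch: np.ndarray, region_mask: np.ndarray | None,
            cfg: AugmentConfig, rng: np.random.Generator):
    """Stochastic augmentation of a (4, h, w, d) patch.

    Each enabled operator fires independently with probability
    `apply_prob`; geometric operators co-transform the region mask.
    Identity when all toggles are off.
    """
    x = patch.copy()
    m = None if region_mask is None else region_mask.copy()
    if cfg.intensity and rng.random() < cfg.apply_prob:
        scale = 1.0 + rng.uniform(-cfg.intensity_bound, cfg.intensity_bound)
        x *= scale
    if cfg.rotation and rng.random() < cfg.apply_prob:
        angle = rng.uniform(-cfg.rotation_bound_deg, cfg.rotation_bound_deg)
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
        x = np.stack([ndimage.rotate(ch, angle, axes=axes, reshape=False,
                                     order=1, mode="nearest") for ch in x])
        if m is not None:
            m = ndimage.rotate(m, angle, axes=axes, reshape=False, order=0,
                               mode="nearest")
    if cfg.elastic and rng.random() < cfg.apply_prob:
        disp = _elastic_displacement(x.shape[1:], cfg.elastic_max_disp, rng)
        x = np.stack([_warp(ch, disp, order=1) for ch in x])
        if m is not None:
            m = _warp(m, disp, order=0).astype(m.dtype)
    if cfg.patch_dropout and rng.random() < cfg.apply_prob:
        lo, hi = [], []
        for s in x.shape[1:]:
            L = int(rng.integers(1, max(s // 3, 2)))
            a = int(rng.integers(0, s - L + 1))
            lo.append(a)
            hi.append(a + L)
        x[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 0.0
    return x, m


# ----------------------------------------------------------------- schedule
def cosine_lr(t: int, total_steps: int, eta0: float, eta_min: float) -> float:
    """eta(t) = eta_min + 1/2 (eta0 - eta_min)(1 + cos(pi t / T))."""
    if not 0 <= t <= total_steps:
        raise ValueError("step outside schedule range")
    return eta_min + 0.5 * (eta0 - eta_min) * (1.0 + math.cos(math.pi * t / total_steps))


# ---------------------------------------------------------------- optimizer
def adamw_step(theta: np.ndarray, grad: np.ndarray, m: np.ndarray, v: np.ndarray,
               t: int, lr: float, beta1: float = 0.9, beta2: float = 0.999,
               eps: float = 1e-8, weight_decay: float = 0.0):
    """One bias-corrected, decoupled-decay AdamW update.

    theta <- theta - lr * m_hat / (sqrt(v_hat) + eps) - lr * wd * theta.
    Returns the new (theta, m, v); `t` is the 1-based step count.
    """
    m = beta1 * m + (1 - beta1) * grad
    v = beta2 * v + (1 - beta2) * grad * grad
    m_hat = m / (1 - beta1**t)
    v_hat = v / (1 - beta2**t)
    theta = theta - lr * m_hat / (np.sqrt(v_hat) + eps) - lr * weight_decay * theta
    return theta, m, v


class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.beta1, self.beta2, self.eps, self.wd = beta1, beta2, eps, weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            p.data, self.m[k], self.v[k] = adamw_step(
                p.data, p.grad, self.m[k], self.v[k], self.t, lr,
                self.beta1, self.beta2, self.eps, self.wd)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def joint_batch_stats(activations: np.ndarray):
    """Mean/variance pooled over the full mixed batch (never per-domain).

    `activations` is (B, C) or (B, C, *spatial); statistics are computed
    per channel over every other axis with ddof=0.
    """
    a = np.asarray(activations, dtype=np.float64)
    axes = (0,) + tuple(range(2, a.ndim))
    mu = a.mean(axis=axes)
    var = a.var(axis=axes)
    return mu, var


# -------------------------------------------------------------------- losses
def total_loss(l_cls: Tensor | float, l_seg: Tensor | float | None,
               l_da: Tensor | float, lambda_da: float = 1.0,
               lambda_seg: float = 1.0) -> Tensor:
    """L_total = L_cls + lambda_seg L_seg + lambda_DA L_DA.

    With the segmentation head disabled (`l_seg is None`) the term is
    absent entirely.
    """
    def lift(x):
        return x if isinstance(x, Tensor) else Tensor(float(x))
    out = lift(l_cls) + lambda_da * lift(l_da)
    if l_seg is not None:
        out = out + lambda_seg * lift(l_seg)
    return out


def combined_val_score(alpha_src: float, alpha_tgt: float, gamma: float = 0.5) -> float:
    """alpha_val = gamma * alpha_src + (1 - gamma) * alpha_tgt."""
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma * alpha_src + (1 - gamma) * alpha_tgt


# -------------------------------------------------------------------- config
@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 200
    eta0: float = 3e-4
    eta_min: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    lambda_da: float = 1.0
    lambda_seg: float = 1.0
    adaptation: da.AdaptationWeights = field(default_factory=da.AdaptationWeights)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    patience: int = 20
    gamma: float = 0.5
    seed: int = 0
    supervised_domains: str = "both"   # "both" | "source"
    grad_clip_norm: float | None = None  # off by default


# --------------------------------------------------------------- data access
@dataclass
class Sample:
    """One training item: a preprocessed patch plus its labels."""

    x: np.ndarray                 # (4, h, w, d)
    y: int
    domain: int
    regions: np.ndarray | None = None
    pair_id: int | None = None


@dataclass
class DomainDataSplits:
    """Per-domain train/val/test sample lists with a shared pairing."""

    train_src: list[Sample]
    train_tgt: list[Sample]
    val_src: list[Sample]
    val_tgt: list[Sample]
    test_src: list[Sample]
    test_tgt: list[Sample]


def _onehot(ys, k: int) -> np.ndarray:
    out = np.zeros((len(ys), k))
    out[np.arange(len(ys)), ys] = 1.0
    return out


def predict_probs(model: DAMLM, samples: list[Sample], batch: int = 32) -> np.ndarray:
    """Class probabilities per sample, eval mode (running BN statistics)."""
    model.set_training(False)
    outs = []
    for start in range(0, len(samples), batch):
        xs = np.stack([s.x for s in samples[start:start + batch]])
        outs.append(model(Tensor(xs), segment=False)["probs"].data)
    model.set_training(True)
    return np.concatenate(outs, axis=0)


def accuracy(model: DAMLM, samples: list[Sample]) -> float:
    if not samples:
        return float("nan")
    probs = predict_probs(model, samples)
    pred = probs.argmax(axis=1)
    return float(np.mean(pred == np.array([s.y for s in samples])))


# ----------------------------------------------------------------- training
def train(model: DAMLM, splits: DomainDataSplits, config: TrainConfig,
          val_score_override=None):
    """Optimize the model on two-domain data; returns (model, history).

    Per step: (a) discriminator update on detached embeddings, (b) joint
    update on the total loss with frozen discriminator parameters.
    Early-stops when the combined validation score fails to improve for
    `config.patience` epochs, restoring the best parameters.
    `val_score_override(epoch)` replaces the measured score (used only
    by contract tests of the early-stopping rule).
    """
    if not splits.train_src or not splits.train_tgt:
        raise ValueError("both domain pools must be nonempty")
    rng = np.random.default_rng(config.seed)
    weights = config.adaptation
    k = model.cfg.class_count
    disc = da.Discriminator(model.cfg.encoder.channels,
                            seed=config.seed + 7919)
    enc_params = model.named_parameters()
    disc_params = disc.named_parameters("disc.")
    opt = AdamW(enc_params, config.beta1, config.beta2, 1e-8, config.weight_decay)
    opt_d = AdamW(disc_params, config.beta1, config.beta2, 1e-8, config.weight_decay)

    # align pairs: index i in train_src pairs with index i in train_tgt
    n_pairs = min(len(splits.train_src), len(splits.train_tgt))
    half = config.batch_size // 2
    steps_per_epoch = max(n_pairs // half, 1)
    total_steps = config.epochs * steps_per_epoch
    segment = model.decoder is not None and config.lambda_seg > 0

    history: list[dict] = []
    step_log: list[dict] = []  # per-step loss bundle (JSON-serializable)
    best = (-np.inf, -1, None)  # score, epoch, params snapshot
    step = 0
    stale = 0
    for epoch in range(config.epochs):
        model.set_training(True)
        sums: dict[str, float] = {}
        nb = 0
        for batch_pairs in epoch_pair_batches(n_pairs, config.batch_size, rng):
            src = [splits.train_src[i] for i in batch_pairs]
            tgt = [splits.train_tgt[i] for i in batch_pairs]
            batch = src + tgt
            xs, regions = [], []
            for s in batch:
                x, m = augment(s.x, s.regions, config.augmentation, rng)
                xs.append(x)
                regions.append(m)
            x_t = Tensor(np.stack(xs))
            y_dom = np.array([s.domain for s in batch], dtype=float).reshape(-1, 1)
            lr = cosine_lr(step, total_steps, config.eta0, config.eta_min)

            out = model(x_t, segment=segment)
            g = out["pooled"]

            # (a) discriminator step on detached embeddings
            opt_d.zero_grad()
            d_hat = disc(g.detach())
            l_disc = da.discriminator_loss(d_hat, y_dom)
            l_disc.backward()
            opt_d.step(lr)

            # (b) joint step; discriminator frozen
            opt.zero_grad()
            if config.supervised_domains == "source":
                sup = slice(0, half)
            else:
                sup = slice(0, len(batch))
            probs_sup = out["probs"][sup]
            y_onehot = _onehot([s.y for s in batch[sup]], k)
            l_cls = classification_loss(probs_sup, y_onehot)
            l_seg = None
            if segment:
                seg_terms = []
                for i, m in enumerate(regions):
                    if m is not None:
                        seg_terms.append(dice_loss(out["seg_probs"][i:i + 1], m[None]))
                if seg_terms:
                    l_seg = seg_terms[0]
                    for t_ in seg_terms[1:]:
                        l_seg = l_seg + t_
                    l_seg = l_seg * (1.0 / len(seg_terms))
            if weights.grl_enabled:
                l_adv = da.grl_encoder_loss(disc(g))
            else:
                l_adv = da.adversarial_confusion_loss(disc(g))
            g_src, g_tgt = g[0:half], g[half:2 * half]
            l_con = da.contrastive_loss(g_src, g_tgt, weights.temperature)
            l_cov = da.covariance_loss(g_src, g_tgt)
            l_da = da.combine_domain_losses(l_adv, l_con, l_cov, weights)
            l_total = total_loss(l_cls, l_seg, l_da, config.lambda_da,
                                 config.lambda_seg)
            l_total.backward()
            for p in disc_params.values():   # confusion-loss grads never update D
                p.zero_grad()
            if config.grad_clip_norm is not None:
                _clip_grads(enc_params, config.grad_clip_norm)
            opt.step(lr)

            bundle = {"step": step, "lr": lr,
                      "lambda_adv": weights.lambda_adv,
                      "lambda_con": weights.lambda_con,
                      "lambda_cov": weights.lambda_cov,
                      "lambda_DA": config.lambda_da}
            for name, val in (("L_total", l_total), ("L_cls", l_cls),
                              ("L_disc", l_disc), ("L_adv", l_adv),
                              ("L_con", l_con), ("L_cov", l_cov), ("L_DA", l_da)):
                sums[name] = sums.get(name, 0.0) + float(val.item())
                bundle[name] = float(val.item())
            step_log.append(bundle)
            if l_seg is not None:
                sums["L_seg"] = sums.get("L_seg", 0.0) + float(l_seg.item())
            sums["lr"] = sums.get("lr", 0.0) + lr
            nb += 1
            step += 1
            if not np.all(np.isfinite(l_total.data)):
                raise FloatingPointError("non-finite loss")

        alpha_src = accuracy(model, splits.val_src)
        alpha_tgt = accuracy(model, splits.val_tgt)
        if val_score_override is not None:
            alpha_val = float(val_score_override(epoch))
        else:
            alpha_val = combined_val_score(alpha_src, alpha_tgt, config.gamma)
        record = {k_: v / max(nb, 1) for k_, v in sums.items()}
        record.update(epoch=epoch, alpha_src=alpha_src, alpha_tgt=alpha_tgt,
                      alpha_val=alpha_val)
        history.append(record)

        if alpha_val > best[0]:
            best = (alpha_val, epoch,
                    {k_: p.data.copy() for k_, p in enc_params.items()})
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best[2] is not None:
        for k_, p in enc_params.items():
            p.data[...] = best[2][k_]
    model.set_training(False)
    return model, {"epochs": history, "steps": step_log,
                   "best_epoch": best[1], "discriminator": disc}


def _clip_grads(params: dict[str, Tensor], max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad**2).sum())
                          for p in params.values() if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
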