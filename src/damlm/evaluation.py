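"""Measurement machinery: classification metrics, region overlap scores,
cross-domain transfer evaluation, perturbation robustness (R_deg),
scanner-shift displacement (D_shift), multi-seed stability intervals,
paired t-tests and the ablation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .phantom import (PerturbationSpec, ScannerProfile, SEVERITIES,
                      apply_perturbation, apply_scanner_profile)

# region nesting convention: WT = edema+core+enhancing, TC = core+enhancing,
# ET = enhancing (codes 1, 2, 3 in the region masks)
REGION_SETS = {"WT": (1, 2, 3), "TC": (2, 3), "ET": (3,)}


# ------------------------------------------------------------------- metrics
@dataclass
class MetricReport:
    acc: float
    f1_macro: float
    auc_per_class: dict[int, float]
    auc_macro: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n: int

    def as_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "auc_per_class"}
        d.update({f"auc_{k}": v for k, v in self.auc_per_class.items()})
        return d


def classification_metrics(y_true, y_pred, scores) -> MetricReport:
    """Accuracy, macro-F1, one-vs-rest ROC-AUC, macro sensitivity /
    specificity and balanced accuracy.

    `scores` holds per-class probabilities (n, K).  Per-class precision
    or recall with an empty denominator counts as 0 (so F1 of an absent
    class is 0); binary sensitivity/specificity generalize to K > 2 by
    macro one-vs-rest averaging.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    n = y_true.size
    classes = list(range(scores.shape[1]))

    acc = float(np.mean(y_true == y_pred))

    f1s, senss, specs = [], [], []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        senss.append(rec if (tp + fn) else 0.0)
        specs.append(tn / (tn + fp) if tn + fp else 0.0)

    aucs: dict[int, float] = {}
    for c in classes:
        mask_pos = y_true == c
        if mask_pos.all() or not mask_pos.any():
            aucs[c] = float("nan")
        else:
            aucs[c] = float(roc_auc_score(mask_pos.astype(int), scores[:, c]))
    finite = [v for v in aucs.values() if np.isfinite(v)]
    auc_macro = float(np.mean(finite)) if finite else float("nan")

    sens = float(np.mean(senss))
    spec = float(np.mean(specs))
    if len(classes) == 2:
        # binary convention: class 1 positive
        sens = senss[1]
        spec = specs[1]
    return MetricReport(acc=acc, f1_macro=float(np.mean(f1s)),
                        auc_per_class=aucs, auc_macro=auc_macro,
                        sensitivity=sens, specificity=spec,
                        balanced_accuracy=0.5 * (sens + spec), n=n)


def region_dice_jaccard(pred_mask, true_mask) -> dict[str, dict[str, float]]:
    """Dice and Jaccard for the nested WT / TC / ET tumor regions.

    Empty-vs-empty regions score 1 by convention.
    """
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    out = {}
    for name, codes in REGION_SETS.items():
        p = np.isin(pred_mask, codes)
        g = np.isin(true_mask, codes)
        inter = float(np.sum(p & g))
        union = float(np.sum(p | g))
        tot = float(p.sum() + g.sum())
        if tot == 0:
            dice = jacc = 1.0
        else:
            dice = 2 * inter / tot
            jacc = inter / union if union else 1.0
        out[name] = {"dice": dice, "jaccard": jacc}
    return out


# ------------------------------------------------------------- cross-domain
def cross_domain_eval(model, target_samples, class_count: int):
    """Evaluate a trained model on a held-out (possibly other-domain) set.

    Returns (MetricReport, mean cross-entropy loss per sample) without
    any fine-tuning.
    """
    from .trainer import predict_probs

    probs = predict_probs(model, target_samples)
    y = np.array([s.y for s in target_samples])
    pred = probs.argmax(axis=1)
    eps = 1e-12
    mean_ce = float(np.mean(-np.log(np.maximum(probs[np.arange(len(y)), y], eps))))
    return classification_metrics(y, pred, probs), mean_ce


# --------------------------------------------------------------- robustness
@dataclass
class RobustnessReport:
    metric_name: str
    baseline: float
    r_deg: dict[tuple[str, str], float | None]
    d_shift: dict[str, float]


def robustness_degradation(metric_fn, eval_volumes, kinds=None, seed: int = 0,
                           metric_name: str = "accuracy") -> RobustnessReport:
    """R_deg(kind, severity) = 1 - M(perturbed) / M(baseline).

    `metric_fn(volumes) -> float` evaluates the model-side metric; the
    same perturbation seed is shared across severities of a kind so
    severities differ only in their parameter.  A baseline of 0 makes
    the ratio undefined and is reported as None with a warning.
    """
    from .phantom import SEVERITY_PARAMS

    kinds = kinds or list(SEVERITY_PARAMS)
    baseline = float(metric_fn(eval_volumes))
    r: dict[tuple[str, str], float | None] = {}
    for kind in kinds:
        for sev in SEVERITIES:
            pert = PerturbationSpec(kind=kind, severity=sev)
            pv = [apply_perturbation(v, pert, seed=seed + i)
                  for i, v in enumerate(eval_volumes)]
            m = float(metric_fn(pv))
            if baseline == 0:
                warnings.warn("baseline metric is 0; R_deg undefined")
                r[(kind, sev)] = None
            else:
                r[(kind, sev)] = 1.0 - m / baseline
    return RobustnessReport(metric_name=metric_name, baseline=baseline,
                            r_deg=r, d_shift={})


def scanner_shift_eval(metric_fn, eval_volumes, profiles=None,
                       seed: int = 0) -> dict[str, float]:
    """D_shift(S_k) = M_orig - M_{S_k} on the metric's native scale."""
    if profiles is None:
        profiles = [ScannerProfile(p) for p in
                    ("low_field", "bias_field", "coil_scaling",
                     "high_noise_low_contrast")]
    m_orig = float(metric_fn(eval_volumes))
    out = {}
    for prof in profiles:
        pv = [apply_scanner_profile(v, prof, seed=seed + i)
              for i, v in enumerate(eval_volumes)]
        out[prof.profile_id] = m_orig - float(metric_fn(pv))
    return out


# ---------------------------------------------------------------- stability
@dataclass
class StabilityReport:
    mean: float
    std: float
    ci95_halfwidth: float
    n_runs: int


def stability_ci(values, z: float = 1.96) -> StabilityReport:
    """CI95 = mean +- 1.96 sigma / sqrt(n) over seeded repeat runs (ddof=1)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 runs")
    std = float(v.std(ddof=1))
    return StabilityReport(mean=float(v.mean()), std=std,
                           ci95_halfwidth=z * std / np.sqrt(n), n_runs=n)


def paired_t_test(runs_a, runs_b, alpha: float = 0.05):
    """Two-tailed paired t-test on per-seed metric differences.

    Degenerate conventions: all-zero differences give (t=0, p=1);
    zero-variance nonzero differences give p=0 with a warning.
    Returns (t, p, significant_flag).
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("runs must be paired with n >= 2")
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0, False
    if np.isclose(d.std(ddof=1), 0):
        warnings.warn("zero-variance nonzero differences; p -> 0 limit")
        return float(np.sign(d.mean()) * np.inf), 0.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


# ------------------------------------------------------------------ ablation
ABLATIONS = ("cnn_only", "transformer_only", "no_adv", "no_con", "no_cov")


def ablation_harness(run_fn, components=ABLATIONS, seeds=(0, 1, 2, 3, 4),
                     metric: str = "acc") -> pd.DataFrame:
    """Run the full configuration plus each ablation across seeds.

    `run_fn(component, seed) -> dict of metric values`, where component
    "full" denotes the unablated model.  Emits a mean +- std table with
    a paired t-test against the full configuration per ablation row.
    """
    rows = []
    per_run: dict[str, list[float]] = {}
    for comp in ("full",) + tuple(components):
        vals = [run_fn(comp, s) for s in seeds]
        per_run[comp] = [v[metric] for v in vals]
        keys = vals[0].keys()
        row = {"variant": comp}
        for k in keys:
            arr = np.array([v[k] for v in vals], dtype=float)
            row[k] = arr.mean()
            row[f"{k}_std"] = arr.std(ddof=1) if len(arr) > 1 else 0.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("variant")
    pvals = {}
    for comp in components:
        if len(seeds) >= 2:
            _, p, _ = paired_t_test(per_run["full"], per_run[comp])
        else:
            p = float("nan")
        pvals[comp] = p
    df["p_vs_full"] = [pvals.get(v, float("nan")) for v in df.index]
    return df
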