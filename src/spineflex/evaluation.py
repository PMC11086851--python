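"""Model evaluation: metrics, 5-fold CV, subset search, ablation, significance.

Metrics follow the usual confusion-matrix definitions with MI as the
positive class:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)          (MI detection rate)
    specificity = TN / (TN + FP)          (MCI detection rate)
    F1          = 2·precision·recall / (precision + recall)

Cross-validation is stratified k-fold; held-out predictions from all folds
are pooled into a single confusion matrix before metrics are computed, so
every record is tested exactly once and the counts sum to n.

The assessment protocol has three stages: (1) baselines with all features
of each family; (2) exhaustive evaluation of every feature subset within a
family (2⁹ = 512 kinematic subsets, 2⁷ = 128 PROMs subsets, the empty set
included as a majority-class predictor); (3) ablation of the chosen mask,
one feature at a time.

Whether an accuracy beats chance is judged against the binomial null of
Combrisson & Jerbi (2015): with n samples and c equiprobable classes the
significance threshold is St(α) = binoinv(1−α, n, 1/c) · 100 / n.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom
from sklearn.model_selection import StratifiedKFold

from .classifier import ModelConfig, predict, train
from .proms import N_PROM_FEATURES, PROM_FEATURE_NAMES
from .repetitions import ANGLE_FEATURE_NAMES, N_ANGLE_FEATURES

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with MI as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    """Accuracy/sensitivity/specificity as percentages, F1 in [0, 1].

    A metric whose denominator is zero is ``None`` (undefined), never
    silently 0. Values are unrounded; :meth:`rounded` applies the 2-decimal
    (percentages) and 3-decimal (F1) reporting convention.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def rounded(self) -> dict[str, float | None]:
        return {
            "accuracy": None if self.accuracy is None else round(self.accuracy, 2),
            "sensitivity": None if self.sensitivity is None else round(self.sensitivity, 2),
            "specificity": None if self.specificity is None else round(self.specificity, 2),
            "f1": None if self.f1 is None else round(self.f1, 3),
        }


def compute_metrics(cm: ConfusionMatrix) -> EvalMetrics:
    """Accuracy, sensitivity, specificity (percent) and F1 from counts."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.n
    accuracy = 100.0 * (tp + tn) / n if n else None
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else None
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else None
    if (tp + fp) and (tp + fn):
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall)
            else 0.0
        )
    else:
        f1 = None
    return EvalMetrics(accuracy, sensitivity, specificity, f1)


@dataclass
class CVResult:
    """Pooled-prediction outcome of one stratified k-fold evaluation."""

    cm: ConfusionMatrix
    metrics: EvalMetrics
    y_true: np.ndarray
    y_pred: np.ndarray
    probs: np.ndarray
    fold_of_record: np.ndarray


def _pool_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def kfold_cv(
    angle_X: np.ndarray | None,
    proms_X: np.ndarray | None,
    y: np.ndarray,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled held-out predictions."""
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
    y_pred = np.empty(n, dtype=int)
    probs = np.empty(n, dtype=float)
    fold_of = np.empty(n, dtype=int)
    dummy = np.zeros(n)  # StratifiedKFold splits on labels only
    for fold, (tr_idx, te_idx) in enumerate(skf.split(dummy, y)):
        params = train(
            None if angle_X is None else angle_X[tr_idx],
            None if proms_X is None else proms_X[tr_idx],
            y[tr_idx],
            config,
        )
        p, lab = predict(
            params,
            None if angle_X is None else angle_X[te_idx],
            None if proms_X is None else proms_X[te_idx],
        )
        probs[te_idx] = p
        y_pred[te_idx] = lab
        fold_of[te_idx] = fold
    cm = _pool_confusion(y, y_pred)
    return CVResult(cm, compute_metrics(cm), y, y_pred, probs, fold_of)


def _domain_config(config: ModelConfig, domain: str) -> ModelConfig:
    full_angle = (True,) * N_ANGLE_FEATURES
    full_proms = (True,) * N_PROM_FEATURES
    off_angle = (False,) * N_ANGLE_FEATURES
    off_proms = (False,) * N_PROM_FEATURES
    if domain == "angle":
        return replace(config, angle_mask=full_angle, proms_mask=off_proms)
    if domain == "proms":
        return replace(config, angle_mask=off_angle, proms_mask=full_proms)
    if domain == "both":
        return replace(config, angle_mask=full_angle, proms_mask=full_proms)
    raise ValueError(f"domain must be 'angle', 'proms' or 'both', got {domain!r}")


def baseline_eval(
    angle_X: np.ndarray,
    proms_X: np.ndarray,
    y: np.ndarray,
    domain: str,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stage-1 baseline: all features of one family (or both) under k-fold CV."""
    config = _domain_config(config or ModelConfig(), domain)
    return kfold_cv(angle_X, proms_X, y, config, k=k, seed=seed)


@dataclass
class SubsetResult:
    """Evaluation of one feature-subset mask within a family."""

    domain: str
    mask: tuple[bool, ...]
    mask_int: int
    n_features: int
    cm: ConfusionMatrix
    metrics: EvalMetrics


def _majority_cm(y: np.ndarray) -> ConfusionMatrix:
    """Confusion matrix of the constant majority-class predictor."""
    y = np.asarray(y).astype(int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos >= n_neg:  # predict MI everywhere
        return ConfusionMatrix(tp=n_pos, fn=0, fp=n_neg, tn=0)
    return ConfusionMatrix(tp=0, fn=n_pos, fp=0, tn=n_neg)


def subset_seed(base_seed: int, mask_int: int) -> int:
    """Deterministic per-subset seed derived from the mask bits (< 2³¹)."""
    return (base_seed * 1_000_003 + mask_int) % _SEED_MOD


def subset_search(
    angle_X: np.ndarray,
    proms_X: np.ndarray,
    y: np.ndarray,
    domain: str,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[SubsetResult]:
    """Exhaustively evaluate every feature subset of one family under k-fold CV.

    All 2^d subsets are enumerated (512 for the 9 kinematic features, 128
    for the 7 PROMs). The empty subset is recorded as a constant
    majority-class predictor, never trained. Results are ranked by F1, ties
    broken by accuracy, then by fewer features; the first element is the
    optimal subset. Per-subset seeds are derived from the mask so the
    ranking does not depend on evaluation order.
    """
    if domain == "angle":
        d = N_ANGLE_FEATURES
    elif domain == "proms":
        d = N_PROM_FEATURES
    else:
        raise ValueError(f"domain must be 'angle' or 'proms', got {domain!r}")
    base = config or ModelConfig()
    results: list[SubsetResult] = []
    for mask_int in range(2**d):
        mask = tuple(bool(mask_int >> i & 1) for i in range(d))
        n_feat = sum(mask)
        if n_feat == 0:
            cm = _majority_cm(y)
            results.append(
                SubsetResult(domain, mask, mask_int, 0, cm, compute_metrics(cm))
            )
            continue
        if domain == "angle":
            cfg = replace(base, angle_mask=mask, proms_mask=(False,) * N_PROM_FEATURES)
        else:
            cfg = replace(base, angle_mask=(False,) * N_ANGLE_FEATURES, proms_mask=mask)
        s = subset_seed(seed, mask_int)
        cfg = replace(cfg, seed=s)
        res = kfold_cv(angle_X, proms_X, y, cfg, k=k, seed=s)
        results.append(SubsetResult(domain, mask, mask_int, n_feat, res.cm, res.metrics))

    def rank_key(r: SubsetResult):
        f1 = r.metrics.f1 if r.metrics.f1 is not None else -1.0
        acc = r.metrics.accuracy if r.metrics.accuracy is not None else -1.0
        return (-f1, -acc, r.n_features, r.mask_int)

    results.sort(key=rank_key)
    return results


def ablation(
    angle_X: np.ndarray,
    proms_X: np.ndarray,
    y: np.ndarray,
    angle_mask: tuple[bool, ...],
    proms_mask: tuple[bool, ...],
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Accuracy drop from removing each active feature of the final mask.

    Returns ``feature name -> accuracy(mask) − accuracy(mask without the
    feature)`` in percentage points; positive deltas mean the feature helped.
    """
    base = replace(config or ModelConfig(), angle_mask=tuple(angle_mask),
                   proms_mask=tuple(proms_mask))
    active = [("angle", i) for i, on in enumerate(angle_mask) if on] + [
        ("proms", i) for i, on in enumerate(proms_mask) if on
    ]
    if len(active) < 2:
        raise ValueError("ablation needs a mask with >= 2 active features")
    full_acc = kfold_cv(angle_X, proms_X, y, base, k=k, seed=seed).metrics.accuracy
    deltas: dict[str, float] = {}
    for family, i in active:
        if family == "angle":
            m = list(base.angle_mask)
            m[i] = False
            cfg = replace(base, angle_mask=tuple(m))
            name = ANGLE_FEATURE_NAMES[i]
        else:
            m = list(base.proms_mask)
            m[i] = False
            cfg = replace(base, proms_mask=tuple(m))
            name = PROM_FEATURE_NAMES[i]
        acc = kfold_cv(angle_X, proms_X, y, cfg, k=k, seed=seed).metrics.accuracy
        deltas[name] = float(full_acc - acc)
    return deltas


@dataclass(frozen=True)
class SignificanceSpec:
    """Binomial chance-level significance threshold for a decoding accuracy."""

    n: int
    c: int
    alpha: float
    z: int  # minimal correct count reaching significance
    threshold_pct: float  # St(α) = z · 100 / n
    exceedance_prob: float  # P(at least z correct by chance)


def chance_threshold(n: int, c: int, alpha: float) -> SignificanceSpec:
    """Minimum accuracy (percent) significantly above chance at level α.

    St(α) = binoinv(1−α, n, 1/c) × 100/n, where binoinv is the binomial
    quantile with n trials and success probability 1/c. Also exposes the
    exceedance probability P(z) of reaching z or more correct by chance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if c < 2:
        raise ValueError("c must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    z = int(binom.ppf(1.0 - alpha, n, 1.0 / c))
    return SignificanceSpec(
        n=n,
        c=c,
        alpha=alpha,
        z=z,
        threshold_pct=100.0 * z / n,
        exceedance_prob=float(binom.sf(z - 1, n, 1.0 / c)),
    )


@dataclass
class ConfusionMatrixSolution:
    """All integer confusion matrices consistent with printed metrics."""

    n: int
    target: tuple[float, float, float]  # accuracy, sensitivity, specificity (%)
    solutions: list[ConfusionMatrix]

    @property
    def consistent(self) -> bool:
        return len(self.solutions) > 0

    @property
    def unique(self) -> bool:
        return len(self.solutions) == 1

    @property
    def matrix(self) -> ConfusionMatrix:
        if not self.solutions:
            raise ValueError(
                f"no integer confusion matrix at n={self.n} reproduces "
                f"accuracy/sensitivity/specificity {self.target} to 2 decimals"
            )
        return self.solutions[0]


def solve_confusion_matrix(
    n: int, accuracy_pct: float, sensitivity_pct: float, specificity_pct: float
) -> ConfusionMatrixSolution:
    """Reconstruct integer TP/FN/FP/TN from printed rounded percentages.

    Enumerates every split of n into (tp, fn, fp, tn) and keeps those whose
    accuracy, sensitivity and specificity round (2 dp) to the given values.
    The result flags inconsistency (no solution) and non-uniqueness.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tol = 0.005 + 1e-9  # half of the last printed decimal

    def match(value: float, target: float) -> bool:
        return abs(value - target) < tol

    sols: list[ConfusionMatrix] = []
    for pos in range(n + 1):  # pos = tp + fn
        neg = n - pos
        if pos == 0 or neg == 0:
            continue  # printed sensitivity and specificity require both classes
        sens_ok = [
            tp for tp in range(pos + 1) if match(100.0 * tp / pos, sensitivity_pct)
        ]
        if not sens_ok:
            continue
        spec_ok = [
            tn for tn in range(neg + 1) if match(100.0 * tn / neg, specificity_pct)
        ]
        for tp in sens_ok:
            for tn in spec_ok:
                if match(100.0 * (tp + tn) / n, accuracy_pct):
                    sols.append(
                        ConfusionMatrix(tp=tp, fn=pos - tp, fp=neg - tn, tn=tn)
                    )
    return ConfusionMatrixSolution(
        n=n, target=(accuracy_pct, sensitivity_pct, specificity_pct), solutions=sols
    )
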