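"""Classification metrics, ROC/AUC and cross-validation protocols.

At the fixed decision threshold of 0.5 (strict: a probability of exactly
0.5 is negative) the confusion counts give

    Acc  = (TN + TP) / (TN + TP + FN + FP)
    Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)

Any metric with a zero denominator is flagged undefined (None), never
silently zeroed, and undefined folds are excluded from that metric's
mean with a warning. AUC is threshold-free and equals the Mann-Whitney
concordance probability (ties counted one half).

Two protocols are provided: stratified 5-fold cross-validation within a
single dataset, and a cross-dataset protocol that trains on one dataset
and tests on another over several independently seeded repeats. 95%
confidence half-widths use the normal approximation 1.96*SD/sqrt(n) over
fold (or repeat) values, with the raw per-fold values retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from acescreen.datasets import LabeledDataset
from acescreen.models import ModelConfig, fit, predict_proba
from acescreen.pseaac import PropertyTable, PseAACParams, encode_batch

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "sens", "spec", "prec", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """Metric values in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    acc: Optional[float] = None
    sens: Optional[float] = None
    spec: Optional[float] = None
    prec: Optional[float] = None
    auc: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class EvalReport:
    """Per-fold metrics with their mean and 95% CI half-widths."""

    protocol: str
    per_fold: list[MetricSet]
    mean: MetricSet
    ci95: dict[str, Optional[float]]
    seeds: list[int]
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    notes: dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        return {
            "protocol": self.protocol,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean.as_dict(),
            "ci95": dict(self.ci95),
            "seeds": list(self.seeds),
            "roc_points": [list(p) for p in self.roc_points],
            "notes": dict(self.notes),
        }


def confusion(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Count TP/TN/FP/FN at a probability threshold (predict positive iff p > t)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(f"labels {y.shape} and probabilities {p.shape} must be parallel 1-D vectors")
    if y.size == 0:
        raise ValueError("empty input vectors")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p > threshold  # strict: p == threshold is a negative call
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and precision from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero instances")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return MetricSet(
        acc=(counts.TN + counts.TP) / counts.total,
        sens=ratio(counts.TP, counts.TP + counts.FN),
        spec=ratio(counts.TN, counts.TN + counts.FP),
        prec=ratio(counts.TP, counts.TP + counts.FP),
    )


def roc_auc(
    labels: Sequence[int],
    probabilities: Sequence[float],
) -> tuple[float, list[tuple[float, float]]]:
    """AUC plus ROC points (FPR, TPR) traversing thresholds high to low."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, _ = roc_curve(y, p)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def _summarize(per_fold: list[MetricSet]) -> tuple[MetricSet, dict[str, Optional[float]]]:
    mean_vals: dict[str, Optional[float]] = {}
    ci: dict[str, Optional[float]] = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            logger.warning(
                "metric %s undefined in %d/%d folds; excluded from its mean",
                name, len(vals) - len(defined), len(vals),
            )
        if not defined:
            mean_vals[name] = None
            ci[name] = None
            continue
        arr = np.asarray(defined)
        mean_vals[name] = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        ci[name] = 1.96 * sd / np.sqrt(len(arr))
    return MetricSet(**mean_vals), ci


def _fold_metrics(y_true: np.ndarray, probs: np.ndarray, threshold: float) -> MetricSet:
    base = metrics(confusion(y_true, probs, threshold))
    auc, _ = roc_auc(y_true, probs)
    return MetricSet(acc=base.acc, sens=base.sens, spec=base.spec, prec=base.prec, auc=auc)


def cross_validate(
    dataset: LabeledDataset,
    config: ModelConfig,
    n_folds: int = 5,
    seed: int = 0,
    *,
    table: Optional[PropertyTable] = None,
    params: PseAACParams = PseAACParams(),
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of one model configuration.

    Peptides are PseAAC-encoded once up front: the encoding depends only
    on each sequence (never on labels or on other peptides), so
    pre-encoding cannot leak information across folds. Per-fold metrics
    come from the held-out fold only; ROC points are pooled over all
    held-out predictions.
    """
    X, ids, skipped = encode_batch(list(dataset.peptides), table, params)
    kept = set(ids)
    y = np.asarray(
        [l for p, l in zip(dataset.peptides, dataset.labels) if p.id in kept], dtype=int
    )
    if skipped:
        logger.info("cross_validate: skipped %d unencodable peptide(s)", len(skipped))
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} instances for {n_folds}-fold CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[MetricSet] = []
    pooled_y: list[np.ndarray] = []
    pooled_p: list[np.ndarray] = []
    fold_seeds: list[int] = []
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_seed = (seed * 1000 + k) % (2**31)
        fold_seeds.append(fold_seed)
        cfg = ModelConfig(config.family, dict(config.hyperparameters), seed=fold_seed)
        model = fit(cfg, X[train_idx], y[train_idx])
        probs = predict_proba(model, X[test_idx])
        per_fold.append(_fold_metrics(y[test_idx], probs, threshold))
        pooled_y.append(y[test_idx])
        pooled_p.append(probs)
    mean, ci = _summarize(per_fold)
    _, roc_points = roc_auc(np.concatenate(pooled_y), np.concatenate(pooled_p))
    return EvalReport(
        protocol=f"cv{n_folds}",
        per_fold=per_fold,
        mean=mean,
        ci95=ci,
        seeds=fold_seeds,
        roc_points=roc_points,
        notes={
            "dataset": dataset.name,
            "family": config.family,
            "stratified": True,
            "n_skipped": len(skipped),
        },
    )


def cross_dataset_eval(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    config: ModelConfig,
    n_repeats: int = 5,
    seed: int = 0,
    *,
    table: Optional[PropertyTable] = None,
    params: PseAACParams = PseAACParams(),
    threshold: float = 0.5,
) -> EvalReport:
    """Train on one dataset, test on another, over independently seeded repeats.

    Sequence overlap between the two datasets is computed and reported in
    the notes (an overlapping test set would trivialize the evaluation).
    """
    overlap = train_ds.sequences() & test_ds.sequences()
    overlap_frac = len(overlap) / max(1, len(test_ds.sequences()))
    if overlap:
        logger.warning(
            "cross_dataset_eval: %d sequence(s) shared between train and test (%.1f%% of test)",
            len(overlap), 100 * overlap_frac,
        )
    X_tr, tr_ids, _ = encode_batch(list(train_ds.peptides), table, params)
    kept_tr = set(tr_ids)
    y_tr = np.asarray(
        [l for p, l in zip(train_ds.peptides, train_ds.labels) if p.id in kept_tr], dtype=int
    )
    X_te, te_ids, _ = encode_batch(list(test_ds.peptides), table, params)
    kept_te = set(te_ids)
    y_te = np.asarray(
        [l for p, l in zip(test_ds.peptides, test_ds.labels) if p.id in kept_te], dtype=int
    )
    per_fold: list[MetricSet] = []
    seeds: list[int] = []
    pooled_p = np.zeros(len(y_te))
    for r in range(n_repeats):
        rep_seed = (seed * 1000 + r) % (2**31)
        seeds.append(rep_seed)
        cfg = ModelConfig(config.family, dict(config.hyperparameters), seed=rep_seed)
        model = fit(cfg, X_tr, y_tr)
        probs = predict_proba(model, X_te)
        per_fold.append(_fold_metrics(y_te, probs, threshold))
        pooled_p += probs / n_repeats
    mean, ci = _summarize(per_fold)
    _, roc_points = roc_auc(y_te, pooled_p)
    return EvalReport(
        protocol="cross_dataset",
        per_fold=per_fold,
        mean=mean,
        ci95=ci,
        seeds=seeds,
        roc_points=roc_points,
        notes={
            "train": train_ds.name,
            "test": test_ds.name,
            "family": config.family,
            "n_overlap": len(overlap),
            "overlap_fraction_of_test": overlap_frac,
        },
    )
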