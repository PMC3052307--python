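"""Confusion metrics, k-fold cross-validation and experiment harnesses.

Metrics follow the standard definitions
Pr = TP/(TP+FP), Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/(TP+FP+TN+FN); an undefined ratio is reported as None,
never silently as 0.  Cross-validation pools (micro-averages) the fold
confusion counts before computing metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import rbfn
from .features import EncoderConfig, build_feature_matrix


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]


def count_predictions(
    true_labels: Sequence[str], predicted: Sequence[str]
) -> ConfusionCounts:
    if len(true_labels) != len(predicted):
        raise ValueError("label vectors differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted):
        if t == "positive":
            tp, fn = (tp + 1, fn) if p == "positive" else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == "negative" else (tn, fp + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Pr, Sn, Sp, Acc from a confusion table; zero-denominator → None."""
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return Metrics(
        precision=ratio(counts.tp, counts.tp + counts.fp),
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        accuracy=(counts.tp + counts.tn) / counts.total,
    )


@dataclass
class CVResult:
    """Per-fold confusion counts plus pooled metrics for one CV run."""

    fold_counts: list
    k: int
    seed: int
    assignments: np.ndarray  # fold index per instance

    @property
    def pooled(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.fold_counts:
            total = total + c
        return total

    @property
    def pooled_metrics(self) -> Metrics:
        return metrics(self.pooled)


def _fold_assignments(
    labels: Sequence[str],
    k: int,
    seed: int,
    stratified: bool,
    groups: Optional[Sequence[str]],
) -> np.ndarray:
    y = np.asarray(labels)
    X_dummy = np.zeros((len(y), 1))
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X_dummy, y, groups=np.asarray(groups))
    elif stratified:
        for cls, count in zip(*np.unique(y, return_counts=True)):
            if count < k:
                raise ValueError(
                    f"class {cls!r} has {count} members, fewer than k={k}"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X_dummy, y)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(y))
        assignments = np.empty(len(y), dtype=int)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignments[chunk] = fold
        return assignments
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(split):
        assignments[test_idx] = fold
    return assignments


def kfold(
    features: np.ndarray,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    groups: Optional[Sequence[str]] = None,
    sigma: float = 5.0,
    ridge: float = 1e-8,
    kernel: str = "2sigma2",
    threshold: Optional[float] = None,
) -> CVResult:
    """Stratified k-fold CV with the RBF network; every instance tested once.

    ``groups`` (e.g. protein ids) switches to group-aware stratification so
    homologous sites never straddle a train/test boundary.
    """
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    if k < 2:
        raise ValueError("k must be ≥ 2")
    assignments = _fold_assignments(labels, k, seed, stratified, groups)
    fold_counts = []
    y = np.asarray(labels)
    for fold in range(k):
        test_mask = assignments == fold
        model = rbfn.train(
            X[~test_mask], list(y[~test_mask]), sigma=sigma, ridge=ridge, kernel=kernel
        )
        pred = rbfn.predict(model, X[test_mask], threshold=threshold)
        fold_counts.append(count_predictions(list(y[test_mask]), pred))
    return CVResult(fold_counts=fold_counts, k=k, seed=seed, assignments=assignments)


# ---------------------------------------------------------------------------
# Experiment harnesses

def window_sweep(
    dataset,
    n_values: Sequence[int] = tuple(range(5, 21)),
    blocks: Tuple[str, ...] = ("AAC",),
    k: int = 5,
    seed: int = 0,
    sigma: float = 5.0,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Cross-validate one model per window half-width; shared fold seed.

    Returns a table with columns window, n, Sn, Sp, Acc — the classical
    window-length experiment that exposes whether positions distant from
    the site carry class signal.
    """
    rows = []
    for n in n_values:
        config = EncoderConfig(n=n, blocks=blocks)
        X, labels, _, _ = build_feature_matrix(
            dataset.proteins, dataset.sites, dataset.profiles, config
        )
        cv = kfold(X, labels, k=k, seed=seed, sigma=sigma, ridge=ridge)
        m = cv.pooled_metrics
        rows.append(
            {
                "window": 2 * n + 1,
                "n": n,
                "Sn": m.sensitivity,
                "Sp": m.specificity,
                "Acc": m.accuracy,
            }
        )
    return pd.DataFrame(rows)


def feature_comparison(
    dataset,
    configs: Dict[str, EncoderConfig],
    k: int = 5,
    seed: int = 0,
    sigma: float = 5.0,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Cross-validate each named feature combination with shared folds.

    ``configs`` is a mapping name → EncoderConfig, or a sequence of
    (name, EncoderConfig) pairs; duplicate names are rejected.
    """
    pairs = list(configs.items()) if isinstance(configs, dict) else list(configs)
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate config names")
    rows = []
    for name, config in pairs:
        X, labels, _, _ = build_feature_matrix(
            dataset.proteins, dataset.sites, dataset.profiles, config
        )
        cv = kfold(X, labels, k=k, seed=seed, sigma=sigma, ridge=ridge)
        m = cv.pooled_metrics
        rows.append(
            {"config": name, "Sn": m.sensitivity, "Sp": m.specificity, "Acc": m.accuracy}
        )
    return pd.DataFrame(rows)


def independent_test(
    model: rbfn.RBFNModel,
    test_features: np.ndarray,
    test_labels: Sequence[str],
    threshold: Optional[float] = None,
) -> Tuple[ConfusionCounts, Metrics]:
    """Apply a trained model to held-out data and count the outcomes."""
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    if len(test_labels) == 0:
        raise ValueError("empty test set")
    if X.shape[0] != len(test_labels):
        raise ValueError("features and labels differ in length")
    pred = rbfn.predict(model, X, threshold=threshold)
    counts = count_predictions(list(test_labels), pred)
    return counts, metrics(counts)
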