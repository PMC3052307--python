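"""F-score feature discrimination statistic and positional scans.

The F-score of a feature is the ratio of the squared deviations of the two
class means from the grand mean to the sum of the two within-class sample
variances:

    F = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] /
        [ 1/(n⁺−1) Σ(x_k⁺ − x̄⁺)²  +  1/(n⁻−1) Σ(x_k⁻ − x̄⁻)² ]

A high F-score marks a feature that separates positive from negative
instances.  The positional scan aggregates the 20 per-residue-channel
F-scores at each window offset, exposing discriminative positions distant
from the central lysine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import AA_INDEX, AA_ORDER, Fragment


def f_score(pos_values, neg_values) -> float:
    """Eq.-style F-score of one feature from its two class samples.

    Returns 0.0 when the numerator is zero, and ``inf`` when the
    within-class variances vanish while the class means differ (perfect
    separation).  Requires at least two instances per class.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("f_score needs ≥ 2 instances in each class")
    mean_pos = pos.mean()
    mean_neg = neg.mean()
    grand = np.concatenate([pos, neg]).mean()
    numerator = (mean_pos - grand) ** 2 + (mean_neg - grand) ** 2
    denominator = (
        np.sum((pos - mean_pos) ** 2) / (pos.size - 1)
        + np.sum((neg - mean_neg) ** 2) / (neg.size - 1)
    )
    if numerator == 0.0:
        return 0.0
    if denominator == 0.0:
        return math.inf
    return float(numerator / denominator)


@dataclass(frozen=True)
class FScoreTable:
    """Per-feature F-scores ranked descending (ties keep column order)."""

    names: Tuple[str, ...]
    scores: Tuple[float, ...]  # aligned with names (input column order)
    order: Tuple[int, ...]  # indices sorted by descending score, stable
    n_pos: int
    n_neg: int

    def ranked(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [self.names[i] for i in self.order],
                "fscore": [self.scores[i] for i in self.order],
            }
        )

    def score_of(self, name: str) -> float:
        return self.scores[self.names.index(name)]


def rank_features(
    matrix: np.ndarray,
    labels: Sequence[str],
    names: Optional[Sequence[str]] = None,
) -> FScoreTable:
    """Column-wise F-scores of a feature matrix against binary labels."""
    X = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("matrix rows must match label count")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    pos_mask = np.array([lab == "positive" for lab in labels])
    if "positive" not in classes:  # generic binary: later-sorted class is positive
        pos_mask = np.array([lab == classes[1] for lab in labels])
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    scores = [f_score(X[pos_mask, j], X[~pos_mask, j]) for j in range(X.shape[1])]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return FScoreTable(
        names=tuple(names),
        scores=tuple(scores),
        order=tuple(order),
        n_pos=int(pos_mask.sum()),
        n_neg=int((~pos_mask).sum()),
    )


def positional_scan(
    fragments: Sequence[Fragment],
    labels: Optional[Sequence[str]] = None,
    channel: str = "composition",
    pssm_windows: Optional[np.ndarray] = None,
    agg: str = "sum",
) -> Dict[int, float]:
    """Aggregate per-offset F-scores across the window.

    channel "composition": at each offset (excluding 0, which is always K)
    the 20 features are residue-identity indicators; channel "pssm": the 20
    features are the PSSM scores at that offset, supplied as
    ``pssm_windows`` with shape (n_fragments, 2n+1, 20).  Per offset the 20
    channel F-scores are aggregated by ``agg`` ("sum" or "max").
    """
    if not fragments:
        raise ValueError("positional_scan needs at least one fragment")
    if labels is None:
        labels = [f.label for f in fragments]
    labels = list(labels)
    if any(lab not in ("positive", "negative") for lab in labels):
        raise ValueError("every fragment needs a positive/negative label")
    ns = {f.n for f in fragments}
    if len(ns) != 1:
        raise ValueError("fragments mix window sizes")
    n = ns.pop()
    pos_mask = np.array([lab == "positive" for lab in labels])
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise ValueError("need ≥ 2 fragments per class")
    if agg not in ("sum", "max"):
        raise ValueError("agg must be 'sum' or 'max'")
    reducer = np.sum if agg == "sum" else np.max

    offsets = list(range(-n, n + 1))
    if channel == "composition":
        offsets = [o for o in offsets if o != 0]
        # indicator tensor (n_frag, n_offsets, 20)
        feats = np.zeros((len(fragments), len(offsets), 20))
        for i, frag in enumerate(fragments):
            for j, o in enumerate(offsets):
                ch = frag.residues[o + n]
                if ch in AA_INDEX:
                    feats[i, j, AA_INDEX[ch]] = 1.0
    elif channel == "pssm":
        if pssm_windows is None:
            raise ValueError("channel='pssm' requires pssm_windows")
        feats = np.asarray(pssm_windows, dtype=float)
        if feats.shape != (len(fragments), 2 * n + 1, 20):
            raise ValueError(
                f"pssm_windows shape {feats.shape} != "
                f"({len(fragments)}, {2 * n + 1}, 20)"
            )
    else:
        raise ValueError(f"unknown channel {channel!r}")

    result: Dict[int, float] = {}
    for j, o in enumerate(offsets):
        per_channel = [
            f_score(feats[pos_mask, j, c], feats[~pos_mask, j, c]) for c in range(20)
        ]
        result[o] = float(reducer(per_channel))
    return result


def top_offsets(scan: Dict[int, float], k: int) -> list[int]:
    """The k offsets with the largest aggregate scores (stable on ties)."""
    return [o for o, _ in sorted(scan.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]
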