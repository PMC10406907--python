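"""Train/test splitting and ROC/AUC model evaluation.

The AUC is computed as the rank-based (Mann-Whitney) statistic — the
probability that a random positive outranks a random negative, with ties
counted one half — which is identical to the trapezoidal area under the
empirical ROC curve.  A constant predictor therefore scores exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["SplitPlan", "RocResult", "split", "auc", "roc"]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test row indices for one split."""

    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self):
        tr, te = set(self.train.tolist()), set(self.test.tolist())
        if tr & te:
            raise ValueError("train and test rows overlap")


def _train_size(n: int, fraction: float) -> int:
    # round half up on the train count
    return int(np.floor(n * fraction + 0.5))


def split(n: int, fraction: float = 0.7, seed: int = 0, stratify_by=None) -> SplitPlan:
    """Random train/test split of ``n`` rows, deterministic given ``seed``.

    With ``stratify_by`` (e.g. the binary outcome), class counts are
    allocated proportionally to the two parts (largest remainder), so the
    training prevalence matches the full-data prevalence as closely as the
    integer counts allow.
    """
    if n < 10:
        raise ValueError("need at least 10 observations to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t = _train_size(n, fraction)
    if stratify_by is None:
        perm = rng.permutation(n)
        train, test = perm[:t], perm[t:]
    else:
        labels = np.asarray(stratify_by)
        classes, counts = np.unique(labels, return_counts=True)
        exact = counts * t / n
        base = np.floor(exact).astype(int)
        remainder = exact - base
        short = t - int(base.sum())
        for idx in np.argsort(-remainder)[:short]:
            base[idx] += 1
        train_parts, test_parts = [], []
        for cls, take in zip(classes, base):
            rows = np.flatnonzero(labels == cls)
            rows = rng.permutation(rows)
            train_parts.append(rows[:take])
            test_parts.append(rows[take:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
        if len(classes) > 1:
            for part, name in ((train, "train"), (test, "test")):
                if len(np.unique(labels[part])) < len(classes):
                    raise ValueError(f"a class is absent from the {name} part")
    return SplitPlan(train=np.asarray(train), test=np.asarray(test),
                     fraction=fraction, seed=seed)


def auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney statistic), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocResult:
    """Empirical ROC curve with its trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(scores, labels) -> RocResult:
    """Empirical ROC curve; its trapezoidal area equals the rank AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    area = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area)
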