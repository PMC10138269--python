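"""Evaluation protocol: repeated shuffled hold-out, confusion metrics
with the minority class as positive, and Welch t-test model comparison.

Sensitivity is the true-positive rate of the minority class;
"selectivity" follows the specificity reading TN / (TN + FP).  Metrics
with a zero denominator are reported as NaN (missing), never coerced
to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LabeledDataset
from .exceptions import ConfigError, InputError

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "shuffled_splits",
    "confusion_metrics",
    "compare_models_ttest",
]


@dataclass(frozen=True)
class SplitPlan:
    """Row-id train/test splits for each shuffled round."""

    rounds: int
    test_fraction: float
    seed: int
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_ids, test_ids)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived rates (percentages; F1 on [0, 1])."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    selectivity: float
    precision: float
    accuracy: float
    f1_positive: float
    f1_negative: float
    positive_label: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "selectivity": self.selectivity,
            "precision": self.precision, "accuracy": self.accuracy,
            "f1_positive": self.f1_positive, "f1_negative": self.f1_negative,
            "positive_label": self.positive_label,
        }


def shuffled_splits(
    data: LabeledDataset,
    rounds: int = 10,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> SplitPlan:
    """Independent uniform shuffles per round (not stratified).

    Each round permutes all rows and holds out round(test_fraction * N)
    of them as the test subset.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    if data.n < 10:
        raise InputError("need at least 10 points for the shuffled-split protocol")
    if rounds < 1:
        raise ConfigError("rounds must be >= 1")
    n_test = int(round(test_fraction * data.n))
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(rounds):
        perm = rng.permutation(data.n)
        test = np.sort(data.row_ids[perm[:n_test]])
        train = np.sort(data.row_ids[perm[n_test:]])
        splits.append((train, test))
    return SplitPlan(
        rounds=rounds, test_fraction=test_fraction, seed=seed, splits=tuple(splits)
    )


def _ratio(num: int, den: int, scale: float) -> float:
    return scale * num / den if den > 0 else float("nan")


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive_label: float = 1
) -> MetricsReport:
    """Confusion counts and derived rates for ±1 label vectors."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if len(y_true) == 0:
        raise InputError("empty input")
    if len(y_true) != len(y_pred):
        raise InputError("y_true and y_pred lengths differ")
    for v in (y_true, y_pred):
        if not np.isin(v, (-1.0, 1.0)).all():
            raise InputError("labels must be -1 or +1")
    if positive_label not in (-1, 1):
        raise ConfigError("positive_label must be -1 or +1")

    pos = y_true == positive_label
    pred_pos = y_pred == positive_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))

    sens = _ratio(tp, tp + fn, 100.0)
    sel = _ratio(tn, tn + fp, 100.0)
    prec = _ratio(tp, tp + fp, 100.0)
    acc = _ratio(tp + tn, tp + fn + tn + fp, 100.0)

    def _f1(p: float, r: float) -> float:
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return float("nan")
        return 2 * (p / 100) * (r / 100) / ((p + r) / 100)

    neg_prec = _ratio(tn, tn + fn, 100.0)
    f1_pos = _f1(prec, sens)
    f1_neg = _f1(neg_prec, sel)
    return MetricsReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, selectivity=sel, precision=prec, accuracy=acc,
        f1_positive=f1_pos, f1_negative=f1_neg,
        positive_label=float(positive_label),
    )


def compare_models_ttest(
    samples_a,
    samples_b,
    alpha: float = 0.05,
    paired: bool = False,
) -> tuple[float, float, bool]:
    """Two-sided t-test between per-round metric samples.

    Welch's unequal-variance two-sample test by default; ``paired``
    switches to the paired test.  Degenerate zero-variance inputs with
    equal means yield (0, 1, False).
    """
    a = np.asarray(samples_a, dtype=np.float64)
    b = np.asarray(samples_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each sample needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0, 0.0 < alpha
    if paired:
        if len(a) != len(b):
            raise InputError("paired test needs equal-length samples")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)
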