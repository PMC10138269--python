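"""Support-value pruning: restoring sparseness to the LS-SVM.

Unlike the standard SVM, every LS-SVM training point carries a nonzero
support value alpha_k = γ e_k, so the model is dense.  Sparseness is
recovered by iteratively discarding the points with the smallest |alpha|
(the least informative ones) and refitting, while a held-out validation
slice guards the error performance.  The retained points are the "most
informative support vectors" that the two-layer pipeline forwards to the
global model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import balanced_accuracy_score, f1_score

from .core import KernelSpec, LabeledDataset, LSSVMModel, fit_lssvm, predict
from .exceptions import ConfigError
from .logging_utils import get_logger

log = get_logger(__name__)

__all__ = ["PruneConfig", "SparseLSSVMModel", "support_values", "prune_lssvm"]

#: Below this many points a dataset is returned unpruned (pass-through).
MIN_PRUNABLE_SIZE = 20

VALIDATION_METRICS = ("f1_positive", "balanced_accuracy")


@dataclass(frozen=True)
class PruneConfig:
    """Knobs of the iterative pruning loop.

    step_fraction
        Fraction of the current point set removed per iteration.
    stop_tolerance
        Maximum tolerated drop of the validation metric from its best
        observed value before pruning stops.
    min_retained_fraction
        Hard floor on the retained fraction of the input set.
    validation_fraction
        Stratified hold-out fraction used to monitor the metric; these
        points are never candidates for removal and are not part of the
        returned retained set.
    metric
        "f1_positive" (F1 of the +1 class) or "balanced_accuracy".
    min_positive_retained_fraction
        Per-region floor on the retained fraction of the positive
        (rare) class.  Support-value ranking under-values well-separated
        rare-class points (tiny residuals), yet the global layer needs
        their coverage; keeping at least half of them per region guards
        it.  Set to 0 to rank purely by support value.
    """

    step_fraction: float = 0.05
    stop_tolerance: float = 0.01
    min_retained_fraction: float = 0.10
    validation_fraction: float = 0.20
    metric: str = "f1_positive"
    min_positive_retained_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction < 1:
            raise ConfigError("step_fraction must lie in (0, 1)")
        if self.stop_tolerance < 0:
            raise ConfigError("stop_tolerance must be non-negative")
        if not 0 < self.min_retained_fraction <= 1:
            raise ConfigError("min_retained_fraction must lie in (0, 1]")
        if not 0 < self.validation_fraction < 1:
            raise ConfigError("validation_fraction must lie in (0, 1)")
        if self.metric not in VALIDATION_METRICS:
            raise ConfigError(f"metric must be one of {VALIDATION_METRICS}")
        if not 0 <= self.min_positive_retained_fraction <= 1:
            raise ConfigError(
                "min_positive_retained_fraction must lie in [0, 1]"
            )


@dataclass(frozen=True)
class SparseLSSVMModel:
    """A pruned LS-SVM plus provenance of what survived.

    ``trajectory`` records (retained count, validation metric) per
    pruning iteration; counts are strictly decreasing.  A NaN metric
    marks a pass-through fit where no validation split was made.
    """

    model: LSSVMModel
    retained_row_ids: np.ndarray
    trajectory: tuple[tuple[int, float], ...]


def validation_score(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    if metric == "f1_positive":
        return float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
    return float(balanced_accuracy_score(y_true, y_pred))


def _stratified_holdout(
    labels: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split that never empties a class on either side.

    Per class, round(fraction * count) points go to validation, clamped
    so both sides keep at least one point of every class with >= 2
    members.
    """
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for lab in (-1.0, 1.0):
        pos = np.flatnonzero(labels == lab)
        if len(pos) == 0:
            continue
        n_val = int(round(fraction * len(pos)))
        if len(pos) >= 2:
            n_val = min(max(n_val, 1), len(pos) - 1)
        else:
            n_val = 0
        perm = rng.permutation(pos)
        val_parts.append(perm[:n_val])
        train_parts.append(perm[n_val:])
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(val_parts)),
    )


def support_values(model: LSSVMModel) -> list[tuple[int, float]]:
    """Rank training points by |alpha| descending; ties by ascending row id."""
    mags = np.abs(model.alphas)
    order = np.lexsort((model.support_row_ids, -mags))
    return [(int(model.support_row_ids[i]), float(mags[i])) for i in order]


def _removal_candidates(
    model: LSSVMModel,
    n_remove: int,
    labels_by_rowid: dict[int, float],
    min_counts: dict[float, int] | None = None,
) -> list[int]:
    """Row ids of the lowest-|alpha| points, honouring per-class floors.

    A point is pinned (skipped) when removing it would push its class
    below ``min_counts`` (at least 1 per class, so fits stay binary).
    """
    if min_counts is None:
        min_counts = {-1.0: 1, 1.0: 1}
    ranking = support_values(model)  # descending
    counts = {-1.0: 0, 1.0: 0}
    for rid, _ in ranking:
        counts[labels_by_rowid[rid]] += 1
    removed: list[int] = []
    for rid, _ in reversed(ranking):  # ascending |alpha|
        if len(removed) == n_remove:
            break
        lab = labels_by_rowid[rid]
        if counts[lab] <= max(min_counts.get(lab, 1), 1):
            continue
        counts[lab] -= 1
        removed.append(rid)
    return removed


def prune_lssvm(
    data: LabeledDataset,
    spec: KernelSpec,
    gamma: float,
    cfg: PruneConfig,
    *,
    standardize: bool = True,
) -> SparseLSSVMModel:
    """Iteratively prune the lowest-support-value points and refit.

    Algorithm: hold out a stratified validation slice; repeatedly fit on
    the current set, score on validation, and drop the
    ``ceil(step_fraction * current)`` lowest-|alpha| points; stop when
    the metric falls more than ``stop_tolerance`` below its best or the
    floor ``min_retained_fraction`` is reached.  The returned model is
    refit on the iteration with the fewest points among those attaining
    the best validation metric seen.

    Datasets below ``MIN_PRUNABLE_SIZE`` points, or configurations that
    allow no removal at all, pass through unpruned.
    """
    min_allowed = max(int(math.ceil(cfg.min_retained_fraction * data.n)), 4)

    def _passthrough() -> SparseLSSVMModel:
        model = fit_lssvm(data, spec, gamma, standardize=standardize)
        return SparseLSSVMModel(
            model=model,
            retained_row_ids=data.row_ids.copy(),
            trajectory=((data.n, float("nan")),),
        )

    if data.n < MIN_PRUNABLE_SIZE or min_allowed >= data.n:
        return _passthrough()

    n_val = int(round(cfg.validation_fraction * data.n))
    if n_val < 1 or data.n - n_val < 2:
        raise ConfigError(
            f"validation_fraction {cfg.validation_fraction} leaves a "
            f"degenerate split for {data.n} points"
        )
    train_pos, val_pos = _stratified_holdout(
        data.labels, cfg.validation_fraction, cfg.seed
    )
    val = data.subset(val_pos)
    if not data.subset(train_pos).has_both_classes() or not val.has_both_classes():
        raise ConfigError("validation split lost a class; lower validation_fraction")

    labels_by_rowid = {int(r): float(l) for r, l in zip(data.row_ids, data.labels)}
    pos_by_rowid = {int(r): int(p) for p, r in enumerate(data.row_ids)}
    n_pos_train = int((data.labels[train_pos] == 1).sum())
    min_counts = {
        -1.0: 1,
        1.0: max(
            1,
            int(math.ceil(cfg.min_positive_retained_fraction * n_pos_train)),
        ),
    }

    current = train_pos
    best = -np.inf
    records: list[tuple[int, float, np.ndarray]] = []
    while True:
        subset = data.subset(current)
        model = fit_lssvm(subset, spec, gamma, standardize=standardize)
        score = validation_score(val.labels, predict(model, val.features), cfg.metric)
        records.append((len(current), score, current))
        best = max(best, score)
        if score < best - cfg.stop_tolerance:
            break
        n_remove = int(math.ceil(cfg.step_fraction * len(current)))
        if len(current) - n_remove < min_allowed:
            break
        drop = _removal_candidates(model, n_remove, labels_by_rowid, min_counts)
        if not drop:  # everything pinned
            break
        drop_pos = {pos_by_rowid[r] for r in drop}
        current = np.array([p for p in current if p not in drop_pos])

    # fewest points among the iterations attaining the best metric
    eligible = [r for r in records if r[1] >= best]
    count, score, chosen = min(eligible, key=lambda r: r[0])
    log.debug(
        "pruned %d -> %d points (metric %.4f, best %.4f)", data.n, count, score, best
    )
    final_model = fit_lssvm(data.subset(chosen), spec, gamma, standardize=standardize)
    return SparseLSSVMModel(
        model=final_model,
        retained_row_ids=data.row_ids[chosen],
        trajectory=tuple((c, s) for c, s, _ in records),
    )
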