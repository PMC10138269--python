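"""Hyperparameter selection by stratified cross-validated grid search.

Selects the regularisation weight γ and (for the RBF kernel) the
bandwidth σ².  The σ² grid adapts to feature scale through the median
squared pairwise distance heuristic.  Ties prefer smoother models:
smaller γ first, then smaller σ².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import KernelSpec, LabeledDataset, fit_lssvm, predict
from .exceptions import ConfigError
from .logging_utils import get_logger
from .pruning import VALIDATION_METRICS, validation_score

log = get_logger(__name__)

__all__ = ["TuningGrid", "tune_hyperparams", "median_sq_distance"]

DEFAULT_GAMMAS = tuple(float(g) for g in np.logspace(-2, 3, 6))
DEFAULT_BANDWIDTH_MULTIPLIERS = (0.1, 0.5, 1.0, 5.0, 10.0)
#: At most this many points enter the median-distance heuristic.
_MEDIAN_SUBSAMPLE = 500


@dataclass(frozen=True)
class TuningGrid:
    """Search space for (γ, σ²).

    ``bandwidth_sq_values=None`` derives the σ² grid at tune time as
    ``DEFAULT_BANDWIDTH_MULTIPLIERS`` times the median squared pairwise
    distance of the data, so defaults adapt to feature scale.  ``folds``
    is reduced to 3 below 100 points.
    """

    gamma_values: tuple[float, ...] = DEFAULT_GAMMAS
    bandwidth_sq_values: tuple[float, ...] | None = None
    folds: int = 5
    metric: str = "f1_positive"
    seed: int = 0
    kernel_family: str = "rbf"

    def __post_init__(self) -> None:
        if len(self.gamma_values) == 0:
            raise ConfigError("gamma grid must be non-empty")
        if any(g <= 0 for g in self.gamma_values):
            raise ConfigError("gamma grid values must be positive")
        if self.bandwidth_sq_values is not None and (
            len(self.bandwidth_sq_values) == 0
            or any(b <= 0 for b in self.bandwidth_sq_values)
        ):
            raise ConfigError("bandwidth grid must be non-empty and positive")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.metric not in VALIDATION_METRICS:
            raise ConfigError(f"metric must be one of {VALIDATION_METRICS}")


def median_sq_distance(X: np.ndarray, seed: int = 0) -> float:
    """Median squared pairwise Euclidean distance (subsampled above 500)."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) > _MEDIAN_SUBSAMPLE:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), _MEDIAN_SUBSAMPLE, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(X, metric="sqeuclidean")
    med = float(np.median(d)) if len(d) else 1.0
    return med if med > 0 else 1.0


def _bandwidth_grid(grid: TuningGrid, X: np.ndarray) -> tuple[float, ...]:
    if grid.kernel_family != "rbf":
        return (1.0,)  # unused placeholder for scale-free kernels
    if grid.bandwidth_sq_values is not None:
        return grid.bandwidth_sq_values
    med = median_sq_distance(X, seed=grid.seed)
    return tuple(m * med for m in DEFAULT_BANDWIDTH_MULTIPLIERS)


def tune_hyperparams(
    data: LabeledDataset,
    grid: TuningGrid,
    *,
    standardize: bool = True,
) -> tuple[float, KernelSpec, pd.DataFrame]:
    """Stratified k-fold grid search over (γ, σ²).

    Returns the winning γ, the corresponding kernel spec, and the full
    cross-validation score table (columns gamma, bandwidth_sq,
    mean_score).  The reported score is the plain mean over folds of the
    configured metric; the winner is its argmax with smoother-model tie
    breaking.
    """
    if not data.has_both_classes():
        raise ConfigError("tuning requires both classes")
    folds = grid.folds if data.n >= 100 else min(grid.folds, 3)
    _, pos = data.class_counts()
    minority = min(pos, data.n - pos)
    if folds > minority:
        raise ConfigError(
            f"stratification failure: {folds} folds but only {minority} "
            "points in the rarer class; use fewer folds"
        )
    # the sigma^2 heuristic must see the same space the kernel will see
    if standardize:
        from .core import Scaler

        heuristic_X = Scaler.fit(data.features).transform(data.features)
    else:
        heuristic_X = data.features
    bandwidths = _bandwidth_grid(grid, heuristic_X)
    splitter = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=grid.seed % (2**32)
    )
    splits = [
        (np.sort(tr), np.sort(te))
        for tr, te in splitter.split(data.features, data.labels)
    ]

    rows = []
    for gamma in grid.gamma_values:
        for bw in bandwidths:
            spec = KernelSpec(family=grid.kernel_family, bandwidth_sq=bw)
            scores = []
            for tr, te in splits:
                model = fit_lssvm(
                    data.subset(tr), spec, gamma, standardize=standardize
                )
                te_data = data.subset(te)
                scores.append(
                    validation_score(
                        te_data.labels, predict(model, te_data.features), grid.metric
                    )
                )
            rows.append((float(gamma), float(bw), float(np.mean(scores))))
    table = pd.DataFrame(rows, columns=["gamma", "bandwidth_sq", "mean_score"])
    # argmax; ties -> smaller gamma, then smaller sigma^2
    best_score = table["mean_score"].max()
    winners = table[table["mean_score"] == best_score]
    winner = winners.sort_values(["gamma", "bandwidth_sq"]).iloc[0]
    spec = KernelSpec(
        family=grid.kernel_family, bandwidth_sq=float(winner["bandwidth_sq"])
    )
    log.debug(
        "tuned gamma=%.4g sigma2=%.4g (%s=%.4f over %d folds)",
        winner["gamma"], winner["bandwidth_sq"], grid.metric, best_score, folds,
    )
    return float(winner["gamma"]), spec, table
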