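"""The two-layer global-local LS-SVM pipeline.

Layer one partitions the (standardised) training inputs with k-means,
repairs degenerate regions, and fits a sparse (pruned) LS-SVM in each
region.  The points each local model retains — its highest-support-value
points — are merged into one reduced pool.  Layer two trains a single
plain LS-SVM on that pool; it is the model used for prediction.

Because the pool keeps each region's informative points rather than a
uniform sample, minority-class points are over-represented in it
relative to the full training set, which is what lets the global model
recover minority sensitivity under strong class imbalance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .core import (
    KernelSpec,
    LabeledDataset,
    LSSVMModel,
    Scaler,
    decision_value,
    fit_lssvm,
    predict,
)
from .exceptions import ConfigError, UnfittableError
from .logging_utils import get_logger
from .partition import PartitionAssignment, kmeans_partition, make_local_problems
from .pruning import PruneConfig, SparseLSSVMModel, prune_lssvm
from .tuning import TuningGrid, tune_hyperparams

log = get_logger(__name__)

__all__ = [
    "GLocalConfig",
    "GLocalModel",
    "TimingReport",
    "extract_support_vectors",
    "fit_glocal",
    "predict_glocal",
]


@dataclass(frozen=True)
class GLocalConfig:
    """Configuration of one two-layer fit.

    ``kernel`` and ``gamma`` may be fixed values or the string "tune",
    in which case a cross-validated grid search runs per region.  The
    global layer tunes independently on the merged pool; set
    ``global_kernel``/``global_gamma`` to fixed values or "tune" to
    override, or leave them None to inherit the local setting.
    ``prune_locals=False`` turns layer-one pruning off (every local
    point reaches the pool); ``sparse_global=True`` additionally prunes
    the global layer, off by default.
    """

    n_partitions: int = 10
    kernel: KernelSpec | str = "tune"
    gamma: float | str = "tune"
    global_kernel: KernelSpec | str | None = None
    global_gamma: float | str | None = None
    prune: PruneConfig = field(default_factory=PruneConfig)
    grid: TuningGrid = field(default_factory=TuningGrid)
    seed: int = 0
    min_partition_size: int = 20
    prune_locals: bool = True
    sparse_global: bool = False
    kmeans_n_init: int = 5
    kmeans_max_iter: int = 300
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ConfigError("n_partitions must be >= 1")
        fixed_kernel = isinstance(self.kernel, KernelSpec)
        if not fixed_kernel and self.kernel != "tune":
            raise ConfigError('kernel must be a KernelSpec or "tune"')
        fixed_gamma = isinstance(self.gamma, (int, float)) and not isinstance(self.gamma, bool)
        if fixed_gamma:
            if self.gamma <= 0:
                raise ConfigError("gamma must be positive")
        elif self.gamma != "tune":
            raise ConfigError('gamma must be a positive number or "tune"')
        if fixed_kernel != fixed_gamma:
            raise ConfigError("kernel and gamma must be both fixed or both tuned")
        if (self.global_kernel is None) != (self.global_gamma is None):
            raise ConfigError(
                "global_kernel and global_gamma must be overridden together"
            )

    @property
    def tune(self) -> bool:
        return self.kernel == "tune"

    @property
    def tune_global(self) -> bool:
        if self.global_kernel is None:
            return self.tune
        return self.global_kernel == "tune"


@dataclass(frozen=True)
class TimingReport:
    """Per-stage wall-clock accounting of one two-layer fit (seconds)."""

    accumulated_local_seconds: float
    average_local_seconds: float
    global_seconds: float
    total_seconds: float
    n_pool_points: int


@dataclass(frozen=True)
class GLocalModel:
    """Fitted two-layer model: the global LS-SVM plus provenance."""

    global_model: LSSVMModel
    merged_pool: LabeledDataset
    pool_partition_ids: np.ndarray  # effective partition id per pooled row
    local_summaries: tuple[dict, ...]
    timing: TimingReport
    partition: PartitionAssignment | None = None
    config: GLocalConfig | None = None


def extract_support_vectors(
    local_models: list[SparseLSSVMModel],
    data: LabeledDataset,
    partition_ids: list[int] | None = None,
) -> tuple[LabeledDataset, np.ndarray]:
    """Merge every local model's retained points into one data pool.

    Returns the pooled dataset (a row-id subset of ``data``) and the
    effective-partition id of each pooled row.
    """
    if not local_models:
        raise UnfittableError("no local models to merge")
    if partition_ids is None:
        partition_ids = list(range(len(local_models)))
    pos_by_rowid = {int(r): i for i, r in enumerate(data.row_ids)}
    positions: list[int] = []
    prov: list[int] = []
    for pid, sm in zip(partition_ids, local_models):
        for rid in sm.retained_row_ids:
            positions.append(pos_by_rowid[int(rid)])
            prov.append(pid)
    pool = data.subset(np.array(positions, dtype=np.int64))
    if not pool.has_both_classes():
        raise UnfittableError("merged support-vector pool is single-class")
    return pool, np.array(prov, dtype=np.int64)


def _local_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _fit_one_local(
    ds: LabeledDataset, cfg: GLocalConfig, seed: int, pid: int
) -> tuple[SparseLSSVMModel, dict]:
    t0 = time.perf_counter()
    if cfg.tune:
        # clamp folds so stratification survives regions with very few
        # rare-class points (repair guarantees at least 2)
        minority = min(ds.class_counts())
        folds = max(2, min(cfg.grid.folds, minority))
        gamma, spec, _ = tune_hyperparams(
            ds, replace(cfg.grid, seed=seed, folds=folds), standardize=False
        )
    else:
        gamma, spec = float(cfg.gamma), cfg.kernel
    if cfg.prune_locals:
        sm = prune_lssvm(
            ds, spec, gamma, replace(cfg.prune, seed=seed), standardize=False
        )
    else:
        model = fit_lssvm(ds, spec, gamma, standardize=False)
        sm = SparseLSSVMModel(
            model=model,
            retained_row_ids=ds.row_ids.copy(),
            trajectory=((ds.n, float("nan")),),
        )
    seconds = time.perf_counter() - t0
    summary = {
        "partition": pid,
        "size": ds.n,
        "retained": len(sm.retained_row_ids),
        "gamma": gamma,
        "kernel_family": spec.family,
        "bandwidth_sq": spec.bandwidth_sq,
        "fit_seconds": seconds,
    }
    return sm, summary


def fit_glocal(data: LabeledDataset, cfg: GLocalConfig) -> GLocalModel:
    """Run the full two-layer scheme on a training set.

    Stages: standardise -> k-means partition -> repair -> per-region
    (tune +) prune -> merge retained support vectors -> (tune +) fit the
    global LS-SVM on the pool.  Per-region seeds are derived from the
    master seed so results are independent of execution order.
    """
    if not data.has_both_classes():
        raise UnfittableError("training set contains a single class")
    t_start = time.perf_counter()

    scaler = Scaler.fit(data.features)
    sdata = LabeledDataset(
        scaler.transform(data.features), data.labels, data.row_ids
    )

    pa = kmeans_partition(
        sdata.features,
        min(cfg.n_partitions, sdata.n),
        cfg.seed,
        n_init=cfg.kmeans_n_init,
        max_iter=cfg.kmeans_max_iter,
    )
    local_problems = make_local_problems(sdata, pa, min_size=cfg.min_partition_size)
    pids = pa.effective_ids if pa.effective_ids else list(range(len(local_problems)))

    jobs = (
        delayed(_fit_one_local)(ds, cfg, _local_seed(cfg.seed, pid), pid)
        for ds, pid in zip(local_problems, pids)
    )
    results = Parallel(n_jobs=cfg.n_jobs)(jobs)
    local_models = [sm for sm, _ in results]
    summaries = tuple(s for _, s in results)
    accumulated = float(sum(s["fit_seconds"] for _, s in results))

    pool_s, prov = extract_support_vectors(local_models, sdata, pids)

    t_global = time.perf_counter()
    g_seed = _local_seed(cfg.seed, -1 & 0x7FFFFFFF)
    if cfg.tune_global:
        g_gamma, g_spec, _ = tune_hyperparams(
            pool_s, replace(cfg.grid, seed=g_seed), standardize=False
        )
    elif cfg.global_kernel is not None:
        g_gamma, g_spec = float(cfg.global_gamma), cfg.global_kernel
    else:
        g_gamma, g_spec = float(cfg.gamma), cfg.kernel
    if cfg.sparse_global:
        g_sparse = prune_lssvm(
            pool_s, g_spec, g_gamma, replace(cfg.prune, seed=g_seed), standardize=False
        )
        global_model = g_sparse.model
    else:
        global_model = fit_lssvm(pool_s, g_spec, g_gamma, standardize=False)
    global_seconds = time.perf_counter() - t_global

    # expose the pipeline scaler so the model predicts from raw features
    global_model = global_model.with_scaler(scaler)

    # report the pool in the original feature space
    pos_by_rowid = {int(r): i for i, r in enumerate(data.row_ids)}
    pool_raw = data.subset(
        np.array([pos_by_rowid[int(r)] for r in pool_s.row_ids], dtype=np.int64)
    )

    total = time.perf_counter() - t_start
    timing = TimingReport(
        accumulated_local_seconds=accumulated,
        average_local_seconds=accumulated / len(local_models),
        global_seconds=global_seconds,
        total_seconds=total,
        n_pool_points=pool_raw.n,
    )
    log.info(
        "glocal fit: %d regions, pool %d/%d points, %.2fs total",
        len(local_models), pool_raw.n, data.n, total,
    )
    return GLocalModel(
        global_model=global_model,
        merged_pool=pool_raw,
        pool_partition_ids=prov,
        local_summaries=summaries,
        timing=timing,
        partition=pa,
        config=cfg,
    )


def predict_glocal(model: GLocalModel, X: np.ndarray) -> np.ndarray:
    """Delegate to the global layer's LS-SVM."""
    return predict(model.global_model, X)


def decision_value_glocal(model: GLocalModel, X: np.ndarray) -> np.ndarray:
    return decision_value(model.global_model, X)
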