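"""Input-space partitioning: k-means regions plus degeneracy repair.

The first layer of the two-layer scheme treats each k-means cluster of
the (standardised) training inputs as a local learning problem.  Under
strong class imbalance many clusters contain a single class; such
regions cannot host a binary model, so they are absorbed into the
nearest region that supplies the missing class.  Repair conserves
points: the local problems are disjoint and their union is the full
training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import LabeledDataset
from .exceptions import InputError, UnfittableError
from .logging_utils import get_logger

log = get_logger(__name__)

__all__ = ["PartitionAssignment", "kmeans_partition", "make_local_problems"]

DEFAULT_MIN_SIZE = 20


@dataclass
class PartitionAssignment:
    """k-means assignment of every training point to one region.

    ``merge_log`` and ``effective_ids`` are filled by
    :func:`make_local_problems` once degenerate regions are repaired:
    each entry of ``merge_log`` is (source id, absorbed-into id, reason)
    and ``effective_ids`` lists the representative cluster id of each
    surviving local problem, in output order.
    """

    centroids: np.ndarray
    assignment: np.ndarray
    per_partition_class_counts: np.ndarray | None = None
    merge_log: list[tuple[int, int, str]] = field(default_factory=list)
    effective_ids: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centroids)


def kmeans_partition(
    X: np.ndarray,
    k: int,
    seed: int,
    n_init: int = 5,
    max_iter: int = 300,
) -> PartitionAssignment:
    """Cluster rows of ``X`` into ``k`` regions.

    Lloyd's algorithm with k-means++ seeding, best of ``n_init``
    restarts by within-cluster sum of squares; deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if not 1 <= k <= n:
        raise InputError(f"k must lie in [1, {n}], got {k}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed % (2**32),
    )
    assignment = km.fit_predict(X)
    return PartitionAssignment(
        centroids=km.cluster_centers_, assignment=assignment.astype(np.int64)
    )


def _class_counts(labels: np.ndarray) -> tuple[int, int]:
    pos = int((labels == 1).sum())
    return len(labels) - pos, pos


def make_local_problems(
    data: LabeledDataset,
    pa: PartitionAssignment,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[LabeledDataset]:
    """Turn a partition assignment into fit-able local datasets.

    A region is healthy when it holds at least ``min_size`` points and
    at least two of each class.  Unhealthy regions are merged (smallest
    first) into the nearest-centroid region that contains the class they
    lack; merges are recorded in ``pa.merge_log``.  If only one region
    survives it is returned as-is (pass-through), provided it is binary.
    """
    if len(pa.assignment) != data.n:
        raise InputError("assignment length does not match dataset size")
    if not data.has_both_classes():
        raise UnfittableError("training set contains a single class")

    groups: dict[int, np.ndarray] = {
        int(c): np.flatnonzero(pa.assignment == c)
        for c in np.unique(pa.assignment)
    }
    pa.per_partition_class_counts = np.array(
        [
            _class_counts(data.labels[groups[c]]) if c in groups else (0, 0)
            for c in range(pa.k)
        ],
        dtype=np.int64,
    )

    def centroid(idx: np.ndarray) -> np.ndarray:
        return data.features[idx].mean(axis=0)

    def healthy(idx: np.ndarray) -> bool:
        neg, pos = _class_counts(data.labels[idx])
        return len(idx) >= min_size and neg >= 2 and pos >= 2

    while len(groups) > 1:
        bad = sorted(
            (c for c in groups if not healthy(groups[c])),
            key=lambda c: (len(groups[c]), c),
        )
        if not bad:
            break
        src = bad[0]
        neg, pos = _class_counts(data.labels[groups[src]])
        if pos < 2:
            missing, reason = 1.0, "missing positive class" if pos == 0 else "too few positives"
        elif neg < 2:
            missing, reason = -1.0, "missing negative class" if neg == 0 else "too few negatives"
        else:
            missing, reason = None, "below minimum size"
        src_centroid = centroid(groups[src])
        candidates = [
            c
            for c in groups
            if c != src
            and (missing is None or (data.labels[groups[c]] == missing).sum() >= 2)
        ]
        if not candidates:  # nobody supplies the missing class: merge anywhere
            candidates = [c for c in groups if c != src]
        dists = {c: float(np.linalg.norm(centroid(groups[c]) - src_centroid)) for c in candidates}
        target = min(candidates, key=lambda c: (dists[c], c))
        groups[target] = np.sort(np.concatenate([groups[target], groups[src]]))
        del groups[src]
        pa.merge_log.append((src, target, reason))

    pa.effective_ids = sorted(groups)
    if len(groups) == 1:
        (only,) = groups.values()
        sole = data.subset(only)
        if not sole.has_both_classes():
            raise UnfittableError("partition repair left a single-class problem")
        log.debug("partition repair collapsed to a single region (pass-through)")
        return [sole]
    log.debug(
        "%d effective regions after %d merges", len(groups), len(pa.merge_log)
    )
    return [data.subset(groups[c]) for c in pa.effective_ids]
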