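"""Support-value ranking and the iterative pruning loop."""

import numpy as np
import pytest

from glocalsvm import (
    KernelSpec,
    LabeledDataset,
    PruneConfig,
    decision_value,
    fit_lssvm,
    prune_lssvm,
    support_values,
)
from glocalsvm.pruning import _removal_candidates

from conftest import random_small_problem

LINEAR = KernelSpec("linear")
RBF1 = KernelSpec("rbf", bandwidth_sq=1.0)


class TestSupportValues:
    def test_equal_alphas_rank_by_row_id(self, two_point_model):
        ranking = support_values(two_point_model)
        assert [rid for rid, _ in ranking] == [0, 1]
        assert ranking[0][1] == pytest.approx(2 / 3, abs=1e-10)

    def test_ranking_complete_and_descending(self):
        rng = np.random.default_rng(5)
        data = random_small_problem(rng)
        model = fit_lssvm(data, RBF1, 10.0)
        ranking = support_values(model)
        assert len(ranking) == data.n
        mags = [m for _, m in ranking]
        assert mags == sorted(mags, reverse=True)
        assert {rid for rid, _ in ranking} == set(data.row_ids)


class TestRemovalSelection:
    def test_lowest_alpha_point_removed_first(self):
        """With a near-duplicate of a training point added, the dense
        solve identifies the point with smallest |alpha| and the
        removal step discards exactly that one (respecting pinning)."""
        data = LabeledDataset(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 0.01]], [1.0, -1.0, 1.0], [0, 1, 2]
        )
        model = fit_lssvm(data, LINEAR, 1.0, standardize=False)
        labels_by_rowid = {0: 1.0, 1: -1.0, 2: 1.0}
        drop = _removal_candidates(model, 1, labels_by_rowid)
        # oracle: rank |alpha| from an independent dense solve
        n = data.n
        A = np.zeros((n + 1, n + 1))
        y = data.labels
        A[0, 1:], A[1:, 0] = y, y
        K = data.features @ data.features.T
        A[1:, 1:] = np.outer(y, y) * K + np.eye(n)
        alphas = np.linalg.solve(A, np.r_[0.0, np.ones(n)])[1:]
        # the negative point is pinned (last of its class): the removable
        # candidate with smallest |alpha| among the positives must match
        positives = [0, 2]
        expected = min(positives, key=lambda i: (abs(alphas[i]), i))
        assert drop == [expected]

    def test_class_never_emptied(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 2))
        y = np.r_[np.ones(1), -np.ones(9)]
        data = LabeledDataset(X, y, np.arange(10))
        model = fit_lssvm(data, RBF1, 1.0)
        labels_by_rowid = {int(r): float(l) for r, l in zip(data.row_ids, data.labels)}
        drop = _removal_candidates(model, 9, labels_by_rowid)
        kept = set(data.row_ids) - set(drop)
        kept_labels = {labels_by_rowid[r] for r in kept}
        assert kept_labels == {-1.0, 1.0}


class TestPruneLoop:
    def test_passthrough_below_minimum_size(self, blobs):
        small = blobs.subset(np.r_[np.arange(5), np.arange(30, 35)])
        sparse = prune_lssvm(small, RBF1, 10.0, PruneConfig(seed=0))
        assert np.array_equal(sparse.retained_row_ids, small.row_ids)

    def test_pruning_disabled_equals_plain_fit(self, blobs):
        cfg = PruneConfig(stop_tolerance=1e9, min_retained_fraction=1.0, seed=0)
        sparse = prune_lssvm(blobs, RBF1, 10.0, cfg)
        assert np.array_equal(sparse.retained_row_ids, blobs.row_ids)
        plain = fit_lssvm(blobs, RBF1, 10.0)
        q = blobs.features[:10]
        assert np.array_equal(decision_value(sparse.model, q), decision_value(plain, q))

    def test_step_ceiling_arithmetic(self, blobs):
        """step_fraction 0.5 removes ceil(0.5 * current) per iteration."""
        cfg = PruneConfig(
            step_fraction=0.5, stop_tolerance=1e9, min_retained_fraction=0.1,
            validation_fraction=0.2, min_positive_retained_fraction=0.0, seed=0,
        )
        sparse = prune_lssvm(blobs, RBF1, 1e4, cfg)
        counts = [c for c, _ in sparse.trajectory]
        assert counts[0] == 48  # 60 minus the 20% validation hold-out
        for prev, nxt in zip(counts, counts[1:]):
            assert prev - nxt == int(np.ceil(0.5 * prev))

    def test_trajectory_strictly_decreasing_and_floor(self, small_benchmark):
        sub = small_benchmark.subset(np.arange(200))
        cfg = PruneConfig(stop_tolerance=1e9, seed=1)
        sparse = prune_lssvm(sub, RBF1, 10.0, cfg)
        counts = [c for c, _ in sparse.trajectory]
        assert all(a > b for a, b in zip(counts, counts[1:]))
        frac = len(sparse.retained_row_ids) / sub.n
        assert cfg.min_retained_fraction <= frac <= 1.0
        assert set(sparse.retained_row_ids) <= set(sub.row_ids)

    def test_returned_metric_within_tolerance_of_best(self, small_benchmark):
        sub = small_benchmark.subset(np.arange(300))
        cfg = PruneConfig(seed=2)
        sparse = prune_lssvm(sub, RBF1, 10.0, cfg)
        scores = [s for _, s in sparse.trajectory]
        best = max(scores)
        retained = len(sparse.retained_row_ids)
        chosen = [s for c, s in sparse.trajectory if c == retained]
        assert chosen and chosen[0] >= best - cfg.stop_tolerance

    def test_seed_determinism(self, small_benchmark):
        sub = small_benchmark.subset(np.arange(250))
        a = prune_lssvm(sub, RBF1, 10.0, PruneConfig(seed=3))
        b = prune_lssvm(sub, RBF1, 10.0, PruneConfig(seed=3))
        assert np.array_equal(a.retained_row_ids, b.retained_row_ids)
        assert np.array_equal(a.model.alphas, b.model.alphas)
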