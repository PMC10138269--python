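"""Seeded synthetic benchmark: an imbalanced, nonlinear Gaussian mixture.

Emulates a medium-sized (10,000 point) binary problem with a 1:9
class ratio, nonlinear structure, and scattered individual minority
patterns: majority points come from a few broad-field Gaussian
components; minority points from more, smaller components, a fraction
of which sit inside majority components (ambiguous, nonlinear regions)
while the rest are scattered across the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import LabeledDataset
from .exceptions import ConfigError

__all__ = ["SynthConfig", "generate_synthetic", "write_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults give the benchmark conditions.

    n_total
        Total number of points (default 10,000).
    minority_fraction
        Fraction of +1 (minority) points; default 0.10, i.e. 1:9.
    n_majority_components / n_minority_components
        Gaussian mixture component counts per class (6 / 8).
    dims
        Feature dimensionality (2 — mixtures are planar by default).
    component_spread
        Within-component standard deviation of the majority class
        (0.5, feature units).
    field_extent
        Component centres are placed uniformly in ±field_extent (10).
    overlap
        Fraction of minority centres placed on the near shoulder
        (1.1-1.6 spreads) of a majority component, where the majority
        tail density rivals the minority core density — contested
        mixing zones that a majority-dominated global fit sacrifices
        (0.3).  The remaining centres sit on the far shoulder (2.8-3.3
        spreads): adjacent to the majority field, hence still embedded
        in it, but locally separable.
    minority_spread_factor
        Minority components are tighter than majority ones by this
        factor (0.45), so they form locally dense individual patterns
        scattered over the majority field.
    """

    n_total: int = 10_000
    minority_fraction: float = 0.10
    n_majority_components: int = 6
    n_minority_components: int = 8
    dims: int = 2
    component_spread: float = 0.5
    field_extent: float = 10.0
    overlap: float = 0.3
    minority_spread_factor: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minority_fraction < 0.5:
            raise ConfigError("minority_fraction must lie in (0, 0.5)")
        if self.n_majority_components < 1 or self.n_minority_components < 1:
            raise ConfigError("need at least one component per class")
        if self.n_total < 4:
            raise ConfigError("n_total too small")
        if round(self.minority_fraction * self.n_total) < 1:
            raise ConfigError("minority count rounds to zero")
        if self.component_spread <= 0 or self.field_extent <= 0:
            raise ConfigError("spread and extent must be positive")
        if not 0 <= self.overlap <= 1:
            raise ConfigError("overlap must lie in [0, 1]")
        if self.minority_spread_factor <= 0:
            raise ConfigError("minority_spread_factor must be positive")
        if self.dims < 1:
            raise ConfigError("dims must be >= 1")


def generate_synthetic(cfg: SynthConfig) -> LabeledDataset:
    """Draw one seeded dataset with exact per-class counts.

    Minority points are labelled +1 (they are the positive class of the
    evaluation convention), majority points -1.  Rows are shuffled so
    ordering carries no class signal; row ids are 0..n_total-1.
    """
    rng = np.random.default_rng(cfg.seed)
    n_min = int(round(cfg.minority_fraction * cfg.n_total))
    n_maj = cfg.n_total - n_min

    maj_centres = rng.uniform(
        -cfg.field_extent, cfg.field_extent, (cfg.n_majority_components, cfg.dims)
    )
    n_overlap = int(round(cfg.overlap * cfg.n_minority_components))
    minority_spread = cfg.component_spread * cfg.minority_spread_factor
    # every minority pattern is attached to a majority component so the
    # rare class is scattered over the majority field: near-shoulder
    # centres are locally contested (majority tail density of the same
    # order as the minority core), far-shoulder centres are adjacent
    # but locally separable
    host = rng.integers(0, cfg.n_majority_components, cfg.n_minority_components)
    direction = rng.normal(size=(cfg.n_minority_components, cfg.dims))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = np.empty((cfg.n_minority_components, 1))
    radius[:n_overlap, 0] = rng.uniform(1.1, 1.6, n_overlap)
    radius[n_overlap:, 0] = rng.uniform(
        2.8, 3.3, cfg.n_minority_components - n_overlap
    )
    min_centres = maj_centres[host] + radius * cfg.component_spread * direction

    def _draw(centres: np.ndarray, n: int, spread: float) -> np.ndarray:
        comp = rng.integers(0, len(centres), n)
        return centres[comp] + rng.normal(scale=spread, size=(n, cfg.dims))

    X = np.vstack([
        _draw(maj_centres, n_maj, cfg.component_spread),
        _draw(min_centres, n_min, minority_spread),
    ])
    y = np.concatenate([-np.ones(n_maj), np.ones(n_min)])
    perm = rng.permutation(cfg.n_total)
    return LabeledDataset(X[perm], y[perm], np.arange(cfg.n_total))


def write_fixture(cfg: SynthConfig, path: str | Path) -> LabeledDataset:
    """Generate a dataset and write it as canonical CSV; returns it."""
    from .io import write_dataset

    data = generate_synthetic(cfg)
    write_dataset(data, path)
    return data
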