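"""Dual-form least-squares support vector machine (LS-SVM).

The LS-SVM replaces the hinge loss of the standard SVM with a squared
error on the margin residuals, so training reduces to one symmetric
linear system instead of a quadratic programme.  For training points
(x_i, y_i), y_i in {-1, +1}, the dual solution (alpha, b) solves the
bordered KKT system

    [ 0   y^T          ] [ b     ]   [ 0   ]
    [ y   Omega + I/γ  ] [ alpha ] = [ 1_N ]

with Omega_ij = y_i y_j k(x_i, x_j).  The decision function is
f(x) = sum_i alpha_i y_i k(x_i, x) + b; the weight vector w and feature
map phi are never materialised (kernel trick).  Every training point has
a nonzero support value alpha_k = γ e_k, proportional to its residual —
the handle the pruning layer uses to rank informativeness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .exceptions import ConfigError, InputError, NumericalError, UnfittableError

__all__ = [
    "LabeledDataset",
    "KernelSpec",
    "Scaler",
    "LSSVMModel",
    "kernel_matrix",
    "fit_lssvm",
    "decision_value",
    "predict",
]

#: Relative residual above which a solve is considered failed.
SOLVE_RESIDUAL_TOL = 1e-8


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledDataset:
    """A feature matrix with ±1 labels and stable row identifiers.

    ``row_ids`` are the original row indices of each point and survive
    subsetting, so provenance of pruned / pooled points can always be
    traced back to the full training set.
    """

    features: np.ndarray
    labels: np.ndarray
    row_ids: np.ndarray
    label_mapping: dict | None = None

    def __post_init__(self) -> None:
        X = np.ascontiguousarray(np.asarray(self.features, dtype=np.float64))
        if X.ndim != 2:
            raise InputError(f"features must be 2-D, got shape {X.shape}")
        y = np.asarray(self.labels, dtype=np.float64).ravel()
        rid = np.asarray(self.row_ids, dtype=np.int64).ravel()
        if not (len(X) == len(y) == len(rid)):
            raise InputError(
                f"inconsistent lengths: {len(X)} features, {len(y)} labels, "
                f"{len(rid)} row_ids"
            )
        if not np.isfinite(X).all():
            raise InputError("features contain non-finite values")
        if not np.isin(y, (-1.0, 1.0)).all():
            raise InputError("labels must be -1 or +1")
        if len(np.unique(rid)) != len(rid):
            raise InputError("row_ids must be unique")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "row_ids", rid)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def minority_fraction(self) -> float:
        pos = int((self.labels == 1).sum())
        return min(pos, self.n - pos) / self.n

    def class_counts(self) -> tuple[int, int]:
        """(negative count, positive count)."""
        pos = int((self.labels == 1).sum())
        return self.n - pos, pos

    def has_both_classes(self) -> bool:
        return 0 < (self.labels == 1).sum() < self.n

    def subset(self, index) -> "LabeledDataset":
        """Positional subset preserving row identifiers."""
        index = np.asarray(index)
        return LabeledDataset(
            self.features[index], self.labels[index], self.row_ids[index],
            label_mapping=self.label_mapping,
        )


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its parameters.

    RBF follows the LS-SVMlab convention k(a, b) = exp(-||a-b||^2 / σ²)
    with ``bandwidth_sq`` = σ² in (squared) feature-space units.
    """

    family: str = "rbf"
    bandwidth_sq: float = 1.0
    degree: int = 3
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "linear", "polynomial"):
            raise ConfigError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and not self.bandwidth_sq > 0:
            raise ConfigError("bandwidth_sq must be positive for the RBF kernel")
        if self.family == "polynomial" and self.degree < 1:
            raise ConfigError("polynomial degree must be >= 1")


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-score transform frozen at fit time."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)  # constant features pass through
        return cls(mean=mean, std=std)

    @classmethod
    def identity(cls, d: int) -> "Scaler":
        return cls(mean=np.zeros(d), std=np.ones(d))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass(frozen=True)
class LSSVMModel:
    """Fitted dual-form LS-SVM.

    ``support_features`` are stored in the scaler's output space;
    ``decision_value`` applies ``scaler`` to queries before the kernel.
    """

    kernel: KernelSpec
    gamma: float
    support_features: np.ndarray
    support_labels: np.ndarray
    alphas: np.ndarray
    bias: float
    scaler: Scaler
    support_row_ids: np.ndarray

    @property
    def n_support(self) -> int:
        return len(self.alphas)

    def with_scaler(self, scaler: Scaler) -> "LSSVMModel":
        return replace(self, scaler=scaler)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = k(A_i, B_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]} columns"
        )
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise InputError("kernel inputs must be finite")
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    if spec.family == "rbf":
        sq = cdist(A, B, metric="sqeuclidean")
        return np.exp(-sq / spec.bandwidth_sq)
    if spec.family == "linear":
        return A @ B.T
    # polynomial
    return (A @ B.T + spec.offset) ** spec.degree


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def fit_lssvm(
    data: LabeledDataset,
    spec: KernelSpec,
    gamma: float,
    *,
    standardize: bool = True,
) -> LSSVMModel:
    """Train an LS-SVM by a direct dense solve of the bordered KKT system.

    Parameters
    ----------
    data
        Training points with both classes present, N >= 2.
    spec
        Kernel specification (bandwidth in standardised units when
        ``standardize`` is on).
    gamma
        Regularisation weight γ > 0 trading margin against squared
        residuals; larger values fit the training set more closely.
    standardize
        Fit a per-feature z-score scaler from ``data`` and apply it
        before the kernel (default).  Pass False when features are
        already in the desired space; an identity scaler is stored.
    """
    if not gamma > 0:
        raise ConfigError(f"gamma must be positive, got {gamma}")
    if data.n < 2:
        raise UnfittableError(f"need at least 2 training points, got {data.n}")
    if not data.has_both_classes():
        raise UnfittableError("training data contains a single class")

    scaler = Scaler.fit(data.features) if standardize else Scaler.identity(data.n_features)
    Xs = scaler.transform(data.features)
    y = data.labels
    n = data.n

    K = kernel_matrix(Xs, Xs, spec)
    K *= y[:, None]
    K *= y[None, :]  # K is now Omega, in place

    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = K
    del K
    idx = np.arange(1, n + 1)
    A[idx, idx] += 1.0 / gamma

    rhs = np.ones(n + 1)
    rhs[0] = 0.0
    try:
        sol = scipy.linalg.solve(A, rhs, assume_a="sym")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise NumericalError(f"KKT solve failed: {exc}") from exc

    residual = np.linalg.norm(A @ sol - rhs)
    rel = residual / np.linalg.norm(rhs)
    if not np.isfinite(rel) or rel > SOLVE_RESIDUAL_TOL:
        import scipy.sparse.linalg as spla

        cond_est = spla.onenormest(A) * spla.onenormest(np.linalg.pinv(A))
        raise NumericalError(
            f"ill-conditioned KKT system: relative residual {rel:.3e} "
            f"(condition estimate ~{cond_est:.3e}); increase gamma "
            "regularisation or rescale features"
        )

    return LSSVMModel(
        kernel=spec,
        gamma=float(gamma),
        support_features=Xs,
        support_labels=y,
        alphas=sol[1:],
        bias=float(sol[0]),
        scaler=scaler,
        support_row_ids=data.row_ids,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def decision_value(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """f(x) = Σ_i α_i y_i k(x_i, x) + b for each row of ``X``."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.zeros(0)
    d = model.support_features.shape[1]
    if X.shape[1] != d:
        raise InputError(f"query has {X.shape[1]} features, model expects {d}")
    Xs = model.scaler.transform(X)
    K = kernel_matrix(Xs, model.support_features, model.kernel)
    return K @ (model.alphas * model.support_labels) + model.bias


def predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Signed class prediction; a decision value of exactly 0 maps to +1."""
    dv = decision_value(model, X)
    return np.where(dv >= 0, 1.0, -1.0)
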