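"""Dataset CSV I/O and versioned model archives.

Datasets travel as comma-separated UTF-8 text with a header row, '.'
decimals, and one label column.  Model archives are NumPy ``.npz``
files carrying a JSON metadata document (kernel, γ, scaler statistics,
provenance, timing) next to the dense numeric payloads, so they are
portable and auditable without unpickling arbitrary objects.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import KernelSpec, LabeledDataset, LSSVMModel, Scaler
from .exceptions import InputError, ModelIOError
from .pipeline import GLocalConfig, GLocalModel, TimingReport
from .pruning import PruneConfig
from .tuning import TuningGrid

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    label_column: str = "label",
    positive_policy: str | float = "minority",
) -> LabeledDataset:
    """Read a delimited text dataset and map labels to ±1.

    ``positive_policy="minority"`` maps the rarer raw label to +1
    (the evaluation convention treats the minority class as positive);
    a frequency tie resolves to the lexicographically larger raw label
    with a warning.  Any other policy value names the raw label to map
    to +1.  The applied mapping is recorded on the returned dataset.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if label_column not in df.columns:
        raise InputError(
            f"label column {label_column!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    raw = df[label_column]
    values = sorted(raw.unique(), key=str)
    if len(values) != 2:
        raise InputError(
            f"label column must hold exactly 2 distinct values, found {values}"
        )
    feats = df.drop(columns=[label_column])
    try:
        X = feats.astype(np.float64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise InputError(f"non-numeric feature cells in {path}: {exc}") from exc

    if positive_policy == "minority":
        counts = raw.value_counts()
        if counts[values[0]] == counts[values[1]]:
            positive = values[1]  # lexicographically larger
            warnings.warn(
                "label frequencies tied; mapping lexicographically larger "
                f"label {positive!r} to +1"
            )
        else:
            positive = counts.idxmin()
    else:
        if positive_policy not in values:
            raise InputError(
                f"positive label {positive_policy!r} not among labels {values}"
            )
        positive = positive_policy
    mapping = {v: (1 if v == positive else -1) for v in values}
    y = raw.map(mapping).to_numpy(dtype=np.float64)
    return LabeledDataset(X, y, np.arange(len(df)), label_mapping=mapping)


def write_dataset(data: LabeledDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect (header, comma, '.', UTF-8)."""
    df = pd.DataFrame(
        data.features, columns=[f"x{i}" for i in range(data.n_features)]
    )
    df["label"] = data.labels.astype(np.int64)
    # %.17g guarantees float64 round-trips through text exactly
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

def _kernel_to_dict(spec: KernelSpec) -> dict:
    return asdict(spec)


def _kernel_from_dict(d: dict) -> KernelSpec:
    return KernelSpec(**d)


def _lssvm_meta(model: LSSVMModel) -> dict:
    return {
        "kernel": _kernel_to_dict(model.kernel),
        "gamma": model.gamma,
        "bias": model.bias,
    }


def _lssvm_arrays(model: LSSVMModel, prefix: str = "") -> dict:
    return {
        f"{prefix}support_features": model.support_features,
        f"{prefix}support_labels": model.support_labels,
        f"{prefix}alphas": model.alphas,
        f"{prefix}support_row_ids": model.support_row_ids,
        f"{prefix}scaler_mean": model.scaler.mean,
        f"{prefix}scaler_std": model.scaler.std,
    }


def _lssvm_from(meta: dict, arrays, prefix: str = "") -> LSSVMModel:
    return LSSVMModel(
        kernel=_kernel_from_dict(meta["kernel"]),
        gamma=float(meta["gamma"]),
        bias=float(meta["bias"]),
        support_features=arrays[f"{prefix}support_features"],
        support_labels=arrays[f"{prefix}support_labels"],
        alphas=arrays[f"{prefix}alphas"],
        support_row_ids=arrays[f"{prefix}support_row_ids"],
        scaler=Scaler(
            mean=arrays[f"{prefix}scaler_mean"], std=arrays[f"{prefix}scaler_std"]
        ),
    )


def _floats(values) -> list[float] | None:
    return None if values is None else [float(v) for v in values]


def _config_to_dict(cfg: GLocalConfig) -> dict:
    grid = asdict(cfg.grid)
    grid["gamma_values"] = _floats(grid["gamma_values"])
    grid["bandwidth_sq_values"] = _floats(grid["bandwidth_sq_values"])
    kernel_field = (
        lambda k: k if k in ("tune", None) else _kernel_to_dict(k)
    )
    return {
        "n_partitions": cfg.n_partitions,
        "kernel": kernel_field(cfg.kernel),
        "gamma": cfg.gamma if isinstance(cfg.gamma, str) else float(cfg.gamma),
        "global_kernel": kernel_field(cfg.global_kernel),
        "global_gamma": (
            cfg.global_gamma
            if isinstance(cfg.global_gamma, str) or cfg.global_gamma is None
            else float(cfg.global_gamma)
        ),
        "prune": asdict(cfg.prune),
        "grid": grid,
        "seed": cfg.seed,
        "min_partition_size": cfg.min_partition_size,
        "prune_locals": cfg.prune_locals,
        "sparse_global": cfg.sparse_global,
        "kmeans_n_init": cfg.kmeans_n_init,
        "kmeans_max_iter": cfg.kmeans_max_iter,
        "n_jobs": cfg.n_jobs,
    }


def _config_from_dict(d: dict) -> GLocalConfig:
    d = dict(d)
    if d["kernel"] != "tune":
        d["kernel"] = _kernel_from_dict(d["kernel"])
    for key in ("global_kernel", "global_gamma"):
        d.setdefault(key, None)
    if d["global_kernel"] not in ("tune", None):
        d["global_kernel"] = _kernel_from_dict(d["global_kernel"])
    grid = dict(d["grid"])
    for key in ("gamma_values", "bandwidth_sq_values"):
        if grid.get(key) is not None:
            grid[key] = tuple(grid[key])
    d["prune"] = PruneConfig(**d["prune"])
    d["grid"] = TuningGrid(**grid)
    return GLocalConfig(**d)


def save_model(model: LSSVMModel | GLocalModel, path: str | Path) -> None:
    """Serialise a fitted model to a versioned ``.npz`` archive."""
    path = Path(path)
    if isinstance(model, LSSVMModel):
        meta = {
            "format_version": FORMAT_VERSION,
            "type": "lssvm",
            **_lssvm_meta(model),
        }
        arrays = _lssvm_arrays(model)
    elif isinstance(model, GLocalModel):
        meta = {
            "format_version": FORMAT_VERSION,
            "type": "glocal",
            "global": _lssvm_meta(model.global_model),
            "local_summaries": list(model.local_summaries),
            "timing": asdict(model.timing),
            "config": _config_to_dict(model.config) if model.config else None,
            "merge_log": list(model.partition.merge_log) if model.partition else [],
        }
        arrays = _lssvm_arrays(model.global_model, prefix="global_")
        arrays.update(
            pool_features=model.merged_pool.features,
            pool_labels=model.merged_pool.labels,
            pool_row_ids=model.merged_pool.row_ids,
            pool_partition_ids=model.pool_partition_ids,
        )
    else:
        raise ModelIOError(f"cannot serialise object of type {type(model).__name__}")
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> LSSVMModel | GLocalModel:
    """Load a model archive; decision values reproduce bitwise."""
    path = Path(path)
    try:
        with np.load(path) as arrays:
            meta = json.loads(bytes(arrays["__meta__"]).decode())
            version = meta.get("format_version")
            if version != FORMAT_VERSION:
                raise ModelIOError(
                    f"archive format version {version} not supported "
                    f"(expected {FORMAT_VERSION}); re-export the model"
                )
            if meta["type"] == "lssvm":
                return _lssvm_from(meta, arrays)
            if meta["type"] == "glocal":
                gm = _lssvm_from(meta["global"], arrays, prefix="global_")
                pool = LabeledDataset(
                    arrays["pool_features"],
                    arrays["pool_labels"],
                    arrays["pool_row_ids"],
                )
                cfg = (
                    _config_from_dict(meta["config"]) if meta.get("config") else None
                )
                return GLocalModel(
                    global_model=gm,
                    merged_pool=pool,
                    pool_partition_ids=arrays["pool_partition_ids"],
                    local_summaries=tuple(meta["local_summaries"]),
                    timing=TimingReport(**meta["timing"]),
                    partition=None,
                    config=cfg,
                )
            raise ModelIOError(f"unknown archive type {meta['type']!r}")
    except ModelIOError:
        raise
    except (OSError, zipfile.BadZipFile, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"corrupt or unreadable model archive {path}: {exc}") from exc
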