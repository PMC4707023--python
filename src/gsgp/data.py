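"""Tabular regression datasets: CSV I/O, splits, and synthetic generation.

Datasets follow the usual convention for the benchmark files this engine
targets: every column is a numeric feature except the last one, which holds
the known target values.

The synthetic generator stands in for the study's external benchmarks
(three pharmacokinetic endpoints — oral bioavailability %F, median lethal
dose LD50, plasma protein binding PPB — plus concrete strength and a
Parkinson voice dataset).  Named presets reproduce their shapes (rows x
features) with a hidden nonlinear ground-truth expression over a handful of
variables plus Gaussian noise, so every stage of the engine is testable
without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expressions import (
    ExpressionNode,
    constant,
    evaluate_tree,
    max_variable_index,
    operator_node,
    variable,
)

__all__ = [
    "Dataset",
    "SplitSpec",
    "DatasetError",
    "read_csv_dataset",
    "write_csv_dataset",
    "split",
    "generate_synthetic_dataset",
    "synthetic_preset",
    "PRESETS",
]


class DatasetError(ValueError):
    """Unreadable, ragged, non-numeric, or otherwise invalid dataset."""


@dataclass
class Dataset:
    """An in-memory regression dataset: features X and target y."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise DatasetError("X must be (n, p) and y length n")
        if self.X.shape[0] < 2:
            raise DatasetError("a dataset needs at least 2 instances")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise DatasetError("X and y must be finite (no missing values)")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Random uniform train/test partition; 70/30 by default."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DatasetError("train_fraction must be in (0, 1)")


def read_csv_dataset(path, has_header: bool = False, name: str | None = None) -> Dataset:
    """Load a rectangular numeric CSV whose last column is the target."""
    try:
        df = pd.read_csv(
            path, header=0 if has_header else None, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise DatasetError(f"{path}: ragged or unparseable CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise DatasetError(f"{path}: need at least one feature column plus a target")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        cell = df.loc[row, col]
        label = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise DatasetError(f"{path}: {label} cell at data row {row}, column {col!r}")
    feature_names = [str(c) for c in df.columns[:-1]] if has_header else None
    return Dataset(
        X=numeric.iloc[:, :-1].to_numpy(dtype=float),
        y=numeric.iloc[:, -1].to_numpy(dtype=float),
        feature_names=feature_names,
        name=name or str(path),
    )


def write_csv_dataset(dataset: Dataset, path, header: bool = True) -> None:
    """Write a dataset back to CSV (features then target).

    Floats are printed with 17 significant digits so a write/read round
    trip is bit-exact.
    """
    names = dataset.feature_names or [f"x{i}" for i in range(dataset.n_features)]
    df = pd.DataFrame(dataset.X, columns=names)
    df["target"] = dataset.y
    df.to_csv(path, index=False, header=header, float_format="%.17g")


def split(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive row partition; reproducible from the seed."""
    n = dataset.n_instances
    n_train = int(round(spec.train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise DatasetError(
            f"split of {n} rows at fraction {spec.train_fraction} leaves a side empty"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (
        Dataset(dataset.X[tr], dataset.y[tr], dataset.feature_names, f"{dataset.name}[train]"),
        Dataset(dataset.X[te], dataset.y[te], dataset.feature_names, f"{dataset.name}[test]"),
    )


def generate_synthetic_dataset(
    n_instances: int,
    n_features: int,
    ground_truth: ExpressionNode,
    noise_sd: float = 0.1,
    seed: int | None = None,
    box: tuple[float, float] = (-1.0, 1.0),
    name: str = "synthetic",
) -> Dataset:
    """Features uniform in a box; target = ground_truth(X) + N(0, noise_sd)."""
    if noise_sd < 0:
        raise DatasetError("noise_sd must be >= 0")
    if max_variable_index(ground_truth) >= n_features:
        raise DatasetError("ground truth uses more variables than n_features")
    lo, hi = box
    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(n_instances, n_features))
    y = evaluate_tree(ground_truth, X) + rng.normal(0.0, noise_sd, size=n_instances)
    return Dataset(X=X, y=y, name=name)


def _x(i: int) -> ExpressionNode:
    return variable(i)


def _add(a, b):
    return operator_node("add", a, b)


def _sub(a, b):
    return operator_node("sub", a, b)


def _mul(a, b):
    return operator_node("mul", a, b)


def _div(a, b):
    return operator_node("div", a, b)


def _rational_truth(i0: int = 0) -> ExpressionNode:
    """x_i0*x_{i0+1} + x_{i0+2} / (1.5 + x_{i0+3}^2) - a smooth nonlinear
    multi-variable target expressible in the engine's own primitive set."""
    return _add(
        _mul(_x(i0), _x(i0 + 1)),
        _div(_x(i0 + 2), _add(constant(1.5), _mul(_x(i0 + 3), _x(i0 + 3)))),
    )


def default_ground_truth(n_features: int) -> ExpressionNode:
    """A nonlinear target using as many variables as the width allows."""
    if n_features >= 6:
        return _interaction_truth()
    if n_features >= 4:
        return _rational_truth()
    if n_features >= 2:
        return _add(_mul(_x(0), _x(1)), _x(0))
    return _mul(_x(0), _x(0))


def _interaction_truth() -> ExpressionNode:
    """x0*(x1 + x2*x3) - x4/(1.2 + x5^2), used for the wider presets."""
    return _sub(
        _mul(_x(0), _add(_x(1), _mul(_x(2), _x(3)))),
        _div(_x(4), _add(constant(1.2), _mul(_x(5), _x(5)))),
    )


def _scaled(truth: ExpressionNode, offset: float, scale: float) -> ExpressionNode:
    """offset + scale * truth — places the target on its endpoint's natural
    units, so that absolute mutation steps (0.01, 0.1, 1) mean for the
    synthetic data what they meant for the real benchmarks."""
    return _add(constant(offset), _mul(constant(scale), truth))


@dataclass(frozen=True)
class _Preset:
    n_instances: int
    n_features: int
    truth: ExpressionNode
    noise_sd: float


#: Named shapes emulating the five study benchmarks (rows x features; the
#: target column is extra).  Targets are hidden nonlinear expressions over
#: the first few variables — the remaining features are decoys, as in real
#: molecular-descriptor tables where most descriptors are uninformative —
#: placed on each endpoint's natural scale (percentages for %F and PPB,
#: mg/kg for LD50, MPa for concrete strength, a clinical score for the
#: Parkinson voice data).  Noise is 1/20 of the target scale factor.
PRESETS: dict[str, _Preset] = {
    "bioavailability-like": _Preset(260, 241, _scaled(_interaction_truth(), 50.0, 30.0), 1.5),
    "ld50-like": _Preset(234, 626, _scaled(_interaction_truth(), 1500.0, 800.0), 40.0),
    "ppb-like": _Preset(131, 626, _scaled(_rational_truth(), 60.0, 30.0), 1.5),
    "concrete-like": _Preset(1030, 8, _scaled(_interaction_truth(), 40.0, 20.0), 1.0),
    "parkinson-like": _Preset(6000, 19, _scaled(_interaction_truth(), 30.0, 15.0), 0.75),
}


def synthetic_preset(
    preset: str, seed: int | None = None, noise_sd: float | None = None
) -> Dataset:
    """Generate one of the named study-shaped synthetic datasets."""
    if preset not in PRESETS:
        raise DatasetError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    p = PRESETS[preset]
    return generate_synthetic_dataset(
        n_instances=p.n_instances,
        n_features=p.n_features,
        ground_truth=p.truth,
        noise_sd=p.noise_sd if noise_sd is None else noise_sd,
        seed=seed,
        name=preset,
    )
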