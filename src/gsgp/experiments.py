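"""Multi-run experiment harness: the benchmark protocol at configurable scale.

For each system (standard / elitist GSGP), each mutation step, and each run
index, the harness draws a fresh 70/30 split (per-run seed = base seed +
run index, so the two systems see paired partitions), runs one seeded
evolution, and aggregates per-generation *medians* of the best individual's
training fitness, test fitness and size — medians, not means, because
run-to-run size distributions are heavily skewed.  Final best-model sizes
are compared between systems with the Shapiro-Wilk-gated Mann-Whitney test.

All artifacts (median curves, final-size table, comparison report, manifest
with every seed and resolved parameter) are plain CSV/JSON and are byte-
reproducible from the ExperimentSpec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, SplitSpec, read_csv_dataset, split, synthetic_preset, PRESETS
from .evolution import RunConfig, run_evolution
from .growth import SizeComparison, compare_final_sizes

__all__ = ["ExperimentSpec", "ExperimentReport", "run_experiment"]

_SYSTEMS = ("standard", "elitist")


@dataclass(frozen=True)
class ExperimentSpec:
    """What to run: dataset, systems, mutation steps, run count, base config.

    ``dataset`` is a preset name, a CSV path, or an in-memory
    :class:`~gsgp.data.Dataset`.  ``n_runs`` defaults to the benchmark
    protocol's 30 independent runs; the command line exposes a scaled-down
    default instead.
    """

    dataset: object
    systems: tuple[str, ...] = _SYSTEMS
    ms_values: tuple[float, ...] = (0.01, 0.1, 1.0)
    n_runs: int = 30
    base_config: RunConfig = field(default_factory=RunConfig)
    train_fraction: float = 0.7
    seed: int = 0
    csv_has_header: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if any(ms <= 0 for ms in self.ms_values):
            raise ValueError("mutation steps must be positive")
        unknown = set(self.systems) - set(_SYSTEMS)
        if unknown:
            raise ValueError(f"unknown systems: {sorted(unknown)}")


@dataclass
class ExperimentReport:
    """Aggregated outcome of one experiment."""

    spec: ExperimentSpec
    #: (system, ms) -> per-generation DataFrame of median best_train,
    #: best_test, best_size and operator success rates across runs
    median_curves: dict
    #: one row per (system, ms, run): final best train/test RMSE and size
    finals: pd.DataFrame
    #: ms -> SizeComparison of standard vs elitist final sizes
    comparisons: dict
    #: (system, ms) -> list of per-run per-generation DataFrames
    per_run: dict


def _resolve_dataset(spec: ExperimentSpec) -> Dataset:
    if isinstance(spec.dataset, Dataset):
        return spec.dataset
    if isinstance(spec.dataset, str) and spec.dataset in PRESETS:
        return synthetic_preset(spec.dataset, seed=spec.seed)
    return read_csv_dataset(spec.dataset, has_header=spec.csv_has_header)


def _rates(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["xo_success_rate"] = frame["xo_successes"] / frame["xo_events"].replace(0, np.nan)
    frame["mut_success_rate"] = frame["mut_successes"] / frame["mut_events"].replace(0, np.nan)
    return frame


def _median_curves(frames: list[pd.DataFrame]) -> pd.DataFrame:
    stacked = pd.concat(frames, ignore_index=True)
    cols = ["best_train", "best_test", "best_size", "median_size",
            "xo_success_rate", "mut_success_rate"]
    stacked["best_size"] = stacked["best_size"].astype(float)
    return stacked.groupby("generation")[cols].median().reset_index()


def run_experiment(spec: ExperimentSpec) -> ExperimentReport:
    """Run the full system x mutation-step x run grid and aggregate."""
    outdir = None
    if spec.output_dir is not None:
        outdir = Path(spec.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        try:
            probe.write_text("")
            probe.unlink()
        except OSError as exc:  # fail before any run
            raise OSError(f"output directory {outdir} is not writable") from exc

    dataset = _resolve_dataset(spec)
    per_run: dict = {}
    final_rows = []
    for system in spec.systems:
        for ms in spec.ms_values:
            frames = []
            for run in range(spec.n_runs):
                run_seed = spec.seed + run
                train, test = split(dataset, SplitSpec(spec.train_fraction, seed=run_seed))
                config = replace(
                    spec.base_config,
                    seed=run_seed,
                    mutation_step=ms,
                    elitist_replacement=(system == "elitist"),
                )
                trace = run_evolution(config, train, test)
                frames.append(_rates(trace.to_frame()))
                best = trace.best
                final_rows.append(
                    {
                        "system": system,
                        "ms": ms,
                        "run": run,
                        "seed": run_seed,
                        "final_train": best.train_fitness,
                        "final_test": best.test_fitness,
                        "final_size": best.size,
                    }
                )
                del trace  # drop the pedigree; only summaries are kept
            per_run[(system, ms)] = frames

    finals = pd.DataFrame(final_rows)
    median_curves = {key: _median_curves(frames) for key, frames in per_run.items()}

    comparisons: dict = {}
    if {"standard", "elitist"} <= set(spec.systems) and spec.n_runs >= 3:
        for ms in spec.ms_values:
            sizes = {
                system: finals.loc[
                    (finals["system"] == system) & (finals["ms"] == ms), "final_size"
                ].tolist()
                for system in ("standard", "elitist")
            }
            comparisons[ms] = compare_final_sizes(sizes["standard"], sizes["elitist"])

    report = ExperimentReport(
        spec=spec,
        median_curves=median_curves,
        finals=finals,
        comparisons=comparisons,
        per_run=per_run,
    )
    if outdir is not None:
        _write_artifacts(report, outdir)
    return report


def _manifest(spec: ExperimentSpec) -> dict:
    dataset = (
        spec.dataset if isinstance(spec.dataset, str) else getattr(spec.dataset, "name", "in-memory")
    )
    return {
        "dataset": dataset,
        "systems": list(spec.systems),
        "ms_values": list(spec.ms_values),
        "n_runs": spec.n_runs,
        "train_fraction": spec.train_fraction,
        "base_seed": spec.seed,
        "per_run_seeds": [spec.seed + r for r in range(spec.n_runs)],
        "base_config": dataclasses.asdict(spec.base_config),
    }


def _write_artifacts(report: ExperimentReport, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(_manifest(report.spec), indent=2, sort_keys=True)
    )
    for (system, ms), curve in report.median_curves.items():
        curve.to_csv(outdir / f"medians_{system}_ms{ms:g}.csv", index=False)
    report.finals.to_csv(outdir / "final_models.csv", index=False)
    summary = {
        "median_final_size": {
            f"{system}_ms{ms:g}": float(
                report.finals.loc[
                    (report.finals["system"] == system) & (report.finals["ms"] == ms),
                    "final_size",
                ]
                .astype(float)
                .median()
            )
            for system in report.spec.systems
            for ms in report.spec.ms_values
        },
        "size_comparisons": {
            f"ms{ms:g}": cmp.to_json() for ms, cmp in report.comparisons.items()
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
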