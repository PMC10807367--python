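"""Experiment harness: repeated seeded runs with per-k aggregation.

Reproduces the standard wrapper-selection protocol: for each KNN neighbor
count and each repeat, draw a fresh stratified split, run the binary swarm
on the wrapper fitness, and score the best subset on the held-out test
partition.  Repeats are aggregated into mean and sample standard deviation
of test accuracy and selected-feature count; convergence histories are
exportable as tidy CSV.

Per-run seeds are derived as ``master_seed + run_index`` (run_index counts
runs in k-major order), so any individual run can be replayed in isolation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .data import (
    LabeledDataset,
    SplitSpec,
    SyntheticDataset,
    SyntheticSpec,
    generate_synthetic,
    load_table,
)
from .fitness import FitnessWeights
from .model import SandCatFeatureSelector
from .optimizer import OptimizerConfig

__all__ = [
    "ExperimentConfig",
    "RunRecord",
    "AggregateRecord",
    "ExperimentReport",
    "run_experiment",
    "recovery_metrics",
    "export_convergence",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs: data source, settings, seeds."""

    source: Union[str, Path, LabeledDataset, SyntheticSpec]
    label_column: Optional[str] = None
    k_values: Sequence[int] = (3, 5, 7)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    n_repeats: int = 5
    master_seed: int = 0
    resplit_per_repeat: bool = True
    output_dir: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.k_values:
            raise ValueError("need at least one k value")


@dataclass
class RunRecord:
    """One (k, repeat) run: scores plus the convergence history."""

    k: int
    repeat: int
    seed: int
    test_accuracy: float
    n_selected: int
    best_fitness: float
    runtime_s: float
    history: np.ndarray
    support: np.ndarray


@dataclass
class AggregateRecord:
    """Per-k mean/std of accuracy (as a percentage) and subset size."""

    k: int
    n_runs: int
    accuracy_mean_pct: float
    accuracy_std_pct: float
    n_selected_mean: float
    n_selected_std: float


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    runs: list[RunRecord]
    aggregates: list[AggregateRecord]
    informative_indices: Optional[np.ndarray] = None

    def runs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [r.k for r in self.runs],
                "repeat": [r.repeat for r in self.runs],
                "seed": [r.seed for r in self.runs],
                "test_accuracy": [r.test_accuracy for r in self.runs],
                "n_selected": [r.n_selected for r in self.runs],
                "best_fitness": [r.best_fitness for r in self.runs],
            }
        )

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [a.k for a in self.aggregates],
                "n_runs": [a.n_runs for a in self.aggregates],
                "accuracy_mean_pct": [
                    round(a.accuracy_mean_pct, 2) for a in self.aggregates
                ],
                "accuracy_std_pct": [
                    round(a.accuracy_std_pct, 2) for a in self.aggregates
                ],
                "n_selected_mean": [a.n_selected_mean for a in self.aggregates],
                "n_selected_std": [a.n_selected_std for a in self.aggregates],
            }
        )


def _std(values: np.ndarray) -> float:
    """Sample (n-1) standard deviation; 0 by convention for a single run."""
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def _resolve_dataset(
    config: ExperimentConfig,
) -> tuple[LabeledDataset, Optional[np.ndarray]]:
    src = config.source
    if isinstance(src, SyntheticSpec):
        spec = src if src.seed is not None else replace(src, seed=config.master_seed)
        synth = generate_synthetic(spec)
        return synth.dataset, synth.informative_indices
    if isinstance(src, SyntheticDataset):
        return src.dataset, src.informative_indices
    if isinstance(src, LabeledDataset):
        return src, None
    return load_table(src, label_column=config.label_column), None


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full repeated protocol and (optionally) write report files."""
    dataset, informative = _resolve_dataset(config)
    runs: list[RunRecord] = []
    run_index = 0
    for k in config.k_values:
        for repeat in range(config.n_repeats):
            seed = (config.master_seed + run_index) % _SEED_MOD
            if not config.resplit_per_repeat:
                # fixed-split mode: every repeat reuses the repeat-0 split
                # seed of its k block while the swarm seed still varies
                split_seed = (config.master_seed + (run_index - repeat)) % _SEED_MOD
            else:
                split_seed = seed
            model = SandCatFeatureSelector.from_dataset(
                dataset,
                k=k,
                alpha=config.weights.alpha,
                beta=config.weights.beta,
                n_agents=config.optimizer.n_agents,
                max_iter=config.optimizer.max_iter,
                transfer=config.optimizer.transfer,
                s_M=config.optimizer.s_M,
                split_spec=replace(config.split, seed=split_seed),
            )
            t0 = time.perf_counter()
            try:
                result = model.fit(seed=seed)
            except Exception as exc:
                raise RuntimeError(f"run k={k} repeat={repeat} failed: {exc}") from exc
            runs.append(
                RunRecord(
                    k=k,
                    repeat=repeat,
                    seed=seed,
                    test_accuracy=result.test_accuracy,
                    n_selected=result.n_selected,
                    best_fitness=result.best_fitness,
                    runtime_s=time.perf_counter() - t0,
                    history=result.history,
                    support=result.support,
                )
            )
            run_index += 1
    aggregates = []
    for k in config.k_values:
        accs = np.array([r.test_accuracy for r in runs if r.k == k])
        sizes = np.array([float(r.n_selected) for r in runs if r.k == k])
        aggregates.append(
            AggregateRecord(
                k=k,
                n_runs=accs.size,
                accuracy_mean_pct=float(accs.mean() * 100),
                accuracy_std_pct=_std(accs * 100),
                n_selected_mean=float(sizes.mean()),
                n_selected_std=_std(sizes),
            )
        )
    report = ExperimentReport(
        config=config, runs=runs, aggregates=aggregates, informative_indices=informative
    )
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def recovery_metrics(
    support: np.ndarray,
    informative_indices: np.ndarray,
) -> tuple[float, float]:
    """Precision and recall of informative-feature recovery.

    Only meaningful on synthetic data where the informative set is known.
    """
    selected = set(np.flatnonzero(np.asarray(support)).tolist())
    informative = set(np.asarray(informative_indices).tolist())
    if not selected:
        raise ValueError("empty selection")
    hits = len(selected & informative)
    precision = hits / len(selected)
    recall = hits / len(informative) if informative else 0.0
    return precision, recall


def export_convergence(report: ExperimentReport, path: "str | Path") -> Path:
    """Write tidy per-iteration best-fitness curves: k, repeat, iteration."""
    frames = []
    for r in report.runs:
        frames.append(
            pd.DataFrame(
                {
                    "k": r.k,
                    "repeat": r.repeat,
                    "iteration": np.arange(1, r.history.size + 1),
                    "best_fitness": r.history,
                }
            )
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # default formatting emits the shortest repr, which round-trips float64
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def _config_echo(config: ExperimentConfig) -> dict:
    src = config.source
    if isinstance(src, SyntheticSpec):
        source = {"synthetic": {
            "n_samples": src.n_samples,
            "n_features": src.n_features,
            "n_informative": src.n_informative,
            "effect_size": src.effect_size,
            "n_classes": src.n_classes,
            "seed": src.seed,
        }}
    elif isinstance(src, (str, Path)):
        source = {"path": str(src), "label_column": config.label_column}
    else:
        source = {"in_memory": True}
    return {
        "source": source,
        "k_values": list(config.k_values),
        "n_repeats": config.n_repeats,
        "master_seed": config.master_seed,
        "resplit_per_repeat": config.resplit_per_repeat,
        "weights": {"alpha": config.weights.alpha, "beta": config.weights.beta},
        "optimizer": {
            "n_agents": config.optimizer.n_agents,
            "max_iter": config.optimizer.max_iter,
            "transfer": config.optimizer.transfer.value,
            "s_M": config.optimizer.s_M,
            "repair_empty": config.optimizer.repair_empty,
        },
        "split": {
            "train_fraction": config.split.train_fraction,
            "validation_fraction": config.split.validation_fraction,
            "test_fraction": config.split.test_fraction,
            "stratified": config.split.stratified,
        },
    }


def _write_report(report: ExperimentReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.report_frame().to_csv(out_dir / "report.csv", index=False)
    report.runs_frame().to_csv(out_dir / "runs.csv", index=False)
    export_convergence(report, out_dir / "convergence.csv")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_echo(report.config), fh, sort_keys=False)
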