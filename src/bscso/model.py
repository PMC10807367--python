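"""Model-style interface to the wrapper feature selector.

``SandCatFeatureSelector`` is built from a feature matrix and labels (or a
DataFrame), holds the split/normalization/fitness/optimizer settings, and
``fit()`` runs the full pipeline: stratified split, min-max normalization
fit on the training partition, binary swarm search of the subset space, and
held-out test evaluation of the best subset.  The returned
``FeatureSelectionResults`` carries the selected support, the fitness and
accuracy achieved, the convergence history, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset, SplitSpec, normalize_minmax, split
from .fitness import (
    EvaluationContext,
    FitnessWeights,
    fitness_function,
    test_accuracy,
    wrapper_fitness,
)
from .optimizer import OptimizationResult, OptimizerConfig, optimize
from .transfer import TransferFunction

__all__ = ["SandCatFeatureSelector", "FeatureSelectionResults"]


class SandCatFeatureSelector:
    """Wrapper feature selection by binary sand cat swarm optimization.

    Parameters
    ----------
    features, labels
        The full dataset; labels may be any hashable class identifiers.
    k
        KNN neighbor count used both inside the fitness and for the final
        test accuracy (odd values 3/5/7 are the usual choices).
    alpha, beta
        Fitness weights for the error-rate and subset-size terms
        (``alpha + beta = 1``).
    n_agents, max_iter, transfer, s_M
        Swarm settings; defaults are population 30, 100 iterations, the V4
        (arctangent) transfer function and hearing constant 2.
    split_spec
        Train/validation/test fractions (default 60/20/20, stratified).
        With a zero validation fraction the fitness error rate is computed
        on the training partition itself (the plain 8:2 protocol).
    normalize
        Min-max normalize features using training-partition column ranges.
    """

    def __init__(
        self,
        features,
        labels,
        *,
        k: int = 5,
        alpha: float = 0.99,
        beta: float = 0.01,
        n_agents: int = 30,
        max_iter: int = 100,
        transfer: "str | TransferFunction" = TransferFunction.V4,
        s_M: float = 2.0,
        split_spec: SplitSpec = SplitSpec(),
        normalize: bool = True,
        feature_names: Optional[Sequence[str]] = None,
    ) -> None:
        features = np.asarray(features, dtype=float)
        raw_labels = np.asarray(labels)
        classes, encoded = np.unique(raw_labels, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        names = (
            [str(n) for n in feature_names]
            if feature_names is not None
            else [f"f{j}" for j in range(features.shape[1])]
        )
        self.dataset = LabeledDataset(
            features=features,
            labels=encoded,
            feature_names=names,
            n_classes=classes.size,
            class_names=[str(c) for c in classes],
        )
        self.k = int(k)
        self.weights = FitnessWeights(alpha=alpha, beta=beta)
        self.optimizer_config = OptimizerConfig(
            n_agents=n_agents,
            max_iter=max_iter,
            transfer=TransferFunction.from_name(transfer),
            s_M=s_M,
        )
        self.split_spec = split_spec
        self.normalize = bool(normalize)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: Optional[str] = None,
        **kwargs,
    ) -> "SandCatFeatureSelector":
        """Build a selector from a DataFrame with one label column."""
        if label_column is None:
            label_column = df.columns[-1]
        feats = df.drop(columns=[label_column])
        return cls(
            feats.to_numpy(dtype=float),
            df[label_column].to_numpy(),
            feature_names=[str(c) for c in feats.columns],
            **kwargs,
        )

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset, **kwargs) -> "SandCatFeatureSelector":
        return cls(
            dataset.features,
            dataset.labels,
            feature_names=dataset.feature_names,
            **kwargs,
        )

    def fit(self, seed: Optional[int] = None) -> "FeatureSelectionResults":
        """Run one seeded split + optimization and score the best subset."""
        spec = replace(self.split_spec, seed=seed)
        train, val, test = split(self.dataset, spec)
        if self.normalize:
            val = normalize_minmax(val, reference=train) if val.n_samples else val
            test = normalize_minmax(test, reference=train)
            train = normalize_minmax(train)
        # with no validation partition the wrapper scores on the training
        # rows themselves (resubstitution), as in the plain 8:2 protocol
        fit_val = val if val.n_samples else train
        context = EvaluationContext(
            train_features=train.features,
            train_labels=train.labels,
            validation_features=fit_val.features,
            validation_labels=fit_val.labels,
            k=self.k,
            weights=self.weights,
        )
        config = replace(self.optimizer_config, seed=seed)
        result = optimize(fitness_function(context), self.dataset.n_features, config)
        evaluation = wrapper_fitness(context, result.best_bits)
        acc = test_accuracy(
            train.features,
            train.labels,
            test.features,
            test.labels,
            result.best_bits,
            k=self.k,
        )
        return FeatureSelectionResults(
            model=self,
            seed=seed,
            support=result.best_bits.astype(bool),
            best_fitness=result.best_fitness,
            validation_error_rate=evaluation.error_rate,
            test_accuracy=acc,
            history=result.history,
            evaluations=result.evaluations,
        )


@dataclass
class FeatureSelectionResults:
    """Outcome of one fitted feature-selection run."""

    model: SandCatFeatureSelector
    seed: Optional[int]
    support: np.ndarray
    best_fitness: float
    validation_error_rate: float
    test_accuracy: float
    history: np.ndarray
    evaluations: int

    @property
    def n_selected(self) -> int:
        return int(self.support.sum())

    @property
    def selected_features(self) -> list[str]:
        names = self.model.dataset.feature_names
        return [names[j] for j in np.flatnonzero(self.support)]

    def transform(self, X) -> np.ndarray:
        """Restrict a feature matrix to the selected columns."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.support.size:
            raise ValueError("feature count mismatch")
        return X[:, self.support]

    def summary(self) -> str:
        ds = self.model.dataset
        w = self.model.weights
        lines = [
            "Binary Sand Cat Swarm Feature Selection",
            "=" * 55,
            f"{'Samples':<28}{ds.n_samples:>10}",
            f"{'Total features (C)':<28}{ds.n_features:>10}",
            f"{'Classes':<28}{ds.n_classes:>10}",
            f"{'KNN neighbors (k)':<28}{self.model.k:>10}",
            f"{'Weights (alpha, beta)':<28}{w.alpha:>5.2f}{w.beta:>5.2f}",
            f"{'Agents x iterations':<28}"
            f"{self.model.optimizer_config.n_agents:>5} x "
            f"{self.model.optimizer_config.max_iter}",
            f"{'Transfer function':<28}"
            f"{self.model.optimizer_config.transfer.value.upper():>10}",
            f"{'Seed':<28}{str(self.seed):>10}",
            "-" * 55,
            f"{'Selected features |S|':<28}{self.n_selected:>10}",
            f"{'Best fitness':<28}{self.best_fitness:>10.6f}",
            f"{'Validation error rate':<28}{self.validation_error_rate:>10.4f}",
            f"{'Test accuracy':<28}{self.test_accuracy * 100:>9.2f}%",
            f"{'Fitness evaluations':<28}{self.evaluations:>10}",
            "=" * 55,
            "Selected: " + ", ".join(self.selected_features),
        ]
        return "\n".join(lines)
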