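"""Tabular data loading, normalization, splitting and synthetic generation.

The loaders target UCI-style tabular classification data: delimited text
with a header row and one label column, or ARFF with a nominal class
attribute.  The synthetic generator emulates the "many features, few
samples" structure of gene-expression sets: a handful of informative
features whose class-conditional Gaussian means are separated by a stated
effect size, buried among independent standard-Gaussian noise features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from sklearn.model_selection import train_test_split

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "SyntheticSpec",
    "SyntheticDataset",
    "load_table",
    "normalize_minmax",
    "split",
    "generate_synthetic",
]


@dataclass
class LabeledDataset:
    """A feature matrix with integer-encoded class labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    n_classes: int
    class_names: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("labels misaligned with feature rows")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length mismatch")
        if not self.class_names:
            self.class_names = [str(c) for c in range(self.n_classes)]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """A new dataset restricted to the given row indices."""
        return LabeledDataset(
            features=self.features[rows],
            labels=self.labels[rows],
            feature_names=list(self.feature_names),
            n_classes=self.n_classes,
            class_names=list(self.class_names),
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = [self.class_names[c] for c in self.labels]
        return df


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition fractions (must sum to 1)."""

    train_fraction: float = 0.6
    validation_fraction: float = 0.2
    test_fraction: float = 0.2
    stratified: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.train_fraction <= 0 or self.test_fraction <= 0:
            raise ValueError("train and test fractions must be positive")
        if self.validation_fraction < 0:
            raise ValueError("validation fraction must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Class-conditional Gaussian data with a known informative subset.

    ``effect_size`` is the separation between adjacent class means on each
    informative feature, in units of the (unit) noise standard deviation.
    """

    n_samples: int = 120
    n_features: int = 30
    n_informative: int = 5
    effect_size: float = 3.0
    n_classes: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must satisfy 0 <= m <= n_features")
        if self.n_samples < 4 * self.n_classes:
            raise ValueError("n_samples must be at least 4 * n_classes")


@dataclass
class SyntheticDataset:
    """A synthetic dataset plus the ground-truth informative column indices."""

    dataset: LabeledDataset
    informative_indices: np.ndarray


def _encode_labels(raw: pd.Series) -> tuple[np.ndarray, list[str]]:
    names: list[str] = []
    codes = np.empty(len(raw), dtype=int)
    lookup: dict[str, int] = {}
    for i, value in enumerate(raw.astype(str)):
        if value not in lookup:
            lookup[value] = len(names)
            names.append(value)
        codes[i] = lookup[value]
    return codes, names


def _frame_to_dataset(
    df: pd.DataFrame,
    label_column: Optional[str],
    on_missing: str,
) -> LabeledDataset:
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise ValueError("no feature columns besides the label")
    coerced = {}
    for col in feature_cols:
        original = df[col]
        numeric = pd.to_numeric(original, errors="coerce")
        bad = numeric.isna() & original.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unparseable cell at row {row}, column {col!r}: "
                f"{original.iloc[row]!r}"
            )
        coerced[col] = numeric
    features = pd.DataFrame(coerced)
    missing = features.isna().any(axis=1) | df[label_column].isna()
    n_dropped = int(missing.sum())
    if n_dropped and on_missing == "error":
        row = int(np.flatnonzero(missing.to_numpy())[0])
        raise ValueError(f"missing value in row {row}")
    keep = ~missing
    labels, class_names = _encode_labels(df.loc[keep, label_column])
    if len(class_names) < 2:
        raise ValueError("dataset contains a single class")
    return LabeledDataset(
        features=features.loc[keep].to_numpy(dtype=float),
        labels=labels,
        feature_names=[str(c) for c in feature_cols],
        n_classes=len(class_names),
        class_names=class_names,
        n_dropped_rows=n_dropped,
    )


def load_table(
    path: "str | Path",
    label_column: Optional[str] = None,
    format: Optional[str] = None,
    on_missing: str = "drop",
) -> LabeledDataset:
    """Load a CSV or ARFF classification table.

    Parameters
    ----------
    path
        File to read; the format is inferred from the extension unless
        ``format`` is given ("csv" or "arff").
    label_column
        Name of the label column; defaults to the last column.
    on_missing
        "drop" removes rows with missing entries (counted in
        ``n_dropped_rows``); "error" raises instead.
    """
    path = Path(path)
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "arff":
        data, _meta = scipy_arff.loadarff(io.StringIO(path.read_text()))
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
    return _frame_to_dataset(df, label_column, on_missing)


def normalize_minmax(
    dataset: LabeledDataset,
    reference: Optional[LabeledDataset] = None,
) -> LabeledDataset:
    """Rescale each column to [0, 1] by ``(x - min) / (max - min)``.

    Column minima and maxima come from ``reference`` when given (fit on the
    training partition, apply everywhere), else from the dataset itself.
    Columns constant in the reference map to 0.
    """
    ref = (reference or dataset).features
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)
    scaled = (dataset.features - lo) / span
    scaled[:, constant] = 0.0
    return LabeledDataset(
        features=scaled,
        labels=dataset.labels,
        feature_names=list(dataset.feature_names),
        n_classes=dataset.n_classes,
        class_names=list(dataset.class_names),
        n_dropped_rows=dataset.n_dropped_rows,
    )


def split(
    dataset: LabeledDataset,
    spec: SplitSpec = SplitSpec(),
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition rows into disjoint train/validation/test datasets.

    Stratification keeps per-class proportions within one instance of the
    requested fractions.  A zero validation fraction yields an empty
    validation partition (the two-way 8:2 protocol).
    """
    rows = np.arange(dataset.n_samples)
    labels = dataset.labels
    strat = labels if spec.stratified else None
    try:
        rest, test_rows = train_test_split(
            rows,
            test_size=spec.test_fraction,
            random_state=spec.seed,
            stratify=strat,
        )
        if spec.validation_fraction > 0:
            val_share = spec.validation_fraction / (
                spec.train_fraction + spec.validation_fraction
            )
            strat_rest = labels[rest] if spec.stratified else None
            train_rows, val_rows = train_test_split(
                rest,
                test_size=val_share,
                random_state=spec.seed,
                stratify=strat_rest,
            )
        else:
            train_rows, val_rows = rest, np.array([], dtype=int)
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    return (
        dataset.subset(np.sort(train_rows)),
        dataset.subset(np.sort(val_rows)),
        dataset.subset(np.sort(test_rows)),
    )


def generate_synthetic(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a balanced class-conditional Gaussian dataset.

    Informative features have class-c mean ``c * effect_size`` with unit
    variance; the remaining features are standard Gaussians identical
    across classes.  Columns are randomly permuted and the post-permutation
    informative index set is returned with the data.
    """
    rng = np.random.default_rng(spec.seed)
    counts = np.full(spec.n_classes, spec.n_samples // spec.n_classes)
    counts[: spec.n_samples % spec.n_classes] += 1
    labels = np.repeat(np.arange(spec.n_classes), counts)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    X[:, : spec.n_informative] += spec.effect_size * labels[:, None]
    perm = rng.permutation(spec.n_features)
    X = X[:, perm]
    informative = np.sort(np.argsort(perm)[: spec.n_informative])
    order = rng.permutation(spec.n_samples)
    dataset = LabeledDataset(
        features=X[order],
        labels=labels[order],
        feature_names=[f"f{j}" for j in range(spec.n_features)],
        n_classes=spec.n_classes,
    )
    return SyntheticDataset(dataset=dataset, informative_indices=informative)
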