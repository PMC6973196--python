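"""Expression-matrix data model, tabular I/O, min-max scaling and data splitting.

The canonical in-memory layout is samples x genes, regardless of how the
table is stored on disk.  Class labels are integer-encoded in first-seen
order; the original label strings are kept in ``class_names`` for reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class ExpressionParseError(ValueError):
    """Raised when a delimited expression table cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """A samples x genes expression table with integer class labels.

    Every class ``0..C-1`` must appear at least once, and labels must be
    one per sample.  Values are stored as a dense float array; loaders
    reject (or impute) missing cells before construction.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        m, n = self.values.shape
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} rows")
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if self.labels.shape != (m,):
            raise ValueError("one label per sample required")
        c = len(self.class_names)
        present = set(self.labels.tolist())
        if present != set(range(c)):
            raise ValueError(
                f"labels must cover classes 0..{c - 1} exactly; saw {sorted(present)}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class NormStats:
    """Per-gene min/max used by :func:`minmax_normalize`."""

    minimum: np.ndarray
    maximum: np.ndarray
    mode: str = "global"

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min and max vectors must have equal length")
        if np.any(self.minimum > self.maximum):
            raise ValueError("per-gene minimum exceeds maximum")


@dataclass
class DatasetSplit:
    """Disjoint train/test row indices covering the full sample set."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        both = np.concatenate([self.train_indices, self.test_indices])
        if len(np.unique(both)) != len(both):
            raise ValueError("train and test indices overlap or repeat")


@dataclass
class FoldPlan:
    """A k-fold partition of the training indices, stratified by class."""

    folds: list[np.ndarray]
    k: int
    seed: int

    def all_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(self.folds))


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, encoding="utf-8")


def read_expression_table(
    path: str | Path,
    orientation: str = "samples_in_rows",
    label_column: str | None = None,
    labels_path: str | Path | None = None,
    missing: str = "reject",
) -> ExpressionMatrix:
    """Load a delimited expression table into the canonical layout.

    Parameters
    ----------
    path:
        CSV/TSV file with an identifier header row and an identifier first
        column (delimiter chosen from the extension).
    orientation:
        ``samples_in_rows`` or ``genes_in_rows``; the latter is transposed
        on load so the result is always samples x genes.
    label_column:
        Name of the column (after orientation is resolved) holding class
        labels.  Mutually exclusive with ``labels_path``.
    labels_path:
        Sidecar single-column text file with one label per sample, in row
        order.
    missing:
        ``reject`` (default) raises on any non-numeric or empty cell;
        ``mean`` imputes the per-gene mean instead.
    """
    if orientation not in {"samples_in_rows", "genes_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if (label_column is None) == (labels_path is None):
        raise ValueError("provide exactly one of label_column or labels_path")
    if missing not in {"reject", "mean"}:
        raise ValueError(f"unknown missing-value policy {missing!r}")

    df = _read_delimited(path)
    if orientation == "genes_in_rows":
        df = df.T

    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"duplicate sample IDs: {dupes}")

    if label_column is not None:
        if label_column not in df.columns:
            raise ExpressionParseError(f"label column {label_column!r} not found")
        raw_labels = df.pop(label_column)
        if raw_labels.isna().any():
            bad = df.index[raw_labels.isna()][0]
            raise ExpressionParseError(f"missing label for sample {bad!r}")
        raw_labels = raw_labels.astype(str).tolist()
    else:
        raw_labels = (
            pd.read_csv(labels_path, header=None, dtype=str, encoding="utf-8")
            .iloc[:, 0]
            .tolist()
        )
        if len(raw_labels) != len(df):
            raise ExpressionParseError(
                f"{len(raw_labels)} labels for {len(df)} samples"
            )

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            if missing == "reject":
                row = df.index[int(np.argmax(bad.to_numpy()))]
                raise ExpressionParseError(
                    f"non-numeric or missing value at sample {row!r}, gene {col!r}"
                )
            converted = converted.fillna(converted.mean())
        numeric[col] = converted

    class_names = list(dict.fromkeys(raw_labels))
    mapping = {name: i for i, name in enumerate(class_names)}
    labels = np.array([mapping[v] for v in raw_labels], dtype=int)

    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        labels=labels,
        class_names=class_names,
    )


def write_expression_table(
    data: ExpressionMatrix,
    path: str | Path,
    label_column: str | None = "class",
    labels_path: str | Path | None = None,
) -> None:
    """Write a samples x genes table (CSV or TSV by extension).

    Labels go either into a named column or a sidecar file, matching what
    :func:`read_expression_table` accepts.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.gene_ids)
    names = [data.class_names[i] for i in data.labels]
    if labels_path is not None:
        pd.Series(names).to_csv(labels_path, index=False, header=False)
    elif label_column is not None:
        df[label_column] = names
    else:
        raise ValueError("provide label_column or labels_path")
    df.to_csv(path, sep=sep, encoding="utf-8")


def minmax_normalize(
    data: ExpressionMatrix,
    mode: str = "global",
    stats: NormStats | None = None,
) -> tuple[ExpressionMatrix, NormStats]:
    """Map each gene linearly onto [0, 1] via (X - Xmin)/(Xmax - Xmin).

    When ``stats`` is supplied (typically train-set statistics applied to
    held-out data) the result is clipped to [0, 1]; out-of-range held-out
    values saturate rather than extrapolate.  Constant genes map to 0.
    """
    if mode not in {"global", "train_fitted"}:
        raise ValueError(f"unknown normalization mode {mode!r}")
    clip = stats is not None
    if stats is None:
        stats = NormStats(
            minimum=data.values.min(axis=0),
            maximum=data.values.max(axis=0),
            mode=mode,
        )
    if stats.minimum.shape[0] != data.n_genes:
        raise ValueError("stats gene count does not match data")
    span = stats.maximum - stats.minimum
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (data.values - stats.minimum) / span
    scaled[:, span == 0] = 0.0
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return replace(data, values=scaled), stats


def split_train_test(
    labels: np.ndarray,
    n_test: int,
    seed: int,
    stratified: bool = True,
) -> DatasetSplit:
    """Randomly split samples into train and test sets.

    Stratified mode allocates per-class test counts proportional to class
    prevalence using largest-remainder rounding, so minority classes stay
    represented on both sides whenever possible.
    """
    labels = np.asarray(labels, dtype=int)
    m = len(labels)
    if not 0 <= n_test < m:
        raise ValueError(f"n_test must be in [0, {m}); got {n_test}")
    rng = np.random.default_rng(seed)

    if not stratified:
        order = rng.permutation(m)
        test = np.sort(order[:n_test])
        train = np.sort(order[n_test:])
        return DatasetSplit(train_indices=train, test_indices=test, seed=seed)

    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    quota_real = n_test * counts / m
    quota = np.floor(quota_real).astype(int)
    remainder = quota_real - quota
    short = n_test - quota.sum()
    # largest remainder first; ties broken by class order for determinism
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        quota[idx] += 1
    for c, q, n_c in zip(classes, quota, counts):
        if q >= n_c and n_c > 0 and q > 0:
            raise ValueError(
                f"class {c} (size {n_c}) would be fully assigned to the test "
                "set; use stratified=False or a smaller n_test"
            )
    test_parts = []
    for c, q in zip(classes, quota):
        members = np.flatnonzero(labels == c)
        test_parts.append(rng.permutation(members)[:q])
    test = np.sort(np.concatenate(test_parts)).astype(int)
    train = np.setdiff1d(np.arange(m), test)
    return DatasetSplit(train_indices=train, test_indices=test, seed=seed)


def make_fold_plan(
    train_indices: np.ndarray,
    k: int,
    labels: np.ndarray,
    seed: int,
) -> FoldPlan:
    """Partition training indices into k label-stratified folds.

    Fold sizes differ by at most one.  ``labels`` is the full label vector;
    only entries at ``train_indices`` are used.
    """
    train_indices = np.asarray(train_indices, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(train_indices):
        raise ValueError(f"k={k} exceeds {len(train_indices)} training samples")
    y = labels[train_indices]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # folds remain valid when a minority class has fewer members than k
        warnings.simplefilter("ignore", UserWarning)
        folds = [np.sort(train_indices[val]) for _, val in skf.split(y.reshape(-1, 1), y)]
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1
    return FoldPlan(folds=folds, k=k, seed=seed)


def compute_split_proportions(
    n_total: int, n_test: int, k: int
) -> tuple[float, float, float]:
    """Percentage shares of the calibration, validation and test sets.

    With ``train = n_total - n_test`` samples split into k folds, one fold
    of ``floor(train/k)`` samples is the validation set and the rest of the
    training data is the calibration set.  Percentages are rounded to one
    decimal.
    """
    if n_test >= n_total:
        raise ValueError("n_test must be smaller than n_total")
    if k < 2:
        raise ValueError("k must be >= 2")
    n_train = n_total - n_test
    fold = math.floor(n_train / k)
    valid = round(100.0 * fold / n_total, 1)
    calib = round(100.0 * (n_train - fold) / n_total, 1)
    test = round(100.0 * n_test / n_total, 1)
    return calib, valid, test


#: Held-out test-set sizes used for the four reference microarray datasets.
#: They are fixed per dataset: no single rounding rule reproduces all four
#: published calibration/validation/test percentage rows.
REFERENCE_TEST_COUNTS: dict[str, int] = {
    "aml_all": 17,
    "colon": 17,
    "st_jude": 60,
    "lung": 58,
}
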