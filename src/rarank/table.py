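"""Two-class feature tables.

The central container is :class:`FeatureTable`: a dense numeric matrix of
``n`` samples by ``p`` features together with a binary label vector. By
convention the *positive* class (label 1) is the minority class, the class
of interest in biomarker screening, and the *negative* class (label 0) is
the majority; the two may be equal in size but the minority is never larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]


@dataclass(frozen=True)
class FeatureTable:
    """A validated two-class sample-by-feature matrix.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric feature matrix; must be finite.
    y : ndarray of shape (n,)
        Binary labels, 1 = minority/positive class, 0 = majority/negative.
    feature_names : tuple of str
        ``p`` unique feature identifiers.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple = field(default=None)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite entries")
        if y.shape != (X.shape[0],):
            raise ValueError("y length does not match the number of rows of X")
        uniq = set(np.unique(y).tolist())
        if not uniq <= {0, 1}:
            raise ValueError("y must be coded 0 (majority) / 1 (minority)")
        y = y.astype(np.int64)
        if X.shape[1] < 2:
            raise ValueError("at least 2 features are required")
        n1 = int(np.sum(y == 1))
        n2 = int(np.sum(y == 0))
        if min(n1, n2) < 2:
            raise ValueError("each class needs at least 2 samples")
        if n1 > n2:
            raise ValueError(
                "positive class (y=1) must be the minority or equal in size; "
                f"got n1={n1} > n2={n2}"
            )
        names = self.feature_names
        if names is None:
            names = tuple(f"feature_{j + 1}" for j in range(X.shape[1]))
        else:
            names = tuple(str(v) for v in names)
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length does not match p")
        if len(set(names)) != len(names):
            raise ValueError("feature_names must be unique")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", names)

    # -- sizes ------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n1(self) -> int:
        """Minority (positive) class size."""
        return int(np.sum(self.y == 1))

    @property
    def n2(self) -> int:
        """Majority (negative) class size."""
        return int(np.sum(self.y == 0))

    @property
    def imbalance_ratio(self) -> float:
        """Majority-to-minority ratio, n2 / n1."""
        return self.n2 / self.n1

    # -- construction ------------------------------------------------------
    @classmethod
    def from_labels(cls, X, labels, positive_label=None, feature_names=None):
        """Build a table from arbitrary (two-valued) labels.

        If ``positive_label`` is not given the rarer label becomes the
        positive class; on an exact tie the lexicographically smaller label
        is chosen, so construction is deterministic.
        """
        labels = np.asarray(labels)
        values, counts = np.unique(labels, return_counts=True)
        if len(values) != 2:
            raise ValueError(f"expected exactly 2 label values, got {len(values)}")
        if positive_label is None:
            order = np.lexsort((values.astype(str), counts))
            positive_label = values[order[0]]
        elif positive_label not in values:
            raise ValueError(f"positive label {positive_label!r} not present")
        y = (labels == positive_label).astype(np.int64)
        return cls(np.asarray(X, dtype=float), y, feature_names)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, label_column, self.y)
        return df


def read_feature_table(
    path,
    label_column: str = "label",
    positive_label=None,
    sep=None,
) -> FeatureTable:
    """Read a CSV/TSV feature table (header row, one label column).

    The delimiter is sniffed from the extension unless ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    non_numeric = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")
    if feats.isna().any().any():
        raise ValueError("missing values are not supported")
    return FeatureTable.from_labels(
        feats.to_numpy(dtype=float), labels, positive_label, tuple(feats.columns)
    )


def write_feature_table(tbl: FeatureTable, path, label_column: str = "label",
                        provenance=None) -> None:
    """Write a table to CSV; optionally add a row-provenance column."""
    df = tbl.to_frame(label_column)
    if provenance is not None:
        df["provenance"] = np.where(np.asarray(provenance, bool), "synthetic", "original")
    df.to_csv(path, index=False)
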