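"""Labeled sample-by-feature datasets.

The universal input of the package: a dense numeric matrix ``X`` with one
row per sample, together with a categorical label per sample taking values
in ``{1, ..., K}``. Labels may be given as arbitrary hashable values; they
are mapped to contiguous integer codes and the original values retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """A sample-by-feature matrix with a K-class label per sample.

    Parameters
    ----------
    X : (N, p) ndarray
        Numeric predictor matrix, no missing values.
    y : (N,) ndarray of int
        Class codes in ``{0, ..., K-1}`` (internal 0-based coding).
    feature_ids : sequence of str, optional
        Identifiers for the p features; generated as ``f1..fp`` if absent.
    sample_ids : sequence of str, optional
        Identifiers for the N samples; generated as ``s1..sN`` if absent.
    class_labels : sequence, optional
        Original label value for each class code.

    Every class must contain at least two samples: the within-group
    variance terms of the discriminative-power indices divide by
    ``n_k - 1`` and are undefined for singleton classes.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    class_labels: list = field(default_factory=list)
    #: relaxed validation (used for CV fold subsets, where a small class may
    #: fall below two members; index computations still require the full
    #: dataset invariant)
    strict: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D sample-by-feature matrix")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite entries")
        y = np.asarray(self.y)
        if y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y has length {y.shape}, expected ({self.X.shape[0]},)"
            )
        if not self.class_labels:
            labels, codes = np.unique(y, return_inverse=True)
            self.class_labels = list(labels)
            self.y = codes.astype(np.int64)
        else:
            self.y = y.astype(np.int64)
            if self.y.min() < 0 or self.y.max() >= len(self.class_labels):
                raise ValueError("class codes outside {0..K-1}")
        counts = np.bincount(self.y, minlength=self.K)
        if self.K < 2:
            raise ValueError("at least two classes are required")
        if self.strict and counts.min() < 2:
            bad = [str(self.class_labels[k]) for k in np.flatnonzero(counts < 2)]
            raise ValueError(
                "every class needs n_k >= 2 samples; too small: " + ", ".join(bad)
            )
        if not self.feature_ids:
            self.feature_ids = [f"f{j + 1}" for j in range(self.p)]
        elif len(self.feature_ids) != self.p:
            raise ValueError("feature_ids length does not match p")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.N)]
        elif len(self.sample_ids) != self.N:
            raise ValueError("sample_ids length does not match N")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return len(self.class_labels) if self.class_labels else int(self.y.max()) + 1

    @property
    def class_counts(self) -> np.ndarray:
        """n_k for k = 1..K."""
        return np.bincount(self.y, minlength=self.K)

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Row subset keeping the global class coding (for CV folds)."""
        rows = np.asarray(rows)
        return LabeledDataset(
            X=self.X[rows],
            y=self.y[rows],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in rows],
            class_labels=list(self.class_labels),
            strict=False,
        )

    @classmethod
    def from_files(cls, x_path: str, y_path: str, sep: str = "\t") -> "LabeledDataset":
        """Read X (samples x features table with header + index) and labels.

        The label file is a single-column table (with or without header)
        aligned to the rows of X.
        """
        xdf = pd.read_csv(x_path, sep=sep, index_col=0)
        ydf = pd.read_csv(y_path, sep=sep, header=None)
        ycol = ydf.iloc[:, -1]
        if str(ycol.iloc[0]).lower() in ("label", "y", "class"):
            ycol = ycol.iloc[1:]
        if len(ycol) != len(xdf):
            raise ValueError(
                f"label file has {len(ycol)} rows, X has {len(xdf)} samples"
            )
        return cls(
            X=xdf.to_numpy(dtype=np.float64),
            y=ycol.to_numpy(),
            feature_ids=[str(c) for c in xdf.columns],
            sample_ids=[str(i) for i in xdf.index],
        )

    def to_files(self, x_path: str, y_path: str, sep: str = "\t") -> None:
        pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_ids).to_csv(
            x_path, sep=sep
        )
        labels = [self.class_labels[k] for k in self.y]
        pd.Series(labels).to_csv(y_path, sep=sep, index=False, header=False)
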