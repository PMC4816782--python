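"""Comparison of connection matrices against ternary tracer-derived truth.

The ground truth marks each unordered region pair as present (1), absent (0),
or indeterminate (-1); indeterminate pairs (and the diagonal) are excluded
from all confusion counts.  A connection is predicted present when its matrix
value is strictly above the acceptance threshold.  Accuracy is

    100 * (TP + TN) / (TP + TN + FP + FN)

and the ROC is traversed by scanning the threshold from 0 to 100 in steps of
1 (percent of initiated streamlines for raw strength matrices; fractions of
the matrix maximum for distance-corrected matrices, which live on their own
scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TernaryTruth",
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "rates",
    "threshold_scan",
    "ThresholdScan",
    "length_binned_rates",
]


@dataclass(frozen=True)
class TernaryTruth:
    """Region-by-region {present: 1, absent: 0, indeterminate: -1} matrix."""

    states: np.ndarray
    region_names: list[str]

    def __post_init__(self):
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "region_names", list(self.region_names))
        n = len(self.region_names)
        if s.shape != (n, n):
            raise ValueError("states must be square and match region_names")
        if not np.array_equal(s, s.T):
            raise ValueError("truth matrix must be symmetric")
        if not np.all(np.diag(s) == -1):
            raise ValueError("diagonal must be indeterminate (-1)")
        if not np.all(np.isin(s, (-1, 0, 1))):
            raise ValueError("states must be in {-1, 0, 1}")

    def pair_indices(self) -> np.ndarray:
        """(k, 2) upper-triangle indices of determinate pairs."""
        iu = np.triu_indices(len(self.region_names), k=1)
        det = self.states[iu] != -1
        return np.column_stack([iu[0][det], iu[1][det]])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.states, index=self.region_names,
                     columns=self.region_names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TernaryTruth":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=int), [str(c) for c in df.columns])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _matrix_and_names(matrix) -> tuple[np.ndarray, list[str] | None]:
    values = getattr(matrix, "values", matrix)
    names = getattr(matrix, "region_names", None)
    return np.asarray(values, dtype=float), names


def confusion(matrix, truth: TernaryTruth, threshold: float) -> ConfusionCounts:
    """Confusion counts over unordered determinate pairs at a strict threshold.

    ``matrix`` is a connection matrix (``SciMatrix``, corrected matrix, or a
    plain symmetric array); predicted present means value > threshold.
    """
    values, names = _matrix_and_names(matrix)
    if names is not None and list(names) != list(truth.region_names):
        raise ValueError("region names of matrix and truth do not match")
    if values.shape != truth.states.shape:
        raise ValueError("matrix shape does not match truth")
    pairs = truth.pair_indices()
    if len(pairs) == 0:
        return ConfusionCounts(0, 0, 0, 0)
    i, j = pairs[:, 0], pairs[:, 1]
    predicted = values[i, j] > threshold
    actual = truth.states[i, j] == 1
    tp = int(np.sum(predicted & actual))
    fp = int(np.sum(predicted & ~actual))
    fn = int(np.sum(~predicted & actual))
    tn = int(np.sum(~predicted & ~actual))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    """Percent of correctly determined connections, 100*(TP+TN)/total."""
    if c.total == 0:
        raise ValueError("accuracy undefined: no determinate pairs")
    return 100.0 * (c.tp + c.tn) / c.total


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def rates(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(tp_rate, fp_rate, percent_tp, percent_tn); NaN where undefined.

    tp_rate = TP/(TP+FN), fp_rate = FP/(FP+TN),
    %TP = 100*TP/(TP+FP), %TN = 100*TN/(TN+FN).
    """
    return (
        _ratio(c.tp, c.tp + c.fn),
        _ratio(c.fp, c.fp + c.tn),
        100.0 * _ratio(c.tp, c.tp + c.fp),
        100.0 * _ratio(c.tn, c.tn + c.fn),
    )


@dataclass(frozen=True)
class ThresholdScan:
    """Threshold sweep results: one row per threshold plus the optimum."""

    table: pd.DataFrame  # columns: threshold, accuracy, tp_rate, fp_rate
    optimum_threshold: float
    optimum_accuracy: float

    def roc(self) -> np.ndarray:
        """(n, 2) array of (fp_rate, tp_rate) ROC points."""
        return self.table[["fp_rate", "tp_rate"]].to_numpy()


def threshold_scan(matrix, truth: TernaryTruth, thresholds=None) -> ThresholdScan:
    """Scan acceptance thresholds (default 0, 1, ..., 100) and locate the
    accuracy optimum (ties broken toward the smallest threshold)."""
    if thresholds is None:
        thresholds = np.arange(101, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    rows = []
    for t in thresholds:
        c = confusion(matrix, truth, t)
        tp_rate, fp_rate, _, _ = rates(c)
        rows.append((t, accuracy(c), tp_rate, fp_rate))
    table = pd.DataFrame(rows, columns=["threshold", "accuracy", "tp_rate", "fp_rate"])
    best = int(np.argmax(table["accuracy"].to_numpy()))
    return ThresholdScan(table, float(thresholds[best]),
                         float(table["accuracy"].iloc[best]))


def length_binned_rates(
    matrix, lci, truth: TernaryTruth, threshold: float, n_bins: int = 5
) -> pd.DataFrame:
    """TP/FP rates per connection-length bin.

    Determinate pairs are ordered by their length-matrix entry (ascending) and
    split into ``n_bins`` contiguous equal-count groups; with remainder ``r``,
    the first ``r`` bins take one extra pair.  Rates within each bin use the
    same strict threshold as :func:`confusion`.
    """
    values, _ = _matrix_and_names(matrix)
    lengths, _ = _matrix_and_names(lci)
    pairs = truth.pair_indices()
    if len(pairs) < n_bins:
        raise ValueError("fewer determinate pairs than bins")
    i, j = pairs[:, 0], pairs[:, 1]
    order = np.argsort(lengths[i, j], kind="stable")
    i, j = i[order], j[order]
    base, rem = divmod(len(pairs), n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    rows, start = [], 0
    for k, size in enumerate(sizes):
        bi, bj = i[start:start + size], j[start:start + size]
        predicted = values[bi, bj] > threshold
        actual = truth.states[bi, bj] == 1
        c = ConfusionCounts(
            int(np.sum(predicted & actual)), int(np.sum(~predicted & ~actual)),
            int(np.sum(predicted & ~actual)), int(np.sum(~predicted & actual)),
        )
        tp_rate, fp_rate, _, _ = rates(c)
        rows.append((k, size, float(lengths[bi, bj].min()),
                     float(lengths[bi, bj].max()), tp_rate, fp_rate))
        start += size
    return pd.DataFrame(
        rows, columns=["bin", "n_pairs", "length_min", "length_max",
                       "tp_rate", "fp_rate"]
    )
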