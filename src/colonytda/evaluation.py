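"""Evaluation surfaces: accuracy, per-class metrics, confusion matrices,
cross-timepoint accuracy grids and the time-differential metric <T,S>.

<T,S> = Acc_T(S) - Acc_{S*}(S), where Acc_A(B) is the accuracy at timepoint B
of a model trained at timepoint A, and S* is a fixed offset before S (10
frames = 50 minutes at the study's 5-minute frame spacing).  It measures how
much of a model's discriminative power transfers across time relative to a
near-contemporaneous model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "AccuracyGrid",
    "accuracy",
    "confusion",
    "class_metrics",
    "cross_time_grid",
    "time_differential",
]


def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of exact class matches."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be nonempty and equal length")
    return float((predictions == labels).mean())


@dataclass
class ConfusionMatrix:
    """Counts (or repeat-averaged counts) indexed (true class, predicted class)."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative (k, k) matrix")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    @staticmethod
    def average(matrices: Sequence["ConfusionMatrix"]) -> "ConfusionMatrix":
        """Elementwise mean over repeat models (matching class order required)."""
        if not matrices:
            raise ValueError("nothing to average")
        classes = matrices[0].classes
        if any(m.classes != classes for m in matrices):
            raise ValueError("class orderings differ")
        return ConfusionMatrix(classes, np.mean([m.counts for m in matrices], axis=0))


def confusion(predictions: Sequence, labels: Sequence, classes: Sequence[str]) -> ConfusionMatrix:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    classes = tuple(classes)
    unknown = (set(labels.tolist()) | set(predictions.tolist())) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(labels.tolist(), predictions.tolist()):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes, counts)


@dataclass
class ClassMetrics:
    """Per-class precision, recall and F1, with degenerate-denominator flags."""

    table: pd.DataFrame  # index: class; columns: precision, recall, f1, degenerate

    def __getitem__(self, cls: str) -> pd.Series:
        return self.table.loc[cls]


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2pr/(p+r).

    A class that is never predicted (or never present) has an undefined
    ratio; the convention here is metric 0 with the ``degenerate`` flag set.
    """
    counts = cm.counts
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    rows = []
    for i, cls in enumerate(cm.classes):
        degenerate = False
        if tp[i] + fp[i] > 0:
            prec = tp[i] / (tp[i] + fp[i])
        else:
            prec, degenerate = 0.0, True
        if tp[i] + fn[i] > 0:
            rec = tp[i] / (tp[i] + fn[i])
        else:
            rec, degenerate = 0.0, True
        if prec + rec > 0:
            f1 = 2 * prec * rec / (prec + rec)
        else:
            f1, degenerate = 0.0, True
        rows.append({"precision": prec, "recall": rec, "f1": f1, "degenerate": degenerate})
    return ClassMetrics(pd.DataFrame(rows, index=list(cm.classes)))


@dataclass
class AccuracyGrid:
    """Acc_T(S) over training timepoints T (rows) and test timepoints S (columns)."""

    train_timepoints: tuple[int, ...]
    test_timepoints: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.train_timepoints), len(self.test_timepoints)):
            raise ValueError("grid shape does not match timepoint lists")
        finite = self.values[np.isfinite(self.values)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.train_timepoints, name="train_T"),
            columns=pd.Index(self.test_timepoints, name="test_S"),
        )


def cross_time_grid(
    models_by_timepoint: Mapping[int, Sequence],
    features_by_timepoint: Mapping[int, np.ndarray],
    labels: Sequence[str],
) -> AccuracyGrid:
    """Acc_T(S) for every (T, S) pair, averaged over repeat models.

    ``models_by_timepoint[T]`` is a list of :class:`TrainingResult` repeats
    trained at T; ``features_by_timepoint[S]`` holds every colony's feature
    row at S (same colony order as ``labels``).  For T == S only each model's
    held-out validation colonies are scored; for T != S the model never saw
    timepoint-S data, so all colonies are scored.
    """
    labels = np.asarray(labels)
    ts = tuple(sorted(models_by_timepoint))
    ss = tuple(sorted(features_by_timepoint))
    dims = {features_by_timepoint[s].shape[1] for s in ss}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions across timepoints: {sorted(dims)}")
    grid = np.empty((len(ts), len(ss)))
    for i, t in enumerate(ts):
        for j, s in enumerate(ss):
            accs = []
            for result in models_by_timepoint[t]:
                X = features_by_timepoint[s]
                if t == s:
                    idx = result.val_idx
                    accs.append(accuracy(result.predict(X[idx]), labels[idx]))
                else:
                    accs.append(accuracy(result.predict(X), labels))
            grid[i, j] = float(np.mean(accs))
    return AccuracyGrid(ts, ss, grid)


def time_differential(grid: AccuracyGrid, offset: int = 10) -> pd.DataFrame:
    """<T,S> = Acc_T(S) - Acc_{S*}(S) with S* = S - offset.

    The metric compares two models on the *same* footing — both classify
    timepoint-S data they were not trained on — so it is defined only for
    T != S; diagonal cells are NaN, as are columns whose S* is not a training
    timepoint in the grid (boundaries are undefined, never extrapolated).
    Cells with T == S* are identically 0 (the same model list on both sides).
    """
    if offset < 1:
        raise ValueError("offset must be >= 1 frame")
    frame = grid.to_frame()
    out = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)
    for s in frame.columns:
        s_star = s - offset
        if s_star in frame.index:
            out[s] = frame[s] - frame.loc[s_star, s]
            if s in frame.index:
                out.loc[s, s] = np.nan
    return out
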