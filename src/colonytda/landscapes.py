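"""Persistence landscapes: fixed-size functional summaries of barcodes.

Each finite bar (b, d) contributes a tent function f_(b,d) rising from b to a
peak of (d-b)/2 at the midpoint and falling back to zero at d.  The k-th
landscape function lambda_k(t) is the k-th largest tent value at t.  Sampling
lambda_1..lambda_K on a grid of filtration values gives the matrix fed to the
classifier; bars with infinite death are excluded (their tent is undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .persistence import PersistenceDiagram

__all__ = [
    "LandscapeGrid",
    "LandscapeMatrix",
    "triangle_function",
    "landscape_value",
    "landscape_matrix",
]

DEFAULT_SAMPLE_POINTS = tuple(float(t) for t in range(1, 41))


@dataclass(frozen=True)
class LandscapeGrid:
    """Sampling configuration: filtration values t_j and functions lambda_1..lambda_K.

    Defaults follow the study design: sample points 1..40, forty functions for
    a single homology dimension, twenty per dimension when both are combined.
    """

    sample_points: tuple[float, ...] = DEFAULT_SAMPLE_POINTS
    n_functions: int = 40

    def __post_init__(self) -> None:
        pts = np.asarray(self.sample_points, dtype=float)
        if pts.size < 1 or not np.all(np.isfinite(pts)) or np.any(pts <= 0):
            raise ValueError("sample points must be finite and positive")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("sample points must be strictly increasing")
        if self.n_functions < 1:
            raise ValueError("n_functions must be >= 1")
        object.__setattr__(self, "sample_points", tuple(float(p) for p in pts))

    @property
    def max_value(self) -> float:
        return self.sample_points[-1]


@dataclass
class LandscapeMatrix:
    """Sampled landscape values: entry (i, j) = lambda_{i+1}(t_j).

    For combined dimensions the dim-0 block (n_functions rows) is stacked
    above the dim-1 block.
    """

    values: np.ndarray
    grid: LandscapeGrid
    dims_used: tuple[int, ...]
    colony_id: str | None = None
    timepoint: int | None = None

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


def triangle_function(b: float, d: float, t) -> float | np.ndarray:
    """Tent function of a finite bar: 0 outside (b, d), peak (d-b)/2 at the midpoint."""
    if not (math.isfinite(b) and math.isfinite(d)):
        raise ValueError("triangle_function requires finite birth and death")
    if d <= b:
        raise ValueError(f"death must exceed birth, got ({b}, {d})")
    t_arr = np.asarray(t, dtype=float)
    out = np.maximum(0.0, np.minimum(t_arr - b, d - t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _tent_values(bars, ts: np.ndarray) -> np.ndarray:
    """(n_bars, n_t) matrix of tent values; rejects infinite bars."""
    if any(not math.isfinite(bar.death) for bar in bars):
        raise ValueError("infinite-death bars must be excluded before landscape evaluation")
    if not bars:
        return np.zeros((0, ts.size))
    b = np.array([bar.birth for bar in bars])
    d = np.array([bar.death for bar in bars])
    return np.maximum(0.0, np.minimum(ts[None, :] - b[:, None], d[:, None] - ts[None, :]))


def landscape_value(bars, k: int, t: float) -> float:
    """lambda_k(t): the k-th largest tent value at t over all finite bars (0 if < k bars)."""
    if k < 1:
        raise ValueError(f"landscape index k must be >= 1, got {k}")
    vals = _tent_values(list(bars), np.asarray([float(t)]))[:, 0]
    if vals.size < k:
        return 0.0
    return float(np.sort(vals)[::-1][k - 1])


def landscape_matrix(
    diagram: PersistenceDiagram,
    dims_used: tuple[int, ...] = (0, 1),
    grid: LandscapeGrid | None = None,
) -> LandscapeMatrix:
    """Sample lambda_1..lambda_K on the grid for each selected homology dimension.

    Blocks are stacked in increasing dimension order (dim 0 above dim 1).  An
    empty selected-dimension bar set yields an all-zero block, not an error.
    """
    if grid is None:
        grid = LandscapeGrid()
    dims = tuple(sorted(set(int(d) for d in dims_used)))
    if not dims or any(d not in (0, 1) for d in dims):
        raise ValueError(f"dims_used must be a nonempty subset of {{0, 1}}, got {dims_used}")
    ts = np.asarray(grid.sample_points)
    blocks = []
    for dim in dims:
        tents = _tent_values(diagram.finite_bars(dim), ts)
        block = np.zeros((grid.n_functions, ts.size))
        if tents.shape[0]:
            k = min(grid.n_functions, tents.shape[0])
            # descending sort per column; top-k rows are lambda_1..lambda_k
            block[:k] = -np.sort(-tents, axis=0)[:k]
        blocks.append(block)
    return LandscapeMatrix(
        values=np.vstack(blocks),
        grid=grid,
        dims_used=dims,
        colony_id=diagram.colony_id,
        timepoint=diagram.timepoint,
    )
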