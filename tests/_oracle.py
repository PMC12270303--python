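"""Independent brute-force Rips persistence oracle.

Computes dimension-0/1 barcodes by reducing the *global* boundary matrix of
the full simplex list (vertices, edges, triangles) over GF(2), with no MST
shortcut, no edge classification and no compiled code.  It shares no code
path with the package implementation beyond numpy, so agreement between the
two is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rips_barcode_bruteforce(points: np.ndarray, threshold: float):
    """Return {0: [(birth, death), ...], 1: [...]} with inf deaths, zero-length dropped."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))

    simplices: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (i,)) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if dist[i, j] <= threshold:
            simplices.append((float(dist[i, j]), 1, (i, j)))
    for i, j, k in itertools.combinations(range(n), 3):
        w = max(dist[i, j], dist[i, k], dist[j, k])
        if w <= threshold:
            simplices.append((float(w), 2, (i, j, k)))
    simplices.sort()
    index = {s[2]: idx for idx, s in enumerate(simplices)}

    lowmap: dict[int, int] = {}
    death_col: dict[int, int] = {}   # birth row -> killing column
    positive: set[int] = set()
    for col_idx, (_val, dim, verts) in enumerate(simplices):
        col = 0
        if dim:
            for facet in itertools.combinations(verts, dim):
                col ^= 1 << index[facet]
        while col:
            low = col.bit_length() - 1
            if low in lowmap:
                col ^= lowmap[low]
            else:
                lowmap[low] = col
                death_col[low] = col_idx
                break
        if col == 0:
            positive.add(col_idx)

    bars: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    for row_idx in positive:
        val, dim, _ = simplices[row_idx]
        if dim > 1:
            continue
        death = simplices[death_col[row_idx]][0] if row_idx in death_col else math.inf
        if death > val:
            bars[dim].append((val, death))
    for dim in bars:
        bars[dim].sort()
    return bars
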