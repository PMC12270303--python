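"""Delimited-text readers and writers for every pipeline artifact.

Formats (all plain text, lossless round-trips):

* coordinates — one row per cell, two columns x,y; comma or tab delimited,
  header optional; named ``<colony>_t<frame>.csv``
* labels      — two columns colony_id,class
* barcode     — columns dim,birth,death with ``inf`` as the essential-class
  death sentinel
* landscape   — one row per landscape function, header row of grid sample
  points, first column tagging the homology dimension of the block
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .landscapes import LandscapeGrid, LandscapeMatrix
from .persistence import PersistenceBar, PersistenceDiagram

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_labels",
    "write_labels",
    "read_barcode",
    "write_barcode",
    "read_landscape",
    "write_landscape",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-numeric field {token!r}") from None


def read_coordinates(path) -> np.ndarray:
    """Read an (n, 2) coordinate array; tolerates header row, comma or tab."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.replace("\t", ",").split(",") if f.strip()]
            if lineno == 1 and any(not _is_number(f) for f in fields):
                continue  # header
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            rows.append((_parse_float(fields[0], path, lineno),
                         _parse_float(fields[1], path, lineno)))
    if not rows:
        raise ParseError(f"{path}: no coordinate rows found")
    return np.asarray(rows, dtype=float)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_coordinates(path, points: np.ndarray, header: bool = True) -> None:
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        if header:
            fh.write("x,y\n")
        for x, y in points:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["colony_id", "class"]:
        raise ParseError(f"{path}: expected columns colony_id,class; got {list(df.columns)}")
    return dict(zip(df["colony_id"], df["class"]))


def write_labels(path, labels: dict[str, str]) -> None:
    pd.DataFrame(
        {"colony_id": list(labels.keys()), "class": list(labels.values())}
    ).to_csv(path, index=False)


def write_barcode(path, diagram: PersistenceDiagram) -> None:
    with open(path, "w") as fh:
        fh.write(f"# threshold={diagram.threshold!r}\n")
        fh.write("dim,birth,death\n")
        for bar in diagram.bars:
            death = "inf" if math.isinf(bar.death) else repr(bar.death)
            fh.write(f"{bar.dim},{bar.birth!r},{death}\n")


def read_barcode(path) -> PersistenceDiagram:
    path = Path(path)
    threshold = math.nan
    bars: list[PersistenceBar] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "threshold=" in line:
                    threshold = _parse_float(line.split("threshold=")[1], path, lineno)
                continue
            if line == "dim,birth,death":
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            death = math.inf if fields[2] == "inf" else _parse_float(fields[2], path, lineno)
            bars.append(PersistenceBar(int(_parse_float(fields[0], path, lineno)),
                                       _parse_float(fields[1], path, lineno), death))
    if math.isnan(threshold):
        raise ParseError(f"{path}: missing threshold header")
    return PersistenceDiagram(bars, threshold)


def write_landscape(path, lm: LandscapeMatrix) -> None:
    n_funcs = lm.grid.n_functions
    with open(path, "w") as fh:
        fh.write("dim," + ",".join(repr(float(t)) for t in lm.grid.sample_points) + "\n")
        for i, row in enumerate(lm.values):
            dim = lm.dims_used[i // n_funcs]
            fh.write(f"{dim}," + ",".join(repr(float(v)) for v in row) + "\n")


def read_landscape(path) -> LandscapeMatrix:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty landscape file")
    header = lines[0].split(",")
    if header[0] != "dim":
        raise ParseError(f"{path}: line 1: expected header starting with 'dim'")
    sample_points = tuple(_parse_float(t, path, 1) for t in header[1:])
    dims, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(",")
        if len(fields) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
        dims.append(int(_parse_float(fields[0], path, lineno)))
        rows.append([_parse_float(v, path, lineno) for v in fields[1:]])
    dims_used = tuple(sorted(set(dims)))
    n_functions = len(dims) // len(dims_used)
    grid = LandscapeGrid(sample_points, n_functions)
    return LandscapeMatrix(np.asarray(rows), grid, dims_used)
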