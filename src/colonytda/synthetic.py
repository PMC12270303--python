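"""Synthetic stem-cell colony point clouds with treatment-specific spatial motifs.

Each colony is a 2-D point process on a disk-shaped footprint.  At timepoint 0
every treatment class draws from the same homogeneous uniform disk (an
undifferentiated morphology); as the timepoint approaches the colony's
``differentiation_time`` the class motif is expressed with linearly
increasing strength, and is fully expressed from then on:

* ``WT``       — uniform disk throughout (no motif).
* ``BMP4``     — sparse boundary fringe: a low-density annulus around a
                 denser interior.
* ``CHIR``     — enlarged footprint at constant cell count (lower density).
* ``DS``       — interior rosettes: circular low-density voids (hard-core
                 exclusion disks), the signature detected by dimension-1
                 homology.
* ``DS+CHIR``  — rosettes combined with an enlarged footprint.

These generative models are deliberately minimal: homogeneous Poisson-like
scatter plus density-ratio annuli and exclusion disks, chosen as the simplest
mechanisms that reproduce the qualitative motifs.  Default geometry puts the
typical nearest-neighbour spacing at a few coordinate units so topological
features fall inside the default landscape grid 1..40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CLASS_NAMES", "ColonySpec", "PointCloud", "generate_colony", "generate_dataset"]

CLASS_NAMES = ("WT", "BMP4", "CHIR", "DS", "DS+CHIR")

#: colony counts per treatment in the real 78-colony study
STUDY_CLASS_COUNTS = {"WT": 12, "BMP4": 16, "CHIR": 16, "DS": 17, "DS+CHIR": 17}


@dataclass(frozen=True)
class PointCloud:
    """One colony at one timepoint: (n, 2) cell-centroid coordinates in image units."""

    colony_id: str
    timepoint: int
    points: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a nonempty (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ColonySpec:
    """Generative parameters for one colony time series.

    ``differentiation_time`` is the frame index at which the class motif is
    fully expressed; motif strength ramps linearly from 0 at frame 0.
    Lengths are in image coordinate units.
    """

    class_label: str
    n_cells: int = 1000
    footprint_radius: float = 175.0
    fringe_width: float = 0.2        # fraction of footprint radius
    fringe_density_ratio: float = 0.25
    rosette_count: int = 4
    rosette_radius: float = 0.09     # fraction of footprint radius
    enlargement: float = 1.35        # fully-expressed footprint scale factor
    differentiation_time: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}; expected one of {CLASS_NAMES}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.footprint_radius > 0:
            raise ValueError("footprint_radius must be positive")
        if not (0 < self.fringe_width < 1 and self.fringe_density_ratio >= 0):
            raise ValueError("fringe parameters out of range")
        if self.rosette_count < 0 or not (0 < self.rosette_radius < 0.5):
            raise ValueError("rosette parameters out of range")
        # rosette disks must fit strictly inside the footprint
        if self.rosette_radius >= 0.5:
            raise ValueError("rosette_radius too large for the footprint")
        if self.enlargement < 1 or self.differentiation_time < 0:
            raise ValueError("enlargement must be >= 1 and differentiation_time >= 0")
        for name in ("footprint_radius", "fringe_width", "fringe_density_ratio",
                     "rosette_radius", "enlargement"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _motif_strength(spec: ColonySpec, timepoint: int) -> float:
    if spec.differentiation_time == 0:
        return 1.0
    return float(min(1.0, timepoint / spec.differentiation_time))


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    return np.c_[r * np.cos(th), r * np.sin(th)]


def _rosette_centres(spec: ColonySpec, radius: float) -> np.ndarray:
    """Fixed per-colony rosette centres, drawn so disks fit inside the footprint.

    Centres are retried for mutual separation of 2.4 hole radii so rosettes do
    not merge into one large void; after 200 tries overlap is accepted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    hole_r = spec.rosette_radius * radius
    max_c = radius - 1.4 * hole_r
    centres: list[np.ndarray] = []
    for _ in range(spec.rosette_count):
        for _ in range(200):
            c = _uniform_disk(rng, 1, max_c)[0]
            if all(np.hypot(*(c - o)) >= 2.4 * hole_r for o in centres):
                break
        centres.append(c)
    return np.asarray(centres) if centres else np.empty((0, 2))


def generate_colony(spec: ColonySpec, timepoint: int) -> PointCloud:
    """Sample the colony's point cloud at one frame; deterministic in (spec, timepoint)."""
    if timepoint < 0:
        raise ValueError("timepoint must be >= 0")
    s = _motif_strength(spec, timepoint)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, timepoint]))
    label = spec.class_label

    radius = spec.footprint_radius
    if label in ("CHIR", "DS+CHIR"):
        radius *= 1.0 + s * (spec.enlargement - 1.0)

    if label == "BMP4" and s > 0:
        pts = _fringe_disk(rng, spec, radius, s)
    elif label in ("DS", "DS+CHIR") and s > 0:
        pts = _rosette_disk(rng, spec, radius, s)
    else:
        pts = _uniform_disk(rng, spec.n_cells, radius)
    return PointCloud(f"{label}_{spec.seed}", timepoint, pts, label)


def _fringe_disk(rng: np.random.Generator, spec: ColonySpec, radius: float, s: float) -> np.ndarray:
    """Interior disk plus boundary annulus whose density is ratio x interior density."""
    w = spec.fringe_width * radius
    r_in = radius - w
    ratio = 1.0 + s * (spec.fringe_density_ratio - 1.0)
    area_in = np.pi * r_in**2
    area_an = np.pi * (radius**2 - r_in**2)
    n_an = int(round(spec.n_cells * ratio * area_an / (area_in + ratio * area_an)))
    n_in = spec.n_cells - n_an
    inner = _uniform_disk(rng, n_in, r_in)
    # uniform on the annulus via inverse-CDF of the radial density
    u = rng.random(n_an)
    r = np.sqrt(r_in**2 + u * (radius**2 - r_in**2))
    th = rng.random(n_an) * 2 * np.pi
    return np.vstack([inner, np.c_[r * np.cos(th), r * np.sin(th)]])


def _rosette_disk(rng: np.random.Generator, spec: ColonySpec, radius: float, s: float) -> np.ndarray:
    """Uniform disk with hard-core exclusion inside each rosette disk.

    The hole radius grows linearly with motif strength; at full strength no
    point lies inside any rosette disk.
    """
    centres = _rosette_centres(spec, radius)
    hole_r = s * spec.rosette_radius * radius
    pts = np.empty((0, 2))
    # rejection sampling in batches until n_cells accepted
    while pts.shape[0] < spec.n_cells:
        batch = _uniform_disk(rng, max(2 * spec.n_cells, 256), radius)
        if centres.size and hole_r > 0:
            d2 = ((batch[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
            batch = batch[np.all(d2 >= hole_r**2, axis=1)]
        pts = np.vstack([pts, batch])
    return pts[: spec.n_cells]


def generate_dataset(
    class_counts: dict[str, int],
    n_timepoints: int,
    master_seed: int,
    differentiation_time: int | None = None,
    **spec_overrides,
) -> tuple[list[list[PointCloud]], dict[str, str]]:
    """Generate labelled colony time series.

    Returns (series, labels): ``series`` holds one list of frames per colony,
    ``labels`` maps colony_id -> class.  Per-colony specs (and thus all
    randomness) derive reproducibly from ``master_seed``.  ``spec_overrides``
    forward to :class:`ColonySpec` (e.g. ``n_cells=150`` for scaled-down runs).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if any(c < 0 for c in class_counts.values()):
        raise ValueError("class counts must be >= 0")
    if sum(class_counts.values()) == 0:
        raise ValueError("empty dataset: all class counts are zero")
    if differentiation_time is None:
        differentiation_time = max(1, n_timepoints // 2)
    root = np.random.SeedSequence(master_seed)
    series: list[list[PointCloud]] = []
    labels: dict[str, str] = {}
    for ci, label in enumerate(sorted(class_counts)):
        for rep in range(class_counts[label]):
            colony_seed = int(
                np.random.SeedSequence([master_seed, ci, rep]).generate_state(1)[0] % (2**31)
            )
            spec = ColonySpec(
                class_label=label,
                differentiation_time=differentiation_time,
                seed=colony_seed,
                **spec_overrides,
            )
            cid = f"{label}_{rep:03d}"
            frames = [
                PointCloud(cid, t, generate_colony(spec, t).points, label)
                for t in range(n_timepoints)
            ]
            series.append(frames)
            labels[cid] = label
    return series, labels
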