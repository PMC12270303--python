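"""Pipeline orchestration: synthesize -> persist -> landscape -> train ->
evaluate / crosstime, with every artifact written as delimited text and a
manifest recording the configuration and seeds.

All randomness flows from one master seed, hierarchically derived per colony
and per repeat model, so any stage can be deleted and re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import TDANet, TrainingConfig, TrainingResult
from .evaluation import ConfusionMatrix, accuracy, class_metrics, confusion, cross_time_grid, time_differential
from .io import (
    read_barcode,
    read_coordinates,
    read_labels,
    read_landscape,
    write_barcode,
    write_coordinates,
    write_labels,
    write_landscape,
)
from .landscapes import LandscapeGrid, landscape_matrix
from .persistence import compute_diagram
from .synthetic import generate_dataset

log = logging.getLogger("colonytda")

STAGES = ("synthesize", "persist", "landscape", "train", "evaluate", "crosstime", "all")


@dataclass
class PipelineConfig:
    """Validated run configuration; serializable to/from a JSON file."""

    output_dir: str = "run"
    class_counts: dict = field(default_factory=lambda: {"WT": 4, "DS": 4})
    n_cells: int = 120
    footprint_radius: float = 80.0
    n_timepoints: int = 3
    differentiation_time: int | None = None
    timepoints: list | None = None      # timepoints to train on (default: all)
    grid_points: list | None = None     # default 1..40
    n_functions: int = 20
    dims_used: list = field(default_factory=lambda: [0, 1])
    threshold: float | None = None      # default 2 x grid maximum
    train_fraction: float = 0.70
    crosstime_train_fraction: float = 0.80
    max_epochs: int = 200
    patience: int = 5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    repeats: int = 10
    crosstime_offset: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.repeats < 1:
            raise ValueError("n_timepoints and repeats must be >= 1")
        if self.timepoints is None:
            self.timepoints = list(range(self.n_timepoints))
        if any(t < 0 or t >= self.n_timepoints for t in self.timepoints):
            raise ValueError("timepoints must lie in [0, n_timepoints)")
        if self.grid_points is None:
            self.grid_points = [float(t) for t in range(1, 41)]
        if self.threshold is None:
            self.threshold = 2.0 * max(self.grid_points)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def grid(self) -> LandscapeGrid:
        return LandscapeGrid(tuple(self.grid_points), self.n_functions)

    def training_config(self, seed: int, crosstime: bool = False) -> TrainingConfig:
        return TrainingConfig(
            train_fraction=self.crosstime_train_fraction if crosstime else self.train_fraction,
            max_epochs=self.max_epochs,
            patience=self.patience,
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            seed=seed,
        )


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


class Pipeline:
    """Stage runner over a :class:`PipelineConfig` rooted at ``config.output_dir``."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.root = Path(config.output_dir)
        self.coords_dir = self.root / "coords"
        self.barcodes_dir = self.root / "barcodes"
        self.landscapes_dir = self.root / "landscapes"
        self.models_dir = self.root / "models"
        self.reports_dir = self.root / "reports"
        self.labels_path = self.root / "labels.csv"

    # -- helpers ------------------------------------------------------------

    def _colony_ids(self) -> list[str]:
        if not self.labels_path.exists():
            raise FileNotFoundError(
                f"missing labels file {self.labels_path}; run the 'synthesize' stage first"
            )
        return list(read_labels(self.labels_path))

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(f"missing input {path}; run the '{producer}' stage first")
        return path

    def _frame_name(self, cid: str, t: int) -> str:
        return f"{cid}_t{t:03d}.csv"

    # -- stages -------------------------------------------------------------

    def synthesize(self) -> None:
        cfg = self.config
        self.coords_dir.mkdir(parents=True, exist_ok=True)
        series, labels = generate_dataset(
            cfg.class_counts,
            cfg.n_timepoints,
            master_seed=cfg.seed,
            differentiation_time=cfg.differentiation_time,
            n_cells=cfg.n_cells,
            footprint_radius=cfg.footprint_radius,
        )
        for frames in series:
            for cloud in frames:
                write_coordinates(
                    self.coords_dir / self._frame_name(cloud.colony_id, cloud.timepoint),
                    cloud.points,
                )
        write_labels(self.labels_path, labels)
        log.info("synthesize: %d colonies x %d frames", len(series), cfg.n_timepoints)

    def persist(self) -> None:
        cfg = self.config
        self.barcodes_dir.mkdir(parents=True, exist_ok=True)
        for cid in self._colony_ids():
            for t in range(cfg.n_timepoints):
                name = self._frame_name(cid, t)
                points = read_coordinates(self._require(self.coords_dir / name, "synthesize"))
                diagram = compute_diagram(points, cfg.threshold, colony_id=cid, timepoint=t)
                write_barcode(self.barcodes_dir / name, diagram)
        log.info("persist: barcodes written to %s", self.barcodes_dir)

    def landscape(self) -> None:
        cfg = self.config
        self.landscapes_dir.mkdir(parents=True, exist_ok=True)
        for cid in self._colony_ids():
            for t in range(cfg.n_timepoints):
                name = self._frame_name(cid, t)
                diagram = read_barcode(self._require(self.barcodes_dir / name, "persist"))
                lm = landscape_matrix(diagram, tuple(cfg.dims_used), cfg.grid)
                write_landscape(self.landscapes_dir / name, lm)
        log.info("landscape: matrices written to %s", self.landscapes_dir)

    def _features_at(self, t: int, colony_ids: list[str]) -> np.ndarray:
        rows = []
        for cid in colony_ids:
            path = self._require(self.landscapes_dir / self._frame_name(cid, t), "landscape")
            rows.append(read_landscape(path).flatten())
        return np.asarray(rows)

    def _train_at(self, t: int, crosstime: bool = False) -> list[TrainingResult]:
        cfg = self.config
        labels = read_labels(self._require(self.labels_path, "synthesize"))
        colony_ids = list(labels)
        X = self._features_at(t, colony_ids)
        y = [labels[c] for c in colony_ids]
        results = []
        for r in range(cfg.repeats):
            seed = _derive_seed(cfg.seed, 1000 + t, r)
            model = TDANet(X, y, config=cfg.training_config(seed, crosstime=crosstime))
            results.append(model.fit())
        return results

    def train(self) -> None:
        cfg = self.config
        self.models_dir.mkdir(parents=True, exist_ok=True)
        for t in cfg.timepoints:
            for r, result in enumerate(self._train_at(t)):
                result.save(self.models_dir / f"t{t:03d}_r{r:02d}.json")
        log.info("train: %d models per timepoint", cfg.repeats)

    def _load_models(self, t: int) -> list[TrainingResult]:
        results = []
        for r in range(self.config.repeats):
            path = self._require(self.models_dir / f"t{t:03d}_r{r:02d}.json", "train")
            results.append(TrainingResult.load(path))
        return results

    def evaluate(self) -> pd.DataFrame:
        """Per-timepoint validation metrics averaged over repeats."""
        cfg = self.config
        self.reports_dir.mkdir(parents=True, exist_ok=True)
        labels = read_labels(self._require(self.labels_path, "synthesize"))
        colony_ids = list(labels)
        y = np.asarray([labels[c] for c in colony_ids])
        classes = tuple(sorted(set(y.tolist())))
        rows = []
        for t in cfg.timepoints:
            X = self._features_at(t, colony_ids)
            cms, accs = [], []
            for result in self._load_models(t):
                idx = result.val_idx
                pred = result.predict(X[idx])
                accs.append(accuracy(pred, y[idx]))
                cms.append(confusion(pred, y[idx], classes))
            cm = ConfusionMatrix.average(cms)
            cm.to_frame().to_csv(self.reports_dir / f"confusion_t{t:03d}.csv")
            metrics = class_metrics(cm).table
            for cls in classes:
                rows.append({
                    "timepoint": t,
                    "class": cls,
                    "val_accuracy": float(np.mean(accs)),
                    "precision": metrics.loc[cls, "precision"],
                    "recall": metrics.loc[cls, "recall"],
                    "f1": metrics.loc[cls, "f1"],
                })
        table = pd.DataFrame(rows)
        table.to_csv(self.reports_dir / "metrics.csv", index=False)
        log.info("evaluate: metrics for %d timepoints", len(cfg.timepoints))
        return table

    def crosstime(self) -> pd.DataFrame:
        """Acc_T(S) grid and the time-differential table <T,S>."""
        cfg = self.config
        self.reports_dir.mkdir(parents=True, exist_ok=True)
        labels = read_labels(self._require(self.labels_path, "synthesize"))
        colony_ids = list(labels)
        y = [labels[c] for c in colony_ids]
        features = {t: self._features_at(t, colony_ids) for t in cfg.timepoints}
        models = {t: self._train_at(t, crosstime=True) for t in cfg.timepoints}
        grid = cross_time_grid(models, features, y)
        grid.to_frame().to_csv(self.reports_dir / "accuracy_grid.csv")
        diff = time_differential(grid, offset=cfg.crosstime_offset)
        diff.to_csv(self.reports_dir / "time_differential.csv")
        log.info("crosstime: grid over %d timepoints", len(cfg.timepoints))
        return diff

    # -- driver -------------------------------------------------------------

    def run(self, stage: str = "all") -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        stages = ("synthesize", "persist", "landscape", "train", "evaluate", "crosstime") \
            if stage == "all" else (stage,)
        for s in stages:
            log.info("running stage: %s", s)
            getattr(self, s)()
        self._write_manifest(stages)

    def _write_manifest(self, stages) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        manifest_path = self.root / "manifest.json"
        manifest = {"version": __version__, "config": asdict(self.config), "stages_run": []}
        if manifest_path.exists():
            with open(manifest_path) as fh:
                previous = json.load(fh)
            if previous.get("config") == manifest["config"]:
                manifest["stages_run"] = previous.get("stages_run", [])
        for s in stages:
            if s not in manifest["stages_run"]:
                manifest["stages_run"].append(s)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig, stage: str = "all") -> Pipeline:
    """Run one or all stages and return the pipeline handle."""
    pipe = Pipeline(config)
    pipe.run(stage)
    return pipe
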