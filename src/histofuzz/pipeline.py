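"""End-to-end orchestration: generate/load -> CLAHE -> CNN -> ANFIS -> report.

Stages run in a fixed order under one master seed.  The master seed fans
out to stage-specific seeds through a splitmix64-style hash of the stage
name, so any stage can be rerun independently and the whole pipeline is
byte-reproducible: the same configuration and seed yield an identical
report file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from histofuzz import anfis, clahe, cnn, evaluate, hbo, synth

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "run_pipeline",
    "desk_config",
]

logger = logging.getLogger("histofuzz")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed below 2**31 from the master seed and the stage name."""
    z = (master_seed * 0x9E3779B97F4A7C15 + zlib.crc32(stage.encode())) % (1 << 64)
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) % (1 << 64)
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) % (1 << 64)
    return int((z ^ (z >> 31)) % (1 << 31))


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters; mirrors the run-settings blocks of the study."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # data: either generate synthetic tiles or point at an existing manifest
    manifest_path: str | None = None
    n_per_class: dict = dataclasses.field(
        default_factory=lambda: {"VT": 100, "NVT": 100, "NT": 100})
    tile_size: int = 64
    # split
    train_fraction: float = 0.7
    # clahe
    clahe_enabled: bool = True
    clahe_grid: tuple[int, int] = (8, 8)
    clahe_clip: float = 2.0
    clahe_bins: int = 256
    # cnn
    cnn_preset: str = "desk"  # desk | full
    learning_rate: float = 0.002
    dropout: float = 0.25
    batch_size: int = 32
    epochs: int = 30
    # anfis
    anfis_inputs: int = 4
    anfis_mfs: int = 2
    anfis_folds: int = 5
    # hbo
    hbo_population: int = 15
    hbo_iterations: int = 40
    hbo_beta: float = 6.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clahe_grid" in raw:
            raw["clahe_grid"] = tuple(raw["clahe_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_grid"] = list(self.clahe_grid)
        return d


def desk_config(out_dir: str = "pipeline_out", seed: int = 0,
                n_per_class: int = 100) -> PipelineConfig:
    """Desk-scale default: 300 synthetic tiles, 70/30 split, small CNN."""
    return PipelineConfig(
        seed=seed, out_dir=out_dir,
        n_per_class={name: n_per_class for name in synth.CLASS_NAMES})


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _preprocess_images(images: np.ndarray, config: PipelineConfig) -> np.ndarray:
    cfg = clahe.CLAHEConfig(
        grid_rows=config.clahe_grid[0], grid_cols=config.clahe_grid[1],
        clip_limit=config.clahe_clip, n_bins=config.clahe_bins)
    return np.stack([clahe.apply_clahe(img, cfg) for img in images])


def run_pipeline(config: PipelineConfig,
                 write_images: bool = False) -> evaluate.EvaluationReport:
    """Execute all five stages and write artifacts under ``config.out_dir``.

    Artifacts: ``manifest.csv`` (when generating), ``features.csv``,
    ``anfis_model.json``, ``hbo_history.csv``, ``report.json``,
    ``confusion.csv`` and ``stage_log.json``.  Enhanced tiles are written
    as PNGs only when ``write_images`` is set (they are large and not
    needed downstream, which consumes arrays in memory).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: dict[str, dict] = {}

    def _stage(name: str, fn, *args, **kwargs):
        logger.info("stage %s ...", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # keep partial artifacts for debugging
            raise StageError(name, exc) from exc
        return result

    # 1. data ---------------------------------------------------------------
    def _load_data():
        if config.manifest_path:
            manifest = synth.DatasetManifest.load(config.manifest_path)
            images, labels = synth.load_manifest_images(manifest)
        else:
            spec = synth.SyntheticImageSpec(
                tile_size=config.tile_size, seed=derive_seed(config.seed, "generate"))
            images, labels = synth.generate_arrays(spec, config.n_per_class)
            pd.DataFrame({
                "path": [f"synthetic:{i}" for i in range(len(labels))],
                "label": [synth.CLASS_NAMES[k] for k in labels],
            }).to_csv(out_dir / "manifest.csv", index=False)
        return images, labels

    images, labels = _stage("generate", _load_data)
    stage_log["generate"] = {"n_images": int(len(labels)),
                             "seed": derive_seed(config.seed, "generate")}

    # 2. contrast enhancement ----------------------------------------------
    if config.clahe_enabled:
        images = _stage("preprocess", _preprocess_images, images, config)
    stage_log["preprocess"] = {
        "enabled": config.clahe_enabled,
        "grid": list(config.clahe_grid), "clip": config.clahe_clip}
    if write_images:
        import imageio.v3 as iio
        img_dir = out_dir / "enhanced"
        img_dir.mkdir(exist_ok=True)
        for i, img in enumerate(images):
            iio.imwrite(img_dir / f"tile_{i:05d}.png", img)

    # 3. split + CNN training ----------------------------------------------
    split_seed = derive_seed(config.seed, "split")
    train_idx, test_idx = evaluate.stratified_split_indices(
        labels, evaluate.SplitSpec(config.train_fraction, seed=split_seed))
    unit = images.astype(float) / 255.0

    def _train():
        spec_cls = (cnn.NetworkSpec.desk if config.cnn_preset == "desk"
                    else cnn.NetworkSpec.full_scale)
        spec = spec_cls(n_classes=len(synth.CLASS_NAMES), dropout=config.dropout)
        return cnn.train_feature_extractor(
            unit[train_idx], labels[train_idx], spec,
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=derive_seed(config.seed, "train-cnn"))

    network, loss_history = _stage("train-cnn", _train)
    network.save(out_dir / "network.npz")
    stage_log["train-cnn"] = {
        "epochs": config.epochs, "batch_size": config.batch_size,
        "learning_rate": config.learning_rate, "dropout": config.dropout,
        "loss_history": [round(v, 6) for v in loss_history],
        "seed": derive_seed(config.seed, "train-cnn")}

    # 4. feature extraction + ANFIS tuning ----------------------------------
    features = _stage("extract-features", cnn.extract_features, network, unit)
    pd.DataFrame(features, columns=[f"f_{i}" for i in range(features.shape[1])]) \
        .assign(label=[synth.CLASS_NAMES[k] for k in labels]) \
        .to_csv(out_dir / "features.csv", index=False)
    stage_log["extract-features"] = {"feature_dim": int(features.shape[1])}

    def _tune():
        projector = anfis.FeatureProjector.fit(features[train_idx],
                                               n_inputs=config.anfis_inputs)
        projected_train = projector.transform(features[train_idx])
        anfis_cfg = anfis.ANFISConfig(
            n_inputs=config.anfis_inputs, mfs_per_input=config.anfis_mfs,
            folds=config.anfis_folds, seed=derive_seed(config.seed, "anfis-folds"))
        hbo_cfg = hbo.HBOConfig(
            population_size=config.hbo_population,
            max_iterations=config.hbo_iterations,
            beta=config.hbo_beta, seed=derive_seed(config.seed, "tune-anfis"))
        model, history = anfis.tune_with_hbo(
            projected_train, labels[train_idx], anfis_cfg, hbo_cfg,
            class_names=synth.CLASS_NAMES)
        return projector, model, history

    projector, model, tune_history = _stage("tune-anfis", _tune)
    anfis.save_model(model, out_dir / "anfis_model.json", projector,
                     metadata={"seed": config.seed})
    hbo.save_history(tune_history, out_dir / "hbo_history.csv")
    stage_log["tune-anfis"] = {
        "population": config.hbo_population, "iterations": config.hbo_iterations,
        "final_fitness": float(tune_history[-1]),
        "seed": derive_seed(config.seed, "tune-anfis")}

    # 5. evaluation ----------------------------------------------------------
    def _evaluate():
        scores = anfis.anfis_forward_batch(
            projector.transform(features[test_idx]), model)
        preds = np.argmax(scores, axis=1)
        report = evaluate.confusion_and_metrics(
            labels[test_idx], preds, scores, class_names=synth.CLASS_NAMES)
        report.split = {
            "train_fraction": config.train_fraction,
            "n_train": int(train_idx.size), "n_test": int(test_idx.size),
            "seed": split_seed}
        return report

    report = _stage("evaluate", _evaluate)
    report.to_json(out_dir / "report.json")
    report.confusion_frame().to_csv(out_dir / "confusion.csv")
    stage_log["evaluate"] = {"n_test": report.n_test,
                             "overall_accuracy": report.overall_accuracy}
    with open(out_dir / "stage_log.json", "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict(), "stages": stage_log},
                  fh, indent=1, sort_keys=True)
    logger.info("pipeline done; overall accuracy %.4f", report.overall_accuracy)
    return report
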