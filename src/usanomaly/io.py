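"""Configuration, PNG/manifest I/O, seeding, and experiment orchestration.

Images are exchanged as 8-bit grayscale PNGs (masks as 0/255 PNGs); all
internal computation is floating point in [0, 1], with quantization only
at the I/O boundary, so a save/load round-trip is exact for masks and
within 1/255 for images.

A single global seed deterministically derives every per-stage seed as
``crc32("<global_seed>:<stage>") & 0x7fffffff``, so stages are independent
yet the whole experiment is reproducible from one integer.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _version
from .evaluation import compare_models, records_from_maps, size_stratified_metrics
from .anomaly import anomaly_map, find_threshold_algorithm1, validation_anomaly_maps
from .models import ModelConfig, ReconstructionModel, save_checkpoint
from .phantom import PhantomConfig, SplitDataset, generate_dataset
from .training import TrainConfig, train_model

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "derive_seed",
    "load_config",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "load_image_dir",
    "save_dataset",
    "load_dataset",
    "run_experiment",
]

log = logging.getLogger("usanomaly.io")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed: crc32 of ``"<seed>:<stage>"`` reduced to 31 bits."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# configuration schema (unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImageSection(_Strict):
    height: int = 64
    width: int = 64
    channels: int = 1


class CountsSection(_Strict):
    train: int = 853
    val: int = 94
    test: int = 200


class LesionSection(_Strict):
    area_min_px: float = 50.0
    area_max_px: float = 400.0
    drop_min: float = 0.3
    drop_max: float = 0.7
    softness: float = 1.0


class SpeckleSection(_Strict):
    scale: float = 0.3
    smoothness: float = 8.0


class ModelSection(_Strict):
    kinds: list[str] = Field(default_factory=lambda: ["ae", "vae", "swae"])
    latent_dim: int = 128
    channels: list[int] = Field(default_factory=lambda: [16, 32, 64, 64])
    spatial_bottleneck: bool = False
    beta: float = 1.0
    lam: float = 10.0
    n_projections: int = 50


class TrainSection(_Strict):
    batch_size: int = 16
    epochs: int = 150
    lr_max: float = 2e-4
    lr_min: float = 0.0
    augment_gamma: bool = True


class EvalSection(_Strict):
    thresholds: list[float] = Field(default_factory=lambda: [0.1, 0.2, 0.3])
    use_algorithm1: bool = True
    size_bins: int = 5


class ExperimentConfig(_Strict):
    """Validated end-to-end experiment configuration."""

    image: ImageSection = Field(default_factory=ImageSection)
    counts: CountsSection = Field(default_factory=CountsSection)
    lesion: LesionSection = Field(default_factory=LesionSection)
    speckle: SpeckleSection = Field(default_factory=SpeckleSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    evaluation: EvalSection = Field(default_factory=EvalSection)
    seed: int = 0

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            height=self.image.height,
            width=self.image.width,
            channels=self.image.channels,
            n_train=self.counts.train,
            n_val=self.counts.val,
            n_test=self.counts.test,
            lesion_area_min_px=self.lesion.area_min_px,
            lesion_area_max_px=self.lesion.area_max_px,
            lesion_drop_min=self.lesion.drop_min,
            lesion_drop_max=self.lesion.drop_max,
            lesion_softness=self.lesion.softness,
            speckle_scale=self.speckle.scale,
            smoothness=self.speckle.smoothness,
            seed=derive_seed(self.seed, "generate"),
        )

    def model_config_for(self, kind: str) -> ModelConfig:
        return ModelConfig(
            kind=kind,
            image_size=(self.image.height, self.image.width),
            in_channels=self.image.channels,
            channels=tuple(self.model.channels),
            latent_dim=self.model.latent_dim,
            spatial_bottleneck=self.model.spatial_bottleneck,
            beta=self.model.beta,
            lam=self.model.lam,
            n_projections=self.model.n_projections,
        )

    def train_config_for(self, kind: str) -> TrainConfig:
        return TrainConfig(
            batch_size=self.train.batch_size,
            epochs=self.train.epochs,
            lr_max=self.train.lr_max,
            lr_min=self.train.lr_min,
            seed=derive_seed(self.seed, f"train:{kind}"),
            augment_gamma=self.train.augment_gamma,
        )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(**raw)


class RunManifest(_Strict):
    """Record of one experiment run: resolved config, stage seeds, outputs."""

    config: ExperimentConfig
    stage_seeds: dict[str, int]
    outputs: dict[str, str]
    version: str = _version


# ---------------------------------------------------------------------------
# PNG and manifest I/O
# ---------------------------------------------------------------------------

def save_image(img: np.ndarray, path) -> None:
    """Quantize a [0, 1] image to 8 bits and write a PNG (grayscale or RGB)."""
    img = np.asarray(img, dtype=np.float64)
    q = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    if q.ndim == 3:
        q = np.moveaxis(q, 0, -1)  # (C, H, W) -> (H, W, C)
        if q.shape[-1] == 1:
            q = q[..., 0]
    PILImage.fromarray(q).save(path)


def load_image(path) -> np.ndarray:
    """Read an 8-bit PNG back into a [0, 1] float array ((H, W) or (C, H, W))."""
    with PILImage.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit PNG, got dtype {arr.dtype}")
    out = arr.astype(np.float64) / 255.0
    if out.ndim == 3:
        out = np.moveaxis(out, -1, 0)
    return out


def save_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    PILImage.fromarray((mask * 255).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    with PILImage.open(path) as im:
        arr = np.asarray(im)
    if not np.isin(arr, (0, 255)).all():
        raise ValueError(f"{path}: mask PNG must contain only 0 and 255")
    return (arr > 0).astype(np.uint8)


def load_image_dir(directory) -> list[np.ndarray]:
    """Load every PNG in a directory (sorted); all must share one size."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG files in {directory}")
    images, shapes = [], {}
    for p in paths:
        img = load_image(p)
        images.append(img)
        shapes.setdefault(img.shape, []).append(p.name)
    if len(shapes) > 1:
        listing = "; ".join(f"{shape}: {names}" for shape, names in shapes.items())
        raise ValueError(f"mixed image sizes in {directory}: {listing}")
    return images


def save_dataset(dataset: SplitDataset, out_dir) -> Path:
    """Write a split dataset as PNGs plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for split, items in (("train", dataset.train_normal), ("val", dataset.val_normal)):
        sub = out_dir / split
        sub.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(items):
            rel = f"{split}/{split}_{i:04d}.png"
            save_image(img, out_dir / rel)
            rows.append({"path": rel, "split": split, "mask_path": "",
                         "lesion_area_px": 0, "seed": dataset.seed})
    sub = out_dir / "test"
    msub = out_dir / "test_masks"
    sub.mkdir(parents=True, exist_ok=True)
    msub.mkdir(parents=True, exist_ok=True)
    for i, (img, mask) in enumerate(dataset.test_abnormal):
        rel = f"test/test_{i:04d}.png"
        mrel = f"test_masks/test_{i:04d}.png"
        save_image(img, out_dir / rel)
        save_mask(mask, out_dir / mrel)
        rows.append({"path": rel, "split": "test", "mask_path": mrel,
                     "lesion_area_px": int(mask.sum()), "seed": dataset.seed})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(root) -> SplitDataset:
    """Read a dataset back from its CSV manifest."""
    root = Path(root)
    df = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    train = [load_image(root / p) for p in df[df.split == "train"].path]
    val = [load_image(root / p) for p in df[df.split == "val"].path]
    test = [(load_image(root / r.path), load_mask(root / r.mask_path))
            for r in df[df.split == "test"].itertuples()]
    seed = int(df.seed.iloc[0]) if len(df) else 0
    return SplitDataset(train_normal=train, val_normal=val, test_abnormal=test, seed=seed)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig, out_dir) -> RunManifest:
    """generate -> train (each requested kind) -> detect -> compare.

    All artifacts (checkpoints, report.csv/json, sweep and size tables,
    manifest.json) land under ``out_dir``; re-running with the same seed
    reproduces identical reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = {"generate": derive_seed(cfg.seed, "generate")}
    outputs: dict[str, str] = {}

    log.info("stage=generate seed=%d", stage_seeds["generate"])
    dataset = generate_dataset(cfg.phantom_config())

    models: list[ReconstructionModel] = []
    histories = []
    for kind in cfg.model.kinds:
        tcfg = cfg.train_config_for(kind)
        stage_seeds[f"train:{kind}"] = tcfg.seed
        log.info("stage=train model=%s seed=%d epochs=%d", kind, tcfg.seed, tcfg.epochs)
        model, history = train_model(kind, dataset, tcfg, cfg.model_config_for(kind))
        models.append(model)
        ckpt = out_dir / f"{kind}.npz"
        save_checkpoint(model, ckpt)
        outputs[f"checkpoint:{kind}"] = str(ckpt)
        hist_df = pd.DataFrame({
            "epoch": range(1, history.epochs + 1),
            "loss": history.losses, "lr": history.lrs,
        })
        hist_path = out_dir / f"history_{kind}.csv"
        hist_df.to_csv(hist_path, index=False)
        outputs[f"history:{kind}"] = str(hist_path)
        histories.append(history)

    log.info("stage=evaluate models=%s", cfg.model.kinds)
    report = compare_models(
        models, dataset,
        thresholds=cfg.evaluation.thresholds,
        include_algorithm1=cfg.evaluation.use_algorithm1,
    )
    report_csv = out_dir / "report.csv"
    report.to_csv(report_csv, index=False)
    report.to_json(out_dir / "report.json", orient="records", indent=2)
    outputs["report"] = str(report_csv)

    # lesion-size stratification of each model at the middle fixed threshold
    mid_th = sorted(cfg.evaluation.thresholds)[len(cfg.evaluation.thresholds) // 2]
    size_rows = []
    for model in models:
        maps = [(anomaly_map(np.asarray(im, dtype=np.float64), model.reconstruct(im)), m)
                for im, m in dataset.test_abnormal]
        records = records_from_maps(maps, mid_th)
        table = size_stratified_metrics(records, n_bins=cfg.evaluation.size_bins)
        table.insert(0, "model", model.kind)
        size_rows.append(table)
    size_table = pd.concat(size_rows, ignore_index=True)
    size_path = out_dir / "size_stratified.csv"
    size_table.to_csv(size_path, index=False)
    outputs["size_stratified"] = str(size_path)

    manifest = RunManifest(config=cfg, stage_seeds=stage_seeds, outputs=outputs)
    with open(out_dir / "manifest.json", "w") as fh:
        fh.write(manifest.model_dump_json(indent=2))
    return manifest
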