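"""Training loop: Adam with a single-cycle cosine-annealed learning rate.

Protocol defaults follow the study setup for all three model kinds:
batch size 16, 150 epochs, Adam with maximum learning rate 2e-4 annealed
to ``lr_min`` (default 0) along one half-cosine over the epochs.  Models
are trained on *normal images only*; gamma-corrected (0.5 / 1.5) copies of
the training split are appended as augmentation when ``augment_gamma`` is
set, and the validation/test splits are never augmented.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .models import ModelConfig, ReconstructionModel
from .phantom import AUGMENT_GAMMAS, SplitDataset, gamma_correct

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainingDivergenceError",
    "cosine_annealing_lr",
    "train_model",
]

log = logging.getLogger("usanomaly.training")


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite; carries the epoch."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 150
    lr_max: float = 2e-4
    lr_min: float = 0.0
    seed: int = 0
    augment_gamma: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0.0 <= self.lr_min <= self.lr_max:
            raise ValueError("need 0 <= lr_min <= lr_max")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss and the learning rate actually used."""

    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    model_kind: str = ""
    seed: int = 0

    @property
    def epochs(self) -> int:
        return len(self.losses)


def cosine_annealing_lr(t: int, total: int, lr_max: float = 2e-4,
                        lr_min: float = 0.0) -> float:
    """Single half-cosine schedule: ``lr_max`` at t=0 down to ``lr_min`` at
    t=total, no warm restarts."""
    if total < 1:
        raise ValueError("total epochs must be >= 1")
    if not 0 <= t <= total:
        raise ValueError(f"epoch index {t} outside [0, {total}]")
    return lr_min + (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / total)) / 2.0


def _training_array(dataset: SplitDataset, cfg: TrainConfig) -> np.ndarray:
    """Stack the normal training split (plus gamma-augmented copies) into
    an (N, C, H, W) array."""
    imgs = list(dataset.train_normal)
    if not imgs:
        raise ValueError("training split is empty")
    if cfg.augment_gamma:
        for g in AUGMENT_GAMMAS:
            imgs.extend(gamma_correct(im, g) for im in dataset.train_normal)
    stacked = np.stack([im if im.ndim == 3 else im[None] for im in imgs])
    return np.ascontiguousarray(stacked, dtype=np.float64)


def train_model(
    model_kind: str,
    dataset: SplitDataset,
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
) -> tuple[ReconstructionModel, TrainHistory]:
    """Train one model kind on the normal training split.

    Fully seeded end-to-end: parameter init, epoch shuffling, VAE noise,
    SWAE prior draws and projection directions all derive from
    ``cfg.seed``, so identical configs reproduce identical histories.
    Returns the final-epoch parameters and the per-epoch history.
    """
    data = _training_array(dataset, cfg)
    n, c, h, w = data.shape
    if model_config is None:
        model_config = ModelConfig(kind=model_kind, image_size=(h, w), in_channels=c)
    elif model_config.kind != model_kind:
        raise ValueError(
            f"model_config.kind {model_config.kind!r} != requested {model_kind!r}"
        )
    if tuple(model_config.image_size) != (h, w) or model_config.in_channels != c:
        raise ValueError(
            f"model_config expects {(model_config.in_channels, *model_config.image_size)}"
            f" but training data is {(c, h, w)}"
        )

    ss = np.random.SeedSequence(cfg.seed)
    init_seed, shuffle_seed, noise_seed = (int(s) for s in ss.generate_state(3))
    model = ReconstructionModel(model_config, seed=init_seed)
    optimizer = model.make_optimizer(lr=cfg.lr_max, beta1=cfg.adam_beta1,
                                     beta2=cfg.adam_beta2)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    noise_rng = np.random.default_rng(noise_seed)

    history = TrainHistory(model_kind=model_kind, seed=cfg.seed)
    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(epoch, cfg.epochs, cfg.lr_max, cfg.lr_min)
        optimizer.lr = lr
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):  # last partial batch kept
            batch = data[order[start : start + cfg.batch_size]]
            try:
                comps = model.train_step(batch, noise_rng)
            except FloatingPointError as exc:
                raise TrainingDivergenceError(epoch) from exc
            optimizer.step()
            epoch_losses.append(comps["loss"])
        mean_loss = float(np.mean(epoch_losses))
        if not math.isfinite(mean_loss):
            raise TrainingDivergenceError(epoch)
        history.losses.append(mean_loss)
        history.lrs.append(lr)
        log.info("model=%s epoch=%d/%d lr=%.6g loss=%.6g",
                 model_kind, epoch + 1, cfg.epochs, lr, mean_loss)
    return model, history
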