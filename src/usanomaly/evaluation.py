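"""Evaluation protocol: reconstruction RMSE, pixel-overlap metrics
(Dice / TPR / FPR), threshold sweeps, lesion-size stratification, and
cross-model comparison tables.

Conventions for degenerate pixel-count denominators (which the clinical
study never meets — every test image there has a lesion — but synthetic
configurations can): with both masks empty, dice = 1 and fpr = 0 while
tpr is undefined; with an empty truth mask but a nonempty prediction,
dice = 0 and tpr is undefined.  Undefined values are returned as NaN and
excluded from means.  Macro averages (per-image means) are the headline
numbers; micro averages (pooled pixel counts) are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomaly import (
    FIXED_THRESHOLDS,
    Threshold,
    anomaly_map,
    binarize,
    find_threshold_algorithm1,
    validation_anomaly_maps,
)
from .models import ReconstructionModel
from .phantom import SplitDataset

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "rmse",
    "dataset_rmse",
    "confusion_counts",
    "overlap_metrics",
    "records_from_maps",
    "threshold_sweep",
    "size_stratified_metrics",
    "compare_models",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricRecord:
    image_id: int
    dice: float
    tpr: float
    fpr: float
    lesion_area_px: int
    threshold: float


def rmse(x: np.ndarray, xhat: np.ndarray) -> float:
    """Root-mean-square reconstruction error over all pixels."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.sqrt(np.mean((xhat - x) ** 2)))


def dataset_rmse(
    model: ReconstructionModel, images: list[np.ndarray]
) -> tuple[float, float]:
    """Average reconstruction RMSE over a list of images.

    Returns ``(macro, micro)``: the mean of per-image RMSEs (headline) and
    the pooled-pixel RMSE.
    """
    if not images:
        raise ValueError("need at least one image")
    per_image = []
    pooled_sq, pooled_n = 0.0, 0
    for im in images:
        xhat = model.reconstruct(im)
        per_image.append(rmse(im, xhat))
        d = np.asarray(im, dtype=np.float64) - xhat
        pooled_sq += float(np.sum(d**2))
        pooled_n += d.size
    return float(np.mean(per_image)), float(np.sqrt(pooled_sq / pooled_n))


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise cross-tabulation of a predicted vs ground-truth mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("masks must be binary (values in {0, 1})")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """Dice, TPR, FPR from pixel confusion counts.

    dice = 2TP / (2TP + FN + FP);  tpr = TP / (TP + FN);
    fpr = FP / (FP + TN).  Undefined ratios (empty denominators) are NaN.
    """
    if min(c.tp, c.fp, c.fn, c.tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom_dice = 2 * c.tp + c.fn + c.fp
    dice = 2 * c.tp / denom_dice if denom_dice else 1.0  # both masks empty
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else float("nan")
    return float(dice), float(tpr), float(fpr)


def records_from_maps(
    maps_and_truths: list[tuple[np.ndarray, np.ndarray]], threshold: float
) -> list[MetricRecord]:
    """Binarize precomputed anomaly maps and score them against truth masks."""
    records = []
    for i, (amap, truth) in enumerate(maps_and_truths):
        pred = binarize(amap, threshold)
        dice, tpr, fpr = overlap_metrics(confusion_counts(pred, truth))
        records.append(MetricRecord(
            image_id=i, dice=dice, tpr=tpr, fpr=fpr,
            lesion_area_px=int(np.sum(truth)), threshold=float(threshold),
        ))
    return records


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=np.float64)
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def threshold_sweep(
    model: ReconstructionModel,
    testset: list[tuple[np.ndarray, np.ndarray]],
    thresholds: list[float],
) -> pd.DataFrame:
    """Mean Dice/TPR/FPR of one model across a threshold grid.

    Anomaly maps are computed once and re-thresholded, so the
    threshold-monotonicity of TPR/FPR is exact on the fixed map set.
    Rows are sorted by ascending threshold.
    """
    if not testset or not thresholds:
        raise ValueError("testset and thresholds must be nonempty")
    maps = [(anomaly_map(np.asarray(im, dtype=np.float64), model.reconstruct(im)), mask)
            for im, mask in testset]
    rows = []
    for th in sorted(float(t) for t in thresholds):
        records = records_from_maps(maps, th)
        rows.append({
            "model": model.kind,
            "threshold": th,
            "mean_dice": _nanmean([r.dice for r in records]),
            "mean_tpr": _nanmean([r.tpr for r in records]),
            "mean_fpr": _nanmean([r.fpr for r in records]),
        })
    return pd.DataFrame(rows)


def size_stratified_metrics(records: list[MetricRecord], n_bins: int = 5) -> pd.DataFrame:
    """Mean Dice/TPR within lesion-size (pixel-area) quantile bins.

    Bin edges are area quantiles over the given records, so bins stay
    populated at any dataset scale; if fewer distinct sizes than bins
    exist, bins are merged with a warning.
    """
    if not records:
        raise ValueError("need at least one record")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    df = pd.DataFrame([{
        "lesion_area_px": r.lesion_area_px, "dice": r.dice, "tpr": r.tpr,
    } for r in records])
    if n_bins == 1:
        bins = pd.Series(["all"] * len(df), index=df.index)
    else:
        try:
            bins = pd.qcut(df["lesion_area_px"], q=n_bins, duplicates="raise")
        except ValueError:
            warnings.warn(
                f"fewer distinct lesion sizes than {n_bins} bins; merging bins",
                stacklevel=2,
            )
            bins = pd.qcut(df["lesion_area_px"], q=n_bins, duplicates="drop")
    grouped = df.groupby(bins, observed=True)
    out = grouped.agg(
        mean_dice=("dice", "mean"), mean_tpr=("tpr", "mean"), count=("dice", "size")
    ).reset_index(names="size_range")
    out["size_range"] = out["size_range"].astype(str)
    return out


def compare_models(
    models: list[ReconstructionModel],
    dataset: SplitDataset,
    thresholds: list[float] | None = None,
    include_algorithm1: bool = True,
) -> pd.DataFrame:
    """Side-by-side model report mirroring the study's comparison tables.

    For each model: normal-validation RMSE, abnormal-test RMSE, and
    Dice/TPR/FPR (macro and micro) at each fixed threshold plus the
    validation-derived threshold.  One row per (model, threshold).
    """
    if not models:
        raise ValueError("need at least one model")
    thresholds = list(FIXED_THRESHOLDS) if thresholds is None else list(thresholds)
    rows = []
    for model in models:
        val_rmse, _ = dataset_rmse(model, dataset.val_normal)
        test_rmse, _ = dataset_rmse(model, [im for im, _ in dataset.test_abnormal])
        maps = [(anomaly_map(np.asarray(im, dtype=np.float64), model.reconstruct(im)), mask)
                for im, mask in dataset.test_abnormal]
        th_list: list[Threshold] = [Threshold(t, "fixed") for t in sorted(thresholds)]
        if include_algorithm1:
            val_maps = validation_anomaly_maps(model, dataset.val_normal)
            th_list.append(find_threshold_algorithm1(val_maps))
        for th in th_list:
            records = records_from_maps(maps, th.value)
            pooled = ConfusionCounts(
                tp=sum(confusion_counts(binarize(m, th.value), t).tp for m, t in maps),
                fp=sum(confusion_counts(binarize(m, th.value), t).fp for m, t in maps),
                fn=sum(confusion_counts(binarize(m, th.value), t).fn for m, t in maps),
                tn=sum(confusion_counts(binarize(m, th.value), t).tn for m, t in maps),
            )
            micro_dice, micro_tpr, micro_fpr = overlap_metrics(pooled)
            rows.append({
                "model": model.kind,
                "threshold_source": th.source,
                "threshold": th.value,
                "val_rmse_normal": val_rmse,
                "test_rmse_abnormal": test_rmse,
                "mean_dice": _nanmean([r.dice for r in records]),
                "mean_tpr": _nanmean([r.tpr for r in records]),
                "mean_fpr": _nanmean([r.fpr for r in records]),
                "micro_dice": micro_dice,
                "micro_tpr": micro_tpr,
                "micro_fpr": micro_fpr,
            })
    return pd.DataFrame(rows)
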