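"""Gland segmentation stage: contract, classical baseline, metrics, edits.

Segmentation is a per-pixel binary classification.  The stage contract is
any callable ``image -> binary mask``; a learned model can be dropped in.
The desk-scale baseline here is classical: local-contrast normalization,
adaptive thresholding, morphological opening and small-component removal.

Evaluation uses the standard confusion-matrix metrics (accuracy,
sensitivity, specificity, IoU).  ``apply_manual_edits`` models the
reviewer pass in which missed areas are added and spurious areas removed
from an automatic mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import filters, measure, morphology

__all__ = [
    "SegmentationError",
    "SegMetrics",
    "SegConfig",
    "segment_baseline",
    "evaluate_segmentation",
    "evaluate_many",
    "apply_manual_edits",
]


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs."""


@dataclass
class SegMetrics:
    """Confusion-matrix metrics, all in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    iou: float


@dataclass
class SegConfig:
    """Baseline parameters (defaults tuned on the synthetic generator).

    bg_sigma: Gaussian scale (px) of the subtracted background estimate.
    block_size: odd window (px) of the adaptive local threshold.
    offset: counts a pixel must exceed its local threshold by.
    opening_radius: disk radius (px) of the morphological opening.
    min_area: components below this pixel count are removed.
    """

    bg_sigma: float = 25.0
    block_size: int = 75
    offset: float = 25.0
    opening_radius: int = 1
    min_area: float = 64  # may be inf (removes everything)


def segment_baseline(image: np.ndarray, config: SegConfig | None = None) -> np.ndarray:
    """Classical baseline segmentation of a grayscale meibography image."""
    if config is None:
        config = SegConfig()
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise SegmentationError("need a non-empty 2-D grayscale image")
    img = image.astype(float)
    norm = img - gaussian_filter(img, config.bg_sigma)
    local = filters.threshold_local(norm, block_size=config.block_size, method="gaussian")
    mask = norm > (local + config.offset)
    if config.opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(config.opening_radius))
    return _drop_small_components(mask, config.min_area)


def _drop_small_components(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_area`` pixels."""
    if not np.isfinite(min_area):
        return np.zeros_like(mask)
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def _confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise SegmentationError("pred and truth dims must match")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, tn, fp, fn


def _metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> SegMetrics:
    total = tp + tn + fp + fn
    # Empty-denominator conventions: a metric with nothing to get wrong is 1.
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    return SegMetrics(
        accuracy=(tp + tn) / total, sensitivity=sens, specificity=spec, iou=iou
    )


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """accuracy=(TP+TN)/all, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    IoU=TP/(TP+FP+FN); see :func:`_metrics_from_counts` for empty-denominator
    conventions."""
    return _metrics_from_counts(*_confusion(pred, truth))


def evaluate_many(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]], mode: str = "mean"
) -> SegMetrics:
    """Aggregate metrics over (pred, truth) pairs.

    ``mode="mean"`` (default) averages per-image metrics; ``mode="pooled"``
    pools the confusion counts across images first.
    """
    if mode not in ("mean", "pooled"):
        raise SegmentationError("mode must be 'mean' or 'pooled'")
    if mode == "pooled":
        tot = np.zeros(4, dtype=np.int64)
        for pred, truth in pairs:
            tot += _confusion(pred, truth)
        return _metrics_from_counts(*tot)
    collected = [evaluate_segmentation(p, t) for p, t in pairs]
    if not collected:
        raise SegmentationError("no pairs to evaluate")
    return SegMetrics(
        accuracy=float(np.mean([m.accuracy for m in collected])),
        sensitivity=float(np.mean([m.sensitivity for m in collected])),
        specificity=float(np.mean([m.specificity for m in collected])),
        iou=float(np.mean([m.iou for m in collected])),
    )


def apply_manual_edits(
    mask: np.ndarray,
    add_regions: Sequence[np.ndarray] = (),
    remove_regions: Sequence[np.ndarray] = (),
) -> np.ndarray:
    """Reviewer edits: result = (mask OR all adds) minus all removes.

    Removal has precedence where a pixel is both added and removed.
    """
    out = np.asarray(mask) > 0
    for region in add_regions:
        region = np.asarray(region) > 0
        if region.shape != out.shape:
            raise SegmentationError("add region dims must match mask")
        out = out | region
    for region in remove_regions:
        region = np.asarray(region) > 0
        if region.shape != out.shape:
            raise SegmentationError("remove region dims must match mask")
        out = out & ~region
    return out
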