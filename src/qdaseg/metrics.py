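"""Segmentation evaluation: confusion-matrix rates, Dice, and the 95th
percentile Hausdorff distance (HD95) between mask boundaries.

Rates with zero denominators are reported as None with a flag rather than
silently as 0.  HD95 uses linear-interpolation percentiles of the directed
boundary nearest-neighbor distances and combines the two directions by max
(the common multi-center benchmark convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["ConfusionCounts", "Rates", "confusion", "rates", "hausdorff95",
           "evaluate_masks"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Rates:
    """Fractional rates; a None value means the denominator was zero."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    specificity: float | None
    dice: float | None

    @property
    def undefined(self) -> list[str]:
        return [k for k, v in self.__dict__.items() if v is None]


def confusion(
    pred: np.ndarray, truth: np.ndarray, domain: np.ndarray | None = None
) -> ConfusionCounts:
    """Voxelwise confusion counts, optionally restricted to ``domain``
    (e.g. the brain mask, so background true negatives do not inflate
    accuracy)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if domain is not None:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != pred.shape:
            raise ValueError("domain shape mismatch")
        pred, truth = pred[domain], truth[domain]
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def rates(c: ConfusionCounts) -> Rates:
    """accuracy, recall, precision, specificity and Dice from counts."""
    return Rates(
        accuracy=_ratio(c.tp + c.tn, c.total),
        recall=_ratio(c.tp, c.tp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        specificity=_ratio(c.tn, c.tn + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def _boundary_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    pts = np.argwhere(mask & ~interior).astype(np.float64)
    return pts * spacing[None, :]


def hausdorff95(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, ...] | None = None,
) -> float | None:
    """95th-percentile symmetric boundary distance (mm if spacing given,
    else pixels).  Returns None when either mask is empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not pred.any() or not truth.any():
        return None
    sp = np.ones(pred.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    a = _boundary_points(pred, sp)
    b = _boundary_points(truth, sp)
    d_ab, _ = cKDTree(b).query(a, k=1)
    d_ba, _ = cKDTree(a).query(b, k=1)
    return float(
        max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
    )


def evaluate_masks(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, ...] | None = None,
    domain: np.ndarray | None = None,
) -> dict:
    """Full metric report as a plain dict (JSON-serializable)."""
    c = confusion(pred, truth, domain=domain)
    r = rates(c)
    return {
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
        "accuracy": r.accuracy,
        "recall": r.recall,
        "precision": r.precision,
        "specificity": r.specificity,
        "dice": r.dice,
        "hd95": hausdorff95(pred, truth, spacing),
        "undefined": r.undefined,
    }
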