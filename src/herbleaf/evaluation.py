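"""Evaluation: pixel metrics, leaf-level extraction bookkeeping, trait errors.

Three levels of evaluation are supported:

* pixel level — a 2x2 confusion matrix between predicted and ground-truth
  masks, and mean intersection-over-union (MIoU) over classes;
* leaf level — candidates are matched one-to-one to ground-truth intact
  leaves by mask IoU, and the extraction run is summarized as TP (matched
  and kept), FN (matched but rejected by the classifier), FP (kept but
  matching no intact leaf) and undetected (intact leaves with no matching
  candidate at all), so that expected = TP + FN + undetected and
  extracted = TP + FN always hold;
* trait level — per-trait MAE, MSE and RMSE between predicted and
  ground-truth trait vectors over matched leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from herbleaf.components import LeafCandidate
from herbleaf.synthetic import LeafInventory
from herbleaf.traits import TRAIT_NAMES

__all__ = [
    "UndefinedMetricError",
    "ConfusionMatrix",
    "ExtractionCounts",
    "confusion_from_masks",
    "miou",
    "classification_metrics",
    "match_extracted_leaves",
    "trait_error_table",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested on counts that cannot define it."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """N x N pixel confusion table; entry (x, y) = pixels of true class x
    predicted as class y."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ExtractionCounts:
    """Leaf-level bookkeeping of one extraction run."""

    tp: int
    fp: int
    fn: int
    undetected: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.undetected) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_expected(self) -> int:
        return self.tp + self.fn + self.undetected

    @property
    def total_extracted(self) -> int:
        return self.tp + self.fn


def confusion_from_masks(pred: np.ndarray, gt: np.ndarray) -> ConfusionMatrix:
    """2x2 pixel confusion between binary masks (classes: background, leaf)."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {gt.shape}")
    counts = np.array(
        [
            [int((~gt & ~pred).sum()), int((~gt & pred).sum())],
            [int((gt & ~pred).sum()), int((gt & pred).sum())],
        ]
    )
    return ConfusionMatrix(counts=counts)


def miou(cm: ConfusionMatrix, skip_absent: bool = True) -> float:
    """Mean over classes of N_xx / (sum_y N_xy + sum_y N_yx - N_xx).

    Classes whose union is empty (never true nor predicted) carry no
    information; by default they are skipped from the mean rather than
    counted as zero, so a sheet with no leaf pixels is not penalized.
    """
    c = cm.counts.astype(float)
    ious = []
    for x in range(cm.n_classes):
        union = c[x, :].sum() + c[:, x].sum() - c[x, x]
        if union == 0:
            if not skip_absent:
                ious.append(0.0)
            continue
        ious.append(c[x, x] / union)
    if not ious:
        raise UndefinedMetricError("no class has a non-empty union")
    return float(np.mean(ious))


def classification_metrics(
    tp: int, fp: int, fn: int, tn: int | None = None
) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from raw counts.

    ``tn`` may be omitted for leaf-level evaluation, where true negatives are
    not a meaningful population; accuracy is then reported as NaN.  All-zero
    counts define no metric at all and raise.
    """
    if min(tp, fp, fn) < 0 or (tn is not None and tn < 0):
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0 and not tn:
        raise UndefinedMetricError("all counts are zero; no metric is defined")
    nan = float("nan")
    precision = tp / (tp + fp) if tp + fp else nan
    recall = tp / (tp + fn) if tp + fn else nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else nan
    if tn is None:
        accuracy = nan
    else:
        accuracy = (tp + tn) / (tp + tn + fp + fn)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def _pair_iou(
    bbox_a: tuple[int, int, int, int], mask_a: np.ndarray,
    bbox_b: tuple[int, int, int, int], mask_b: np.ndarray,
) -> float:
    """IoU of two masks given in their own bbox frames (sheet coordinates)."""
    ax0, ay0, ax1, ay1 = bbox_a
    bx0, by0, bx1, by1 = bbox_b
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax1, bx1), min(ay1, by1)
    area_a, area_b = int(mask_a.sum()), int(mask_b.sum())
    if ix0 >= ix1 or iy0 >= iy1:
        inter = 0
    else:
        sub_a = mask_a[iy0 - ay0 : iy1 - ay0, ix0 - ax0 : ix1 - ax0]
        sub_b = mask_b[iy0 - by0 : iy1 - by0, ix0 - bx0 : ix1 - bx0]
        inter = int((sub_a & sub_b).sum())
    union = area_a + area_b - inter
    return inter / union if union else 0.0


def match_extracted_leaves(
    candidates_all: Sequence[LeafCandidate],
    kept: Sequence[LeafCandidate],
    inventory: LeafInventory,
    iou_threshold: float = 0.5,
) -> ExtractionCounts:
    """Match candidates to ground-truth intact leaves and tally the run.

    Matching is greedy one-to-one by descending mask IoU, accepting pairs at
    or above ``iou_threshold``.  A matched candidate that was kept is a TP; a
    matched candidate the classifier rejected is an FN; a kept candidate with
    no match is an FP; an intact leaf no candidate matched is undetected.
    """
    intact = [leaf for leaf in inventory.leaves if leaf.category == "intact"]
    kept_ids = {c.id for c in kept}
    pairs = []
    for ci, cand in enumerate(candidates_all):
        m_c = np.asarray(cand.mask_crop) > 0
        for li, leaf in enumerate(intact):
            iou = _pair_iou(cand.bbox, m_c, leaf.bbox, np.asarray(leaf.mask_crop) > 0)
            if iou >= iou_threshold:
                pairs.append((iou, ci, li))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_c: dict[int, int] = {}
    matched_l: set[int] = set()
    for iou, ci, li in pairs:
        if ci in matched_c or li in matched_l:
            continue
        matched_c[ci] = li
        matched_l.add(li)

    tp = sum(1 for ci in matched_c if candidates_all[ci].id in kept_ids)
    fn = len(matched_c) - tp
    fp = sum(
        1 for ci, cand in enumerate(candidates_all)
        if cand.id in kept_ids and ci not in matched_c
    )
    undetected = len(intact) - len(matched_l)
    return ExtractionCounts(tp=tp, fp=fp, fn=fn, undetected=undetected)


def trait_error_table(
    pred: Mapping[int, Mapping[str, float]],
    gt: Mapping[int, Mapping[str, float]],
) -> pd.DataFrame:
    """Per-trait MAE, MSE and RMSE over leaves present in both mappings."""
    ids = sorted(set(pred) & set(gt))
    if not ids:
        raise ValueError("no common leaf ids between predicted and ground truth")
    rows = {}
    for trait in TRAIT_NAMES:
        diffs = np.array([pred[i][trait] - gt[i][trait] for i in ids], dtype=float)
        mae = float(np.mean(np.abs(diffs)))
        mse = float(np.mean(diffs**2))
        rows[trait] = {"MAE": mae, "MSE": mse, "RMSE": float(np.sqrt(mse))}
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(TRAIT_NAMES)]
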