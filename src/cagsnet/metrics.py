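"""Segmentation evaluation: Dice, sensitivity, PPV and 95% Hausdorff
distance over the nested BraTS tumor regions.

Regions are derived from the integer label convention {0 background,
1 necrotic/non-enhancing core (NCR/NET), 2 edema (ED), 4 enhancing tumor
(ET)}:

    ET = label 4,   TC = ET u label 1,   WT = TC u label 2

so ET is contained in TC is contained in WT by construction.

The 95HD is the symmetric 95th percentile of Euclidean surface-to-surface
distances: surfaces are the boundary voxels of each mask (mask minus its
erosion), distances honour anisotropic voxel spacing (mm), and the reported
value is the max of the two directed 95th percentiles — the BraTS
convention. Degenerate cases follow fixed conventions: both masks empty ->
0 (a perfect absence), exactly one empty -> the image diagonal as a sentinel
(configurable), with a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts", "RegionMaskSet", "MetricReport", "REGIONS",
    "region_masks", "confusion_counts", "overlap_metrics", "hausdorff95",
    "evaluate_case", "average_reports", "write_reports",
]

REGIONS = ("WT", "TC", "ET")
_VALID_LABELS = frozenset((0, 1, 2, 4))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class RegionMaskSet:
    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region.lower())


@dataclass
class MetricReport:
    """Per-region metrics for one case (or an average over cases)."""

    case_id: str
    scores: dict = field(default_factory=dict)  # region -> metric -> float

    def as_rows(self) -> list[dict]:
        return [
            {"case_id": self.case_id, "region": region, **metrics}
            for region, metrics in self.scores.items()
        ]


def region_masks(labels: np.ndarray) -> RegionMaskSet:
    """Build the nested WT/TC/ET masks from an integer label volume."""
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    unknown = sorted(present - _VALID_LABELS)
    if unknown:
        raise ValueError(f"unknown label values {unknown}; expected subset of "
                         f"{sorted(_VALID_LABELS)}")
    et = labels == 4
    tc = et | (labels == 1)
    wt = tc | (labels == 2)
    return RegionMaskSet(wt=wt, tc=tc, et=et)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(DSC, sensitivity, PPV). With TP = 0: all three are 1 if the masks are
    both empty (FP = FN = 0), else 0."""
    if c.tp == 0:
        val = 1.0 if (c.fp == 0 and c.fn == 0) else 0.0
        return val, val, val
    dsc = 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp)
    sens = c.tp / (c.tp + c.fn)
    ppv = c.tp / (c.tp + c.fp)
    return dsc, sens, ppv


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: the mask minus its one-voxel erosion."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def hausdorff95(truth: np.ndarray, pred: np.ndarray,
                spacing=(1.0, 1.0, 1.0), percentile: float = 95.0,
                empty_sentinel: float | None = None) -> float:
    """Symmetric `percentile`-th Hausdorff distance between mask surfaces,
    in spacing units (mm for mm spacing)."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(f"truth shape {truth.shape} != pred shape {pred.shape}")
    spacing = np.asarray(spacing, dtype=float)
    t_empty, p_empty = not truth.any(), not pred.any()
    if t_empty and p_empty:
        return 0.0
    if t_empty or p_empty:
        if empty_sentinel is None:
            empty_sentinel = float(
                np.linalg.norm(np.asarray(truth.shape) * spacing))
        warnings.warn("hausdorff95: one mask is empty; returning sentinel "
                      f"{empty_sentinel:.2f}", stacklevel=2)
        return float(empty_sentinel)
    s_t, s_p = _surface(truth), _surface(pred)
    # distance_transform_edt on the complement gives, at every voxel, the
    # distance to the nearest surface voxel of the other mask
    d_to_p = ndimage.distance_transform_edt(~s_p, sampling=spacing)
    d_to_t = ndimage.distance_transform_edt(~s_t, sampling=spacing)
    d_tp = d_to_p[s_t]
    d_pt = d_to_t[s_p]
    return float(max(np.percentile(d_tp, percentile),
                     np.percentile(d_pt, percentile)))


def evaluate_case(pred_labels: np.ndarray, truth_labels: np.ndarray,
                  spacing=(1.0, 1.0, 1.0), case_id: str = "case") -> MetricReport:
    """All four metrics for each of WT, TC, ET on one label-volume pair."""
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError(
            f"prediction shape {pred_labels.shape} != truth shape "
            f"{truth_labels.shape}")
    pred_regions = region_masks(pred_labels)
    truth_regions = region_masks(truth_labels)
    report = MetricReport(case_id=case_id)
    for region in REGIONS:
        c = confusion_counts(pred_regions[region], truth_regions[region])
        dsc, sens, ppv = overlap_metrics(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hd = hausdorff95(truth_regions[region], pred_regions[region],
                             spacing=spacing)
        report.scores[region] = {
            "dsc": dsc, "sensitivity": sens, "ppv": ppv, "hd95": hd,
        }
    return report


def average_reports(reports: list[MetricReport]) -> MetricReport:
    """Mean of each metric over cases, region by region."""
    if not reports:
        raise ValueError("no reports to average")
    avg = MetricReport(case_id="mean")
    for region in REGIONS:
        avg.scores[region] = {
            key: float(np.mean([r.scores[region][key] for r in reports]))
            for key in reports[0].scores[region]
        }
    return avg


def write_reports(reports: list[MetricReport], csv_path=None, json_path=None):
    """Persist reports as CSV (one row per case x region) and/or JSON."""
    rows = [row for r in reports for row in r.as_rows()]
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    if json_path is not None:
        payload = {r.case_id: r.scores for r in reports}
        Path(json_path).write_text(json.dumps(payload, indent=2))
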