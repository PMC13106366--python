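"""Scoring of instance labelings and point-density diagnostics.

Instance-level scoring follows the field-phenotyping convention: predicted
and ground-truth plants are matched one-to-one greedily by point-set IoU; a
ground-truth plant whose match reaches the IoU threshold is a true positive,
unmatched predictions are false positives and unmatched ground-truth plants
are false negatives.  Recall, precision and F are reported as percentages to
two decimals (half-up, matching how field benchmarks print them); mIoU is the
mean IoU over matched pairs.

Density diagnostics report points per convex-hull surface area (pts/mm^2) and
per convex-hull volume (pts/mm^3), a uniformity measure for reconstructed
clouds.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core_io import PointCloud
from .segment import InstanceLabeling

__all__ = [
    "ConfusionCounts", "SegMetrics", "DensityMetrics",
    "match_instances", "prf", "aggregate_micro", "miou",
    "density_metrics", "score_labeling",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


@dataclasses.dataclass
class SegMetrics:
    r: float
    p: float
    f: float
    per_instance_iou: dict
    miou: float


@dataclasses.dataclass
class DensityMetrics:
    d_sur: float   # points / mm^2
    d_vol: float   # points / mm^3
    a_cs: float    # mm^2
    v_cv: float    # mm^3
    n: int


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _instance_sets(labeling: InstanceLabeling) -> dict[int, set]:
    labels = labeling.labels
    return {int(k): set(np.nonzero(labels == k)[0].tolist())
            for k in np.unique(labels) if k != 0}


def match_instances(pred: InstanceLabeling, gt: InstanceLabeling,
                    iou_min: float = 0.5
                    ) -> tuple[ConfusionCounts, list[tuple[int, int, float]]]:
    """Greedy one-to-one matching by descending point-set IoU.

    Returns the confusion counts and the matched (gt_label, pred_label, IoU)
    triples with IoU >= ``iou_min``.
    """
    if len(pred.labels) != len(gt.labels):
        raise ValueError("labelings must cover the same cloud")
    pred_sets = _instance_sets(pred)
    gt_sets = _instance_sets(gt)
    cands = []
    for gk, gset in gt_sets.items():
        for pk, pset in pred_sets.items():
            inter = len(gset & pset)
            if inter:
                iou = inter / len(gset | pset)
                cands.append((iou, gk, pk))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g, used_p, matches = set(), set(), []
    for iou, gk, pk in cands:
        if gk in used_g or pk in used_p or iou < iou_min:
            continue
        used_g.add(gk)
        used_p.add(pk)
        matches.append((gk, pk, iou))
    tp = len(matches)
    return ConfusionCounts(tp=tp, fp=len(pred_sets) - tp, fn=len(gt_sets) - tp), matches


def prf(c: ConfusionCounts) -> tuple[float, float, float]:
    """(recall, precision, F) as percentages rounded half-up to 2 decimals:
    r = 100 tp/(tp+fn), p = 100 tp/(tp+fp), F = 2pr/(p+r)."""
    if c.tp + c.fn == 0 or c.tp + c.fp == 0:
        raise ValueError("undefined metrics: empty ground truth or predictions")
    r = 100.0 * c.tp / (c.tp + c.fn)
    p = 100.0 * c.tp / (c.tp + c.fp)
    f = 0.0 if p + r == 0 else 2.0 * p * r / (p + r)
    return _round2(r), _round2(p), _round2(f)


def aggregate_micro(counts) -> tuple[float, float, float]:
    """prf on summed counts (micro aggregation across plots)."""
    counts = list(counts)
    if not counts:
        raise ValueError("no counts to aggregate")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return prf(total)


def miou(pred: InstanceLabeling, gt: InstanceLabeling, matches) -> float:
    """Mean IoU over matched (gt, pred) pairs; 0.0 when nothing matched."""
    if not matches:
        return 0.0
    return float(np.mean([m[2] for m in matches]))


def score_labeling(pred: InstanceLabeling, gt: InstanceLabeling,
                   iou_min: float = 0.5) -> SegMetrics:
    counts, matches = match_instances(pred, gt, iou_min=iou_min)
    r, p, f = prf(counts)
    return SegMetrics(r=r, p=p, f=f,
                      per_instance_iou={gk: iou for gk, _, iou in matches},
                      miou=miou(pred, gt, matches))


def density_metrics(cloud: PointCloud) -> DensityMetrics:
    """Convex-hull surface/volume density of a cloud, in mm units."""
    pts_mm = np.asarray(cloud.points if isinstance(cloud, PointCloud) else cloud,
                        dtype=np.float64) * 1000.0
    if len(pts_mm) < 4:
        raise ValueError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(pts_mm)
    except QhullError as exc:
        raise ValueError(f"degenerate convex hull: {exc}") from exc
    n = len(pts_mm)
    return DensityMetrics(d_sur=n / hull.area, d_vol=n / hull.volume,
                          a_cs=float(hull.area), v_cv=float(hull.volume), n=n)
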