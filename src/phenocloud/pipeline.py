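"""End-to-end orchestration and the parameter-sensitivity protocol.

``run_field_pipeline`` chains the stages on an already-aligned field cloud
(ground at z ~ 0): hue-aware cloth ground split, stem-layer localization,
dynamically constrained growth, overlap resolution — returning labels on the
*full* input cloud so they can be scored directly against ground truth.

``parameter_sweep`` mirrors the robustness protocol used to validate the
segmentation: each core parameter (eps, MinPts, d, alpha, delta, tau_N) is
varied one-at-a-time by a given fraction around its default, clipped to its
documented admissible range, and the resulting mIoU change against ground
truth is recorded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_io import PointCloud
from .evaluate import match_instances, miou
from .localize import HeightLayer, locate_plants
from .preprocess import hcsf_ground_mask
from .segment import GrowthParams, InstanceLabeling, estimate_normals_curvature, \
    segment_population

__all__ = ["PipelineResult", "run_field_pipeline", "miou_vs_truth",
           "parameter_sweep", "PARAM_RANGES"]

#: Documented admissible ranges of the core segmentation parameters
#: (the calibration search ranges); the sensitivity sweep clips to these.
PARAM_RANGES = {
    "eps": (0.008, 0.020),
    "min_pts": (3, 10),
    "d_cyl": (0.02, 0.04),
    "alpha": (20.0, 50.0),
    "delta": (0.010, 0.030),
    "tau_n": (0.70, 0.95),
}

DEFAULTS = {"eps": 0.012, "min_pts": 6, "d_cyl": 0.03, "alpha": 35.0,
            "delta": 0.015, "tau_n": 0.85}


@dataclasses.dataclass
class PipelineResult:
    labels: np.ndarray            # per-point instance labels on the full cloud
    gp_indices: np.ndarray
    gs_indices: np.ndarray
    registry: pd.DataFrame
    gp: PointCloud                # plant cloud with normals/curvature attached
    gs: PointCloud
    labeling_gp: InstanceLabeling

    def labeling(self) -> InstanceLabeling:
        return InstanceLabeling(labels=self.labels, contested={})


def run_field_pipeline(cloud: PointCloud, layer: HeightLayer = HeightLayer(),
                       eps: float | None = 0.012, min_pts: int = 6,
                       params: GrowthParams = GrowthParams(),
                       variety: str = "", plot: str = "") -> PipelineResult:
    """Ground split + localization + constrained growth on an aligned cloud."""
    is_ground = hcsf_ground_mask(cloud)
    gp_idx = np.nonzero(~is_ground)[0]
    gs_idx = np.nonzero(is_ground)[0]
    gp = estimate_normals_curvature(cloud.select(gp_idx), k=params.k_normals)
    gs = cloud.select(gs_idx)
    locators, registry = locate_plants(gp, layer=layer, eps=eps,
                                       min_pts=min_pts, variety=variety,
                                       plot=plot)
    labeling_gp = segment_population(gp, locators, params)
    labels = np.zeros(len(cloud), dtype=np.int64)
    labels[gp_idx] = labeling_gp.labels
    return PipelineResult(labels=labels, gp_indices=gp_idx, gs_indices=gs_idx,
                          registry=registry, gp=gp, gs=gs,
                          labeling_gp=labeling_gp)


def miou_vs_truth(labels: np.ndarray, gt_labels: np.ndarray,
                  iou_min: float = 0.5) -> float:
    pred = InstanceLabeling(labels=labels, contested={})
    gt = InstanceLabeling(labels=np.asarray(gt_labels, dtype=np.int64), contested={})
    counts, matches = match_instances(pred, gt, iou_min=iou_min)
    return miou(pred, gt, matches)


def _clip(name: str, value):
    lo, hi = PARAM_RANGES[name]
    return min(max(value, lo), hi)


def parameter_sweep(cloud: PointCloud, gt_labels: np.ndarray,
                    frac: float = 0.2,
                    layer: HeightLayer = HeightLayer()) -> pd.DataFrame:
    """One-at-a-time sensitivity of mIoU to the six core parameters.

    Each parameter is multiplied by (1 - frac) and (1 + frac), clipped to its
    documented range (MinPts is rounded to an integer), and the full
    localization + segmentation is rerun.  Returns a table of runs with mIoU
    and the change in percentage points relative to the default run.
    """
    def run(overrides: dict) -> float:
        cfg = {**DEFAULTS, **overrides}
        gp_kwargs = {k: cfg[k] for k in ("delta", "tau_n", "d_cyl", "alpha")}
        res = run_field_pipeline(cloud, layer=layer, eps=cfg["eps"],
                                 min_pts=int(round(cfg["min_pts"])),
                                 params=GrowthParams(**gp_kwargs))
        return miou_vs_truth(res.labels, gt_labels)

    rows = [{"param": "default", "factor": 1.0, "value": np.nan,
             "miou": run({})}]
    base = rows[0]["miou"]
    for name in PARAM_RANGES:
        for factor in (1.0 - frac, 1.0 + frac):
            value = _clip(name, DEFAULTS[name] * factor)
            if name == "min_pts":
                value = int(round(value))
            m = run({name: value})
            rows.append({"param": name, "factor": factor, "value": value,
                         "miou": m})
    df = pd.DataFrame(rows)
    df["delta_pp"] = (df["miou"] - base) * 100.0
    return df
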