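"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain O(n^2) scans and
re-derivations from first principles, kept simple enough to audit by eye.
"""

from __future__ import annotations

import numpy as np


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """O(n^2) density-reachability clustering; border ties to lowest id.

    Mirrors the textbook definition: core points have >= min_pts neighbors
    within eps (self included); clusters are the connected components of core
    points under the eps relation, plus border points attached to the first
    (lowest-id) cluster that reaches them.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    nbr = d <= eps
    is_core = nbr.sum(axis=1) >= min_pts
    labels = np.zeros(n, dtype=np.int64)
    next_id = 1
    for start in range(n):
        if labels[start] != 0 or not is_core[start]:
            continue
        labels[start] = next_id
        changed = True
        while changed:
            changed = False
            members = labels == next_id
            reach = nbr[members & is_core].any(axis=0) & (labels == 0)
            if reach.any():
                labels[reach] = next_id
                changed = True
        next_id += 1
    return labels


def brute_sor_mask(points: np.ndarray, k: int, std_mult: float):
    """O(n^2) statistical-outlier-removal keep mask."""
    pts = np.asarray(points, dtype=np.float64)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    d_sorted = np.sort(d, axis=1)
    mean_d = d_sorted[:, 1:k + 1].mean(axis=1)
    return mean_d <= mean_d.mean() + std_mult * mean_d.std()


def reference_grow(points, normals, curvatures, seeds, regions, params):
    """Unoptimized region growing that re-scans every point each round.

    Same rules as the production grower (distance, normal coherence with the
    curvature gate, region membership, synchronized rounds, contested
    freezing) but with no spatial index and no frontier bookkeeping.
    """
    n = len(points)
    labels = np.zeros(n, dtype=np.int64)
    contested: dict[int, set] = {}
    plant_ids = sorted(seeds)
    for k in plant_ids:
        labels[np.asarray(seeds[k])] = k

    def link_ok(p, q):
        if np.linalg.norm(points[p] - points[q]) >= params.delta:
            return False
        if params.curv_gate is not None and (
                curvatures[p] > params.curv_gate or curvatures[q] > params.curv_gate):
            return True
        return abs(normals[p] @ normals[q]) >= params.tau_n

    while True:
        claims: dict[int, list] = {}
        for k in plant_ids:
            mine = np.nonzero(labels == k)[0]
            for q in range(n):
                if labels[q] != 0:
                    continue
                if not regions[k].contains(points[q][None])[0]:
                    continue
                if any(link_ok(p, q) for p in mine):
                    if q in contested:
                        contested[q].add(k)
                    else:
                        claims.setdefault(q, [])
                        if k not in claims[q]:
                            claims[q].append(k)
        if not claims:
            break
        for q, ks in claims.items():
            if len(ks) == 1:
                labels[q] = ks[0]
            else:
                contested[q] = set(ks)
    return labels, {q: tuple(sorted(ks)) for q, ks in contested.items()}


def pairwise_iou(a_idx: set, b_idx: set) -> float:
    """Set IoU by explicit set arithmetic."""
    return len(a_idx & b_idx) / len(a_idx | b_idx)
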