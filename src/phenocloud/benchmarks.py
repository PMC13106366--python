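"""Published field-benchmark confusion counts for cotton-plot instance
segmentation.

The reference study this pipeline targets reports plant-level confusion counts
for three cotton cultivars, each grown in three replicate plots of a 2 m x 2 m
breeding field (plot-level table) and aggregated per cultivar against three
classical clustering baselines (method-comparison table).  The counts are
inputs for metric arithmetic — recall/precision/F are always recomputed from
them with :func:`phenocloud.evaluate.prf`, never stored.
"""

from __future__ import annotations

from .evaluate import ConfusionCounts

__all__ = ["PLOT_COUNTS", "METHOD_COUNTS", "plot_confusions", "method_confusions"]

#: (variety, replicate) -> (manually counted, divided, fp, fn, tp)
PLOT_COUNTS: dict[tuple[str, str], tuple[int, int, int, int, int]] = {
    ("VARc94", "a"): (43, 43, 3, 5, 40),
    ("VARc94", "b"): (45, 45, 4, 3, 41),
    ("VARc94", "c"): (45, 45, 5, 5, 40),
    ("VARf6", "a"): (44, 44, 3, 4, 41),
    ("VARf6", "b"): (43, 43, 3, 4, 40),
    ("VARf6", "c"): (45, 45, 4, 3, 41),
    ("VARx36", "a"): (48, 48, 5, 3, 43),
    ("VARx36", "b"): (46, 46, 4, 3, 42),
    ("VARx36", "c"): (44, 44, 4, 5, 40),
}

#: method -> variety -> (manually counted, divided, fp, fn, tp)
METHOD_COUNTS: dict[str, dict[str, tuple[int, int, int, int, int]]] = {
    "DBSCAN": {
        "VARc94": (133, 79, 41, 36, 38),
        "VARf6": (132, 81, 37, 29, 44),
        "VARx36": (138, 75, 43, 35, 32),
    },
    "Euclidean": {
        "VARc94": (133, 87, 39, 42, 48),
        "VARf6": (132, 95, 43, 39, 52),
        "VARx36": (138, 93, 40, 43, 53),
    },
    "HDBSCAN": {
        "VARc94": (133, 112, 21, 20, 91),
        "VARf6": (132, 115, 18, 17, 98),
        "VARx36": (138, 118, 22, 19, 99),
    },
    "Ours": {
        "VARc94": (133, 133, 12, 13, 121),
        "VARf6": (132, 132, 10, 11, 122),
        "VARx36": (138, 138, 13, 11, 125),
    },
}


def plot_confusions() -> dict[tuple[str, str], ConfusionCounts]:
    """Plot-level confusion counts as ConfusionCounts, keyed (variety, rep)."""
    return {key: ConfusionCounts(tp=tp, fp=fp, fn=fn)
            for key, (_, _, fp, fn, tp) in PLOT_COUNTS.items()}


def method_confusions(method: str = "Ours") -> dict[str, ConfusionCounts]:
    """Cultivar-level confusion counts for one method from the comparison table."""
    return {var: ConfusionCounts(tp=tp, fp=fp, fn=fn)
            for var, (_, _, fp, fn, tp) in METHOD_COUNTS[method].items()}
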