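"""Benchmarking detections and aggregated cells against ground truth.

2D detection quality is measured in the object-detection idiom: greedy
one-to-one IOU matching per layer and class, precision-recall curves over a
descending confidence sweep, and average precision as the area under the
right-running-max interpolated PR curve.  3D cell recovery is measured by
centroid matching within the truth radius and by per-region count
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate3d import Cell3D
from .detections_io import DetectionBox

__all__ = [
    "MatchResult",
    "PRCurve",
    "box_iou",
    "match_boxes",
    "precision_recall",
    "match_cells_3d",
    "count_comparison",
]


@dataclass
class MatchResult:
    """One-to-one matches between predicted and truth boxes at an IOU threshold."""

    pairs: list[tuple[int, int, float]]
    unmatched_predicted: list[int]
    unmatched_truth: list[int]
    iou_threshold: float


def box_iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two axis-aligned boxes (same plane assumed)."""
    ax0, ax1 = a.x_c - a.width / 2, a.x_c + a.width / 2
    ay0, ay1 = a.y_c - a.height / 2, a.y_c + a.height / 2
    bx0, bx1 = b.x_c - b.width / 2, b.x_c + b.width / 2
    by0, by1 = b.y_c - b.height / 2, b.y_c + b.height / 2
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    return inter / union


def _greedy_match(
    predicted: Sequence[DetectionBox],
    truth: Sequence[DetectionBox],
    iou_threshold: float,
) -> list[tuple[int, int, float]]:
    """Greedy matching in descending confidence order (ties by input position).

    Each prediction claims the highest-IOU still-unmatched truth box of the
    same class on the same layer, provided IOU ≥ threshold.
    """
    truth_by_key: dict[tuple[int, str], list[int]] = {}
    for j, t in enumerate(truth):
        truth_by_key.setdefault((t.z_index, t.cell_class), []).append(j)
    order = sorted(range(len(predicted)), key=lambda i: (-predicted[i].confidence, i))
    taken = np.zeros(len(truth), dtype=bool)
    pairs = []
    for i in order:
        p = predicted[i]
        best_j, best_iou = -1, 0.0
        for j in truth_by_key.get((p.z_index, p.cell_class), []):
            if taken[j]:
                continue
            iou = box_iou(p, truth[j])
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            pairs.append((i, best_j, best_iou))
    return pairs


def match_boxes(
    predicted: Sequence[DetectionBox],
    truth: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """One-to-one greedy IOU matching of predictions to truth boxes."""
    pairs = _greedy_match(predicted, truth, iou_threshold)
    matched_p = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_predicted=[i for i in range(len(predicted)) if i not in matched_p],
        unmatched_truth=[j for j in range(len(truth)) if j not in matched_t],
        iou_threshold=iou_threshold,
    )


@dataclass
class PRCurve:
    """Precision-recall sweep over descending confidence thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float


def precision_recall(
    predicted: Sequence[DetectionBox],
    truth: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """PR curve and average precision for a set of scored predictions.

    Thresholds are the distinct confidences, descending; at each, precision
    = TP/(TP+FP) and recall = TP/|truth| cumulatively.  AP integrates the
    curve with precision interpolated as the running maximum to the right
    of each recall level.  Duplicate confidences are handled stably by
    input position, so AP does not depend on their input order.

    Raises
    ------
    ValueError
        If the truth set is empty (recall undefined).
    """
    if len(truth) == 0:
        raise ValueError("recall is undefined for an empty truth set")
    pairs = _greedy_match(predicted, truth, iou_threshold)
    matched_p = {i for i, _, _ in pairs}
    order = sorted(range(len(predicted)), key=lambda i: (-predicted[i].confidence, i))
    conf_sorted = np.array([predicted[i].confidence for i in order], dtype=float)
    is_tp = np.array([i in matched_p for i in order], dtype=bool)

    if len(order) == 0:
        return PRCurve(
            thresholds=np.zeros(0),
            precision=np.zeros(0),
            recall=np.zeros(0),
            average_precision=0.0,
        )

    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    prec_all = tp_cum / (tp_cum + fp_cum)
    rec_all = tp_cum / len(truth)

    # Collapse to the last entry of each distinct confidence value.
    last_of_value = np.flatnonzero(np.diff(conf_sorted, append=-np.inf) != 0)
    thresholds = conf_sorted[last_of_value]
    precision = prec_all[last_of_value]
    recall = rec_all[last_of_value]

    # Right-running-max interpolation at the distinct thresholds, then a step
    # integral over recall — evaluating only at block ends keeps AP stable
    # when predictions share a confidence value.
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - r_prev) * p_interp))
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        average_precision=ap,
    )


def match_cells_3d(
    predicted: Sequence[Cell3D],
    truth: pd.DataFrame,
) -> MatchResult:
    """Match predicted 3D cells to truth cells by centroid distance.

    A prediction matches the nearest still-unmatched truth cell of its
    class whose centre lies within the truth cell's radius; matching is
    greedy over predictions in input order.  The stored "IOU" slot holds
    the centroid distance instead.
    """
    tpos = truth[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    tcls = truth["cell_class"].to_numpy(dtype=str)
    trad = truth["diameter_um"].to_numpy(dtype=float) / 2.0
    taken = np.zeros(len(truth), dtype=bool)
    pairs = []
    for i, cell in enumerate(predicted):
        sel = np.flatnonzero((tcls == cell.cell_class) & ~taken)
        if sel.size == 0:
            continue
        d = np.linalg.norm(tpos[sel] - (cell.x, cell.y, cell.z), axis=1)
        k = int(np.argmin(d))
        if d[k] <= trad[sel[k]]:
            taken[sel[k]] = True
            pairs.append((i, int(sel[k]), float(d[k])))
    matched_p = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_predicted=[i for i in range(len(predicted)) if i not in matched_p],
        unmatched_truth=[j for j in range(len(truth)) if j not in matched_t],
        iou_threshold=float("nan"),
    )


def count_comparison(
    predicted_cells: Sequence[Cell3D] | pd.DataFrame,
    truth_cells: pd.DataFrame,
    regions: Sequence[tuple[float, float, float, float, float, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-region, per-class comparison of predicted vs true cell counts.

    ``regions`` holds axis-aligned boxes (x0, y0, z0, x1, y1, z1) with
    half-open bounds [lo, hi).  Overlapping regions trigger a warning but
    are still reported individually.
    """
    if isinstance(regions, pd.DataFrame):
        region_list = [
            (r.x0, r.y0, r.z0, r.x1, r.y1, r.z1) for r in regions.itertuples(index=False)
        ]
    else:
        region_list = [tuple(map(float, r)) for r in regions]
    for a in range(len(region_list)):
        for b in range(a + 1, len(region_list)):
            ra, rb = region_list[a], region_list[b]
            if all(ra[k] < rb[k + 3] and rb[k] < ra[k + 3] for k in range(3)):
                warnings.warn(f"regions {a} and {b} overlap; counts reported per region anyway",
                              stacklevel=2)
                break

    if isinstance(predicted_cells, pd.DataFrame):
        ppos = predicted_cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        pcls = predicted_cells["cell_class"].to_numpy(dtype=str)
    else:
        ppos = np.array([[c.x, c.y, c.z] for c in predicted_cells], dtype=float).reshape(-1, 3)
        pcls = np.array([c.cell_class for c in predicted_cells], dtype=str)
    tpos = truth_cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    tcls = truth_cells["cell_class"].to_numpy(dtype=str)

    classes = sorted(set(pcls) | set(tcls))
    rows = []
    for ridx, (x0, y0, z0, x1, y1, z1) in enumerate(region_list):
        lo = np.array([x0, y0, z0])
        hi = np.array([x1, y1, z1])
        pin = ((ppos >= lo) & (ppos < hi)).all(axis=1) if len(ppos) else np.zeros(0, dtype=bool)
        tin = ((tpos >= lo) & (tpos < hi)).all(axis=1) if len(tpos) else np.zeros(0, dtype=bool)
        for c in classes:
            rows.append(
                {
                    "region": ridx,
                    "cell_class": c,
                    "n_predicted": int((pin & (pcls == c)).sum()) if len(ppos) else 0,
                    "n_true": int((tin & (tcls == c)).sum()) if len(tpos) else 0,
                }
            )
    return pd.DataFrame(rows, columns=["region", "cell_class", "n_predicted", "n_true"])
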