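"""Greedy aggregation of per-layer 2D boxes into 3D cells.

A cell imaged as a z-stack leaves a run of concentric 2D boxes on
consecutive layers.  Aggregation links them back together: boxes of each
class are ordered largest/brightest first; the first unassigned box seeds a
cell at its centre ``q`` with maximum diameter ``d = max(width, height)``,
and absorbs every still-unassigned same-class box whose centre lies at
distance < d/2 from ``q``.  The absorbed set becomes one 3D cell and is
removed; the scan repeats until every box is allocated.  The same distance
rule also absorbs duplicate detections from mosaic-tile overlap regions.

Intensity enters only through the processing order and is never
thresholded, so cells of different brightness are treated alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detections_io import Calibration, DetectionBox

__all__ = [
    "AggregationParams",
    "Cell3D",
    "AggregationResult",
    "aggregate_boxes",
    "cells_to_frame",
    "frame_to_cells",
    "write_cells_table",
    "read_cells_table",
]

CELL_COLUMNS = ["cell_class", "x_um", "y_um", "z_um", "max_diameter_um", "n_boxes"]

_DISTANCE_MODES = ("euclidean3d", "xy_plus_z_window")


@dataclass(frozen=True)
class AggregationParams:
    """Tunables of the box-linking rule.

    distance_mode
        ``"euclidean3d"`` (default): absorb boxes with 3D Euclidean distance
        from the seed centre < d/2, z in μm.  ``"xy_plus_z_window"``: absorb
        boxes with xy-distance < d/2 *and* |Δz| < d/2.
    min_boxes_per_cell
        Cells built from fewer boxes are discarded (reported separately);
        the default 1 keeps single-layer detections as cells.
    """

    distance_mode: str = "euclidean3d"
    min_boxes_per_cell: int = 1

    def __post_init__(self) -> None:
        if self.distance_mode not in _DISTANCE_MODES:
            raise ValueError(
                f"distance_mode must be one of {_DISTANCE_MODES}, got {self.distance_mode!r}"
            )
        if self.min_boxes_per_cell < 1:
            raise ValueError("min_boxes_per_cell must be >= 1")


@dataclass(frozen=True)
class Cell3D:
    """One aggregated cell: a point location with a maximum diameter.

    ``member_ids`` are positions of the absorbed boxes in the input
    sequence; ``z`` always lies within the z-range of the member layers.
    """

    cell_class: str
    x: float
    y: float
    z: float
    max_diameter: float
    n_boxes: int
    member_ids: tuple[int, ...] = field(repr=False)


@dataclass
class AggregationResult:
    """Cells kept, plus cells discarded by the ``min_boxes_per_cell`` filter."""

    cells: list[Cell3D]
    discarded: list[Cell3D]


def aggregate_boxes(
    boxes: Sequence[DetectionBox],
    calibration: Calibration,
    params: AggregationParams | None = None,
) -> AggregationResult:
    """Partition 2D boxes into 3D cells, class by class.

    Every input box is assigned to exactly one cell of its own class.  The
    processing order is lexicographic over unassigned boxes: maximum box
    diameter descending, then mean intensity descending (falling back to the
    confidence score for boxes without an intensity, with a single warning),
    then confidence descending, then input position ascending — a
    deterministic order, so permuting the input leaves the output multiset
    of cells unchanged.

    The cell centroid is the unweighted mean of member box centres (z from
    ``z_index * z_step``); its diameter is the members' largest extent.
    """
    if params is None:
        params = AggregationParams()
    if len(boxes) == 0:
        return AggregationResult(cells=[], discarded=[])

    n = len(boxes)
    cls = np.array([b.cell_class for b in boxes])
    x = np.array([b.x_c for b in boxes], dtype=float)
    y = np.array([b.y_c for b in boxes], dtype=float)
    z = np.array([b.z_index for b in boxes], dtype=float) * calibration.z_step
    diam = np.array([b.max_diameter for b in boxes], dtype=float)
    conf = np.array([b.confidence for b in boxes], dtype=float)
    mfi = np.array(
        [np.nan if b.mean_intensity is None else b.mean_intensity for b in boxes], dtype=float
    )
    have_mfi = np.isfinite(mfi)
    if have_mfi.any() and not have_mfi.all():
        warnings.warn(
            "mean_intensity is absent on some boxes; using the confidence score "
            "as the ordering key for those boxes",
            stacklevel=2,
        )
    brightness = np.where(have_mfi, mfi, conf)

    cells: list[Cell3D] = []
    discarded: list[Cell3D] = []
    for class_name in sorted(set(cls)):
        idx = np.flatnonzero(cls == class_name)
        # Static lexicographic order: diameter desc, brightness desc,
        # confidence desc, input position asc (deterministic final tiebreak).
        order = idx[np.lexsort((idx, -conf[idx], -brightness[idx], -diam[idx]))]
        assigned = np.zeros(n, dtype=bool)
        for seed in order:
            if assigned[seed]:
                continue
            free = order[~assigned[order]]
            d = diam[seed]
            dx = x[free] - x[seed]
            dy = y[free] - y[seed]
            dz = z[free] - z[seed]
            if params.distance_mode == "euclidean3d":
                absorb = np.sqrt(dx * dx + dy * dy + dz * dz) < d / 2.0
            else:
                absorb = (np.sqrt(dx * dx + dy * dy) < d / 2.0) & (np.abs(dz) < d / 2.0)
            members = free[absorb]  # seed is at distance 0, always included
            assigned[members] = True
            members_sorted = np.sort(members)
            cell = Cell3D(
                cell_class=str(class_name),
                x=float(x[members_sorted].mean()),
                y=float(y[members_sorted].mean()),
                z=float(z[members_sorted].mean()),
                max_diameter=float(diam[members_sorted].max()),
                n_boxes=int(members.size),
                member_ids=tuple(int(i) for i in members_sorted),
            )
            if cell.n_boxes >= params.min_boxes_per_cell:
                cells.append(cell)
            else:
                discarded.append(cell)
    return AggregationResult(cells=cells, discarded=discarded)


def cells_to_frame(cells: Sequence[Cell3D]):
    """Tabulate cells with the columns of the cells CSV."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_class": [c.cell_class for c in cells],
            "x_um": [c.x for c in cells],
            "y_um": [c.y for c in cells],
            "z_um": [c.z for c in cells],
            "max_diameter_um": [c.max_diameter for c in cells],
            "n_boxes": [c.n_boxes for c in cells],
        },
        columns=CELL_COLUMNS,
    )


def frame_to_cells(frame) -> list[Cell3D]:
    """Rebuild :class:`Cell3D` records from a cells table (member ids are not stored)."""
    missing = [c for c in CELL_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ValueError(f"cells table is missing columns: {', '.join(missing)}")
    n_boxes = frame["n_boxes"] if "n_boxes" in frame.columns else [1] * len(frame)
    return [
        Cell3D(
            cell_class=str(c),
            x=float(x),
            y=float(y),
            z=float(z),
            max_diameter=float(d),
            n_boxes=int(nb),
            member_ids=(),
        )
        for c, x, y, z, d, nb in zip(
            frame["cell_class"], frame["x_um"], frame["y_um"], frame["z_um"],
            frame["max_diameter_um"], n_boxes,
        )
    ]


def write_cells_table(cells: Sequence[Cell3D], path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def read_cells_table(path) -> list[Cell3D]:
    import pandas as pd

    return frame_to_cells(pd.read_csv(path))
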