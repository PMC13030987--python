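"""Reading and writing per-slice 2D cell detections.

Detections arrive either as per-tile text files in the YOLO dialect (one box
per line, geometry normalized to the tile) together with a tile-placement
manifest, or as a single consolidated CSV table in global micrometre
coordinates.  All downstream stages consume :class:`DetectionBox` sequences
in global micrometres.

Conventions: coordinates are 0-based, a tile's origin pixel maps exactly to
its mosaic offset, x grows to the right, y downward, and z with the layer
index.  Overlapping mosaic tiles are *not* deduplicated at read time;
duplicate boxes from overlap regions are absorbed later by the distance rule
of the 3D aggregation step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "DetectionBox",
    "TABLE_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_tile_manifest",
    "read_tile_detections",
    "read_detection_table",
    "write_detection_table",
]

#: Column order of the consolidated detection table.
TABLE_COLUMNS = [
    "cell_class",
    "x_um",
    "y_um",
    "z_index",
    "width_um",
    "height_um",
    "confidence",
    "mean_intensity",
]

#: Column order of the tile-placement manifest.
MANIFEST_COLUMNS = [
    "tile_id",
    "x_offset_px",
    "y_offset_px",
    "z_index",
    "tile_width_px",
    "tile_height_px",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel and layer spacing of the acquisition.

    Parameters
    ----------
    pixel_size_x, pixel_size_y : float
        Lateral pixel size in μm/pixel.
    z_step : float
        Axial distance between consecutive image layers in μm.  Defaults to
        5 μm, a typical confocal z-stack spacing for whole-marrow imaging.
    """

    pixel_size_x: float
    pixel_size_y: float
    z_step: float = 5.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_x", "pixel_size_y", "z_step"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"Calibration.{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class DetectionBox:
    """One 2D bounding box on one z-layer, in global μm coordinates.

    ``x_c``/``y_c`` locate the box centre; ``width``/``height`` are the box
    extents; ``confidence`` is the detector's score in [0, 1];
    ``mean_intensity`` is an optional mean fluorescence intensity used only
    for ordering during aggregation.
    """

    cell_class: str
    x_c: float
    y_c: float
    z_index: int
    width: float
    height: float
    confidence: float
    mean_intensity: float | None = None
    source_tile: str | None = None

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"box width must be > 0, got {self.width!r}")
        if not self.height > 0:
            raise ValueError(f"box height must be > 0, got {self.height!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence!r}")
        if self.z_index < 0:
            raise ValueError(f"z_index must be >= 0, got {self.z_index!r}")

    @property
    def max_diameter(self) -> float:
        """Largest in-plane extent, max(width, height)."""
        return max(self.width, self.height)


def read_tile_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a tile-placement manifest CSV."""
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {', '.join(missing)}")
    if manifest["tile_id"].duplicated().any():
        dupes = manifest.loc[manifest["tile_id"].duplicated(), "tile_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate tile ids: {dupes}")
    if (manifest[["x_offset_px", "y_offset_px", "z_index"]] < 0).any().any():
        raise ValueError(f"manifest {path}: offsets and z_index must be >= 0")
    if (manifest[["tile_width_px", "tile_height_px"]] <= 0).any().any():
        raise ValueError(f"manifest {path}: tile dimensions must be > 0")
    return manifest


def read_tile_detections(
    detection_dir: str | Path,
    manifest: str | Path | pd.DataFrame,
    calibration: Calibration,
    class_map: Mapping[int, str],
) -> list[DetectionBox]:
    """Read per-tile YOLO-style detection files into global μm boxes.

    Each tile listed in the manifest must have a file
    ``<detection_dir>/<tile_id>.txt`` whose lines read
    ``class x_center y_center width height confidence`` with geometry
    normalized to [0, 1] of the tile size.  ``class_map`` maps the integer
    class ids in the files to class names.

    Raises
    ------
    FileNotFoundError
        If a tile referenced by the manifest has no detection file.
    ValueError
        For malformed lines (named by file and line number) or class ids
        absent from ``class_map``.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_tile_manifest(manifest)
    detection_dir = Path(detection_dir)
    boxes: list[DetectionBox] = []
    for row in manifest.itertuples(index=False):
        tile_path = detection_dir / f"{row.tile_id}.txt"
        if not tile_path.exists():
            raise FileNotFoundError(
                f"tile {row.tile_id!r} referenced by the manifest has no detection file {tile_path}"
            )
        with open(tile_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split()
                if len(fields) != 6:
                    raise ValueError(
                        f"{tile_path}:{lineno}: expected 6 fields "
                        f"'class x y w h conf', got {len(fields)}"
                    )
                try:
                    class_id = int(fields[0])
                    xn, yn, wn, hn, conf = (float(v) for v in fields[1:])
                except ValueError as exc:
                    raise ValueError(f"{tile_path}:{lineno}: unparseable value: {exc}") from None
                if class_id not in class_map:
                    raise ValueError(
                        f"{tile_path}:{lineno}: class id {class_id} not in class map "
                        f"{sorted(class_map)}"
                    )
                boxes.append(
                    DetectionBox(
                        cell_class=class_map[class_id],
                        x_c=(row.x_offset_px + xn * row.tile_width_px) * calibration.pixel_size_x,
                        y_c=(row.y_offset_px + yn * row.tile_height_px) * calibration.pixel_size_y,
                        z_index=int(row.z_index),
                        width=wn * row.tile_width_px * calibration.pixel_size_x,
                        height=hn * row.tile_height_px * calibration.pixel_size_y,
                        confidence=conf,
                        source_tile=str(row.tile_id),
                    )
                )
    return boxes


def read_detection_table(path: str | Path) -> list[DetectionBox]:
    """Read a consolidated detection table CSV.

    Round-trips bit-exactly with :func:`write_detection_table` for values
    written at full precision.  An empty ``mean_intensity`` field is read
    back as absent.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"detection table {path} is missing columns: {', '.join(missing)}")
    boxes: list[DetectionBox] = []
    for i, row in enumerate(table.itertuples(index=False)):
        mfi = row.mean_intensity
        try:
            boxes.append(
                DetectionBox(
                    cell_class=str(row.cell_class),
                    x_c=float(row.x_um),
                    y_c=float(row.y_um),
                    z_index=int(row.z_index),
                    width=float(row.width_um),
                    height=float(row.height_um),
                    confidence=float(row.confidence),
                    mean_intensity=None if pd.isna(mfi) else float(mfi),
                )
            )
        except ValueError as exc:
            raise ValueError(f"detection table {path}, row {i}: {exc}") from None
    return boxes


def write_detection_table(boxes: Sequence[DetectionBox], path: str | Path) -> None:
    """Write boxes as a consolidated CSV (header always present)."""
    table = pd.DataFrame(
        {
            "cell_class": [b.cell_class for b in boxes],
            "x_um": [b.x_c for b in boxes],
            "y_um": [b.y_c for b in boxes],
            "z_index": [b.z_index for b in boxes],
            "width_um": [b.width for b in boxes],
            "height_um": [b.height for b in boxes],
            "confidence": [b.confidence for b in boxes],
            "mean_intensity": [
                np.nan if b.mean_intensity is None else b.mean_intensity for b in boxes
            ],
        },
        columns=TABLE_COLUMNS,
    )
    # %.17g round-trips IEEE doubles exactly
    table.to_csv(path, index=False, float_format="%.17g")
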