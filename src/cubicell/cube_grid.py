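"""Cube discretization of the imaged volume and its face-adjacency graph.

The tissue volume is divided into non-overlapping cubes of side θ (default
45 μm), and the number of cells of each class falling in each cube is
recorded.  Cubes are the spatial units of every downstream statistic.  A
cube's reported coordinate (u, v, z) is the midpoint of its lowest-z face:
x and y at the face centre, z at the lower plane.

Two cubes are neighbors iff they share a face (centroid distance exactly θ),
so an interior cube has 6 neighbors — a 7-cube neighborhood including
itself — and boundary cubes have fewer.  An optional marrow mask restricts
both the cell counts and the graph to in-tissue cubes; cells, not cubes, are
the unit of exclusion, so cubes only partially covered by tissue are kept
if the mask says so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .aggregate3d import Cell3D

__all__ = [
    "GridSpec",
    "CubeGrid",
    "NeighborGraph",
    "build_grid",
    "neighbor_graph",
    "read_mask_csv",
    "read_mask_tiff",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the cube grid: side length θ (μm), origin (μm), cube counts."""

    cube_size: float
    origin: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.cube_size > 0:
            raise ValueError(f"cube_size must be > 0, got {self.cube_size!r}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must all be >= 1, got {self.dims!r}")

    def cube_coordinate(self, ix: int, iy: int, iz: int) -> tuple[float, float, float]:
        """(u, v, z) of cube (ix, iy, iz): midpoint of its lowest-z face."""
        t = self.cube_size
        x0, y0, z0 = self.origin
        return (x0 + (ix + 0.5) * t, y0 + (iy + 0.5) * t, z0 + iz * t)

    def cube_center(self, ix: int, iy: int, iz: int) -> tuple[float, float, float]:
        """Geometric centre of cube (ix, iy, iz)."""
        t = self.cube_size
        x0, y0, z0 = self.origin
        return (x0 + (ix + 0.5) * t, y0 + (iy + 0.5) * t, z0 + (iz + 0.5) * t)


class CubeGrid:
    """θ-sided cube discretization with per-class counts and an optional mask.

    Attributes
    ----------
    spec : GridSpec
    classes : tuple of str
        Cell classes, in sorted order.
    counts : dict mapping class -> int array of shape ``spec.dims``
    mask : bool array of shape ``spec.dims``
        True for in-marrow cubes; all True when no mask was supplied.
    n_excluded : dict mapping class -> int
        Cells dropped because they fell in out-of-mask cubes.
    """

    def __init__(
        self,
        spec: GridSpec,
        counts: Mapping[str, np.ndarray],
        mask: np.ndarray | None = None,
        n_excluded: Mapping[str, int] | None = None,
    ) -> None:
        self.spec = spec
        self.classes = tuple(sorted(counts))
        self.counts = {c: np.asarray(counts[c], dtype=np.int64) for c in self.classes}
        for c, arr in self.counts.items():
            if arr.shape != spec.dims:
                raise ValueError(f"counts[{c!r}] shape {arr.shape} != grid dims {spec.dims}")
            if (arr < 0).any():
                raise ValueError(f"counts[{c!r}] contains negative entries")
        if mask is None:
            mask = np.ones(spec.dims, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spec.dims:
            raise ValueError(f"mask shape {mask.shape} != grid dims {spec.dims}")
        self.mask = mask
        self.n_excluded = dict(n_excluded or {})

    # -- canonical in-mask ordering -------------------------------------
    @property
    def node_flat_indices(self) -> np.ndarray:
        """Flat (C-order) indices of in-mask cubes — the canonical node order."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    @property
    def n_nodes(self) -> int:
        return int(self.mask.sum())

    def counts_in_mask(self, cell_class: str) -> np.ndarray:
        """Per-cube counts of one class over in-mask cubes, in node order."""
        if cell_class not in self.counts:
            raise KeyError(f"unknown cell class {cell_class!r}; have {self.classes}")
        return self.counts[cell_class].ravel(order="C")[self.node_flat_indices]

    # -- conversions ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Cube table: u_um,v_um,z_um,ix,iy,iz,in_mask plus one count column per class."""
        nx, ny, nz = self.spec.dims
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
        t = self.spec.cube_size
        x0, y0, z0 = self.spec.origin
        frame = pd.DataFrame(
            {
                "u_um": x0 + (ix + 0.5) * t,
                "v_um": y0 + (iy + 0.5) * t,
                "z_um": z0 + iz * t,
                "ix": ix,
                "iy": iy,
                "iz": iz,
                "in_mask": self.mask.ravel(),
            }
        )
        for c in self.classes:
            frame[f"count_{c}"] = self.counts[c].ravel()
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cube_size: float, origin=(0.0, 0.0, 0.0)) -> "CubeGrid":
        """Rebuild a grid from a cube table written by :meth:`to_frame`."""
        required = ["ix", "iy", "iz", "in_mask"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"cube table is missing columns: {', '.join(missing)}")
        if {"u_um", "v_um", "z_um"} <= set(frame.columns) and len(frame):
            # Recover origin from the first cube's (u, z) coordinate.
            row = frame.iloc[0]
            origin = (
                float(row.u_um - (row.ix + 0.5) * cube_size),
                float(row.v_um - (row.iy + 0.5) * cube_size),
                float(row.z_um - row.iz * cube_size),
            )
        dims = (int(frame["ix"].max()) + 1, int(frame["iy"].max()) + 1, int(frame["iz"].max()) + 1)
        spec = GridSpec(cube_size=cube_size, origin=tuple(origin), dims=dims)
        mask = np.zeros(dims, dtype=bool)
        mask[frame["ix"], frame["iy"], frame["iz"]] = frame["in_mask"].astype(bool)
        counts = {}
        for col in frame.columns:
            if col.startswith("count_"):
                arr = np.zeros(dims, dtype=np.int64)
                arr[frame["ix"], frame["iy"], frame["iz"]] = frame[col].astype(np.int64)
                counts[col[len("count_"):]] = arr
        return cls(spec, counts, mask=mask)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, np.ndarray] | np.ndarray,
        cube_size: float = 45.0,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        mask: np.ndarray | None = None,
        cell_class: str = "cells",
    ) -> "CubeGrid":
        """Build a grid directly from count arrays (handy for analyses and tests)."""
        if isinstance(counts, np.ndarray):
            counts = {cell_class: counts}
        dims = next(iter(counts.values())).shape
        spec = GridSpec(cube_size=cube_size, origin=origin, dims=tuple(int(d) for d in dims))
        return cls(spec, counts, mask=mask)


def build_grid(
    cells: Sequence[Cell3D] | pd.DataFrame,
    cube_size: float = 45.0,
    mask: np.ndarray | None = None,
    origin: tuple[float, float, float] | None = None,
    dims: tuple[int, int, int] | None = None,
    classes: Iterable[str] | None = None,
) -> CubeGrid:
    """Assign cells to θ-sided cubes and count them per class.

    A cell at position p goes to cube ``floor((p - origin) / θ)`` per axis —
    half-open intervals ``[origin + kθ, origin + (k+1)θ)``, so a cell at
    exactly a cube boundary belongs to the upper cube.  When ``origin`` is
    omitted it defaults to the componentwise minimum of the cell positions;
    an explicit origin must bound the data from below.  Cells landing in
    out-of-mask cubes are excluded and tallied in ``n_excluded``.
    """
    if isinstance(cells, pd.DataFrame):
        names = cells["cell_class"].to_numpy(dtype=str)
        pos = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        names = np.array([c.cell_class for c in cells])
        pos = np.array([[c.x, c.y, c.z] for c in cells], dtype=float)
        if len(cells) == 0:
            pos = pos.reshape(0, 3)
    if not np.isfinite(pos).all():
        raise ValueError("cell coordinates must be finite")

    if origin is None:
        if len(pos) == 0:
            origin = (0.0, 0.0, 0.0)
        else:
            origin = tuple(float(v) for v in pos.min(axis=0))
    origin_arr = np.asarray(origin, dtype=float)
    if len(pos) and (pos < origin_arr - 1e-9).any():
        bad = int(np.argmax((pos < origin_arr - 1e-9).any(axis=1)))
        raise ValueError(
            f"cell {bad} at {tuple(pos[bad])} lies below the grid origin {tuple(origin_arr)}; "
            "the origin must bound the data"
        )

    idx = np.floor((pos - origin_arr) / cube_size).astype(int) if len(pos) else pos.astype(int)
    if dims is None:
        if mask is not None:
            dims = tuple(int(d) for d in np.asarray(mask).shape)
        elif len(pos):
            dims = tuple(int(v) + 1 for v in idx.max(axis=0))
        else:
            dims = (1, 1, 1)
    if len(pos) and (idx >= np.asarray(dims)).any():
        bad = int(np.argmax((idx >= np.asarray(dims)).any(axis=1)))
        raise ValueError(
            f"cell {bad} at {tuple(pos[bad])} falls outside the {dims} grid extent"
        )

    all_classes = sorted(set(names) | set(classes or ()))
    spec = GridSpec(cube_size=float(cube_size), origin=tuple(float(v) for v in origin_arr), dims=dims)
    if mask is None:
        mask_arr = np.ones(dims, dtype=bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    counts: dict[str, np.ndarray] = {}
    n_excluded: dict[str, int] = {}
    for c in all_classes:
        sel = names == c
        cidx = idx[sel]
        if len(cidx):
            inside = mask_arr[cidx[:, 0], cidx[:, 1], cidx[:, 2]]
        else:
            inside = np.zeros(0, dtype=bool)
        n_excluded[c] = int((~inside).sum())
        kept = cidx[inside]
        arr = np.zeros(dims, dtype=np.int64)
        if len(kept):
            np.add.at(arr, (kept[:, 0], kept[:, 1], kept[:, 2]), 1)
        counts[c] = arr
    return CubeGrid(spec, counts, mask=mask_arr, n_excluded=n_excluded)


class NeighborGraph:
    """Face-adjacency graph over in-mask cubes with binary weights.

    Nodes are in-mask cubes in canonical (C-raveled) order; two distinct
    nodes are linked iff their cube indices differ by exactly 1 along exactly
    one axis — equivalently, centroid distance exactly θ.  Weights are
    symmetric 0/1; ``sum_weights`` counts ordered pairs (i, j), i ≠ j.
    """

    def __init__(self, grid: CubeGrid) -> None:
        mask = grid.mask
        dims = mask.shape
        flat = np.arange(mask.size).reshape(dims)
        node_of = -np.ones(mask.size, dtype=np.int64)
        nodes = np.flatnonzero(mask.ravel(order="C"))
        node_of[nodes] = np.arange(nodes.size)

        rows, cols = [], []
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            pair_ok = mask[tuple(lo)] & mask[tuple(hi)]
            a = flat[tuple(lo)][pair_ok]
            b = flat[tuple(hi)][pair_ok]
            rows.append(node_of[a])
            cols.append(node_of[b])
        r = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
        c = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
        n = nodes.size
        data = np.ones(r.size, dtype=np.int8)
        adj = sp.coo_matrix((data, (r, c)), shape=(n, n))
        adj = (adj + adj.T).tocsr()

        self.grid = grid
        self.nodes = nodes
        self.node_of = node_of
        self.adjacency = adj
        self.degrees = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.size)

    @property
    def sum_weights(self) -> int:
        """Σ_{i≠j} φ_ij over ordered pairs."""
        return int(self.degrees.sum())

    def neighbors(self, node: int) -> np.ndarray:
        """Node ids adjacent to ``node`` (excluding the node itself)."""
        a = self.adjacency
        return a.indices[a.indptr[node]:a.indptr[node + 1]]

    def neighborhood_size(self, node: int) -> int:
        """Number of cubes in the neighborhood including the centre cube."""
        return int(self.degrees[node]) + 1


def neighbor_graph(grid: CubeGrid) -> NeighborGraph:
    """Build the face-adjacency graph of a grid's in-mask cubes."""
    return NeighborGraph(grid)


def read_mask_csv(path, dims: tuple[int, int, int] | None = None) -> np.ndarray:
    """Read a per-cube boolean mask CSV with columns ix,iy,iz,in_mask."""
    frame = pd.read_csv(path)
    missing = [c for c in ("ix", "iy", "iz", "in_mask") if c not in frame.columns]
    if missing:
        raise ValueError(f"mask table {path} is missing columns: {', '.join(missing)}")
    if dims is None:
        dims = (int(frame["ix"].max()) + 1, int(frame["iy"].max()) + 1, int(frame["iz"].max()) + 1)
    mask = np.zeros(dims, dtype=bool)
    mask[frame["ix"], frame["iy"], frame["iz"]] = frame["in_mask"].astype(bool)
    return mask


def read_mask_tiff(
    path,
    cube_size: float,
    pixel_size: float,
    z_step: float,
    dims: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Downsample a TIFF label stack (z, y, x) to a per-cube mask by majority vote.

    A cube is in-mask when more than half of its covered voxels are nonzero.
    Partial cubes at the upper edges vote over the voxels they do cover.
    """
    import tifffile

    stack = np.asarray(tifffile.imread(path)) != 0
    if stack.ndim == 2:
        stack = stack[None, :, :]
    nzl, nyp, nxp = stack.shape
    bx = max(1, int(round(cube_size / pixel_size)))
    bz = max(1, int(round(cube_size / z_step)))
    if dims is None:
        dims = (
            int(np.ceil(nxp / bx)),
            int(np.ceil(nyp / bx)),
            int(np.ceil(nzl / bz)),
        )
    mask = np.zeros(dims, dtype=bool)
    for ix in range(dims[0]):
        for iy in range(dims[1]):
            for iz in range(dims[2]):
                block = stack[
                    iz * bz : (iz + 1) * bz,
                    iy * bx : (iy + 1) * bx,
                    ix * bx : (ix + 1) * bx,
                ]
                if block.size:
                    mask[ix, iy, iz] = block.mean() > 0.5
    return mask
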