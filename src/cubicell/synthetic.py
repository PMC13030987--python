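"""Synthetic 3D tissue: point-process cell placement and optical slicing.

Ground-truth cells are placed in a box volume by one of three point
processes per class — complete spatial randomness (homogeneous Poisson),
a Thomas cluster process (Poisson parents, Poisson-distributed offspring
displaced isotropically by a Gaussian), or hard-core-thinned CSR (CSR with
a minimum pairwise separation).  These regimes emulate, respectively, a
strongly clustered abundant population, a weakly clustered sparse one, and
a near-random rare one of large cells.

Cells are spheres.  Slicing emulates a z-stack at a fixed z-step: a cell
with centre z0 and diameter D leaves, on every image plane z with
|z − z0| < D/2, a square box of side 2·sqrt((D/2)² − (z − z0)²) (the chord
of the sphere at that plane).  A noise model then jitters box centres and
sizes, drops boxes (missed detections), and adds spurious boxes with low
confidence scores.  Everything is driven by a single seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detections_io import Calibration, DetectionBox

__all__ = [
    "ClassSpec",
    "NoiseModel",
    "CellTruth",
    "SliceResult",
    "simulate_cells",
    "slice_to_boxes",
    "default_class_specs",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["cell_class", "x_um", "y_um", "z_um", "diameter_um"]

_PROCESSES = ("csr", "thomas", "hardcore-csr")


@dataclass(frozen=True)
class ClassSpec:
    """Point-process parameters for one cell class.

    process
        ``"csr"``: homogeneous Poisson with ``intensity`` (cells/μm³).
        ``"thomas"``: Poisson parents at ``parent_intensity`` (μm⁻³), each
        with Poisson(``mean_offspring``) children displaced by an isotropic
        Gaussian of sd ``dispersion`` μm; children outside the volume are
        discarded.
        ``"hardcore-csr"``: CSR thinned so accepted cells keep pairwise
        centre separation ≥ ``min_separation`` μm.
    diameter_mean, diameter_sd
        Sphere diameter distribution (μm); draws are clipped to
        mean ± 2 sd (and to > 0.5 μm) so extreme diameters cannot occur.
    """

    name: str
    process: str = "csr"
    intensity: float = 0.0
    parent_intensity: float = 0.0
    mean_offspring: float = 0.0
    dispersion: float = 1.0
    diameter_mean: float = 12.0
    diameter_sd: float = 0.0
    min_separation: float = 0.0

    def __post_init__(self) -> None:
        if self.process not in _PROCESSES:
            raise ValueError(f"process must be one of {_PROCESSES}, got {self.process!r}")
        for key in ("intensity", "parent_intensity", "mean_offspring", "dispersion",
                    "diameter_mean", "diameter_sd", "min_separation"):
            if getattr(self, key) < 0:
                raise ValueError(f"ClassSpec.{key} must be non-negative")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise parameters applied when slicing truth into boxes.

    miss_rate
        Probability an emitted box is dropped (a missed detection).
    fp_rate
        Expected spurious boxes per layer per 100×100 μm² of field.
    center_jitter_sd, size_jitter_sd
        Gaussian jitter (μm) on box centres and sides.
    matched_confidence, spurious_confidence
        Beta(a, b) parameters of the confidence score for true and spurious
        boxes; the defaults put true boxes high (~0.9) and spurious low (~0.2).
    """

    miss_rate: float = 0.0
    fp_rate: float = 0.0
    center_jitter_sd: float = 0.0
    size_jitter_sd: float = 0.0
    matched_confidence: tuple[float, float] = (9.0, 1.0)
    spurious_confidence: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.fp_rate < 0 or self.center_jitter_sd < 0 or self.size_jitter_sd < 0:
            raise ValueError("noise rates and jitter sds must be non-negative")


@dataclass
class CellTruth:
    """Simulated ground truth: cell table, volume, generating parameters, seed."""

    cells: pd.DataFrame
    volume: tuple[float, float, float]
    class_specs: tuple[ClassSpec, ...]
    seed: int | None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts_by_class(self) -> pd.Series:
        return self.cells["cell_class"].value_counts()


@dataclass
class SliceResult:
    """Boxes produced by slicing, plus truth rows that left no box."""

    boxes: list[DetectionBox]
    unobservable: list[int]


def default_class_specs() -> tuple[ClassSpec, ClassSpec, ClassSpec]:
    """Three-class preset mirroring the regimes of an infiltrated marrow.

    In a 500³ μm³ volume these give on average ≈5,000 strongly clustered
    "AML" cells, ≈500 weakly clustered "CTL" cells, and ≈100 near-random,
    well-separated large "MK" cells.  Diameters are chosen so that a
    noiselessly sliced sphere always re-aggregates into a single cell at a
    5 μm z-step (see the methods note).
    """
    v = 500.0**3
    return (
        ClassSpec(
            name="AML",
            process="thomas",
            parent_intensity=40 / v,
            mean_offspring=125.0,
            dispersion=30.0,
            diameter_mean=12.0,
            diameter_sd=0.5,
        ),
        ClassSpec(
            name="CTL",
            process="thomas",
            parent_intensity=25 / v,
            mean_offspring=20.0,
            dispersion=40.0,
            diameter_mean=12.0,
            diameter_sd=0.5,
        ),
        ClassSpec(
            name="MK",
            process="hardcore-csr",
            intensity=100 / v,
            min_separation=30.0,
            diameter_mean=25.0,
            diameter_sd=1.5,
        ),
    )


def _draw_diameters(rng: np.random.Generator, spec: ClassSpec, n: int) -> np.ndarray:
    d = rng.normal(spec.diameter_mean, spec.diameter_sd, size=n)
    lo = max(0.5, spec.diameter_mean - 2 * spec.diameter_sd)
    hi = spec.diameter_mean + 2 * spec.diameter_sd
    return np.clip(d, lo, hi)


def simulate_cells(
    volume: tuple[float, float, float],
    class_specs: Sequence[ClassSpec],
    seed: int | None = None,
) -> CellTruth:
    """Place cells of each class in the volume by its point process.

    Raises
    ------
    RuntimeError
        If hard-core thinning cannot reach its target count within the
        rejection budget (100 attempts per requested cell); the message
        reports the achieved count.
    """
    lx, ly, lz = (float(v) for v in volume)
    if min(lx, ly, lz) <= 0:
        raise ValueError("volume dimensions must be positive")
    v = lx * ly * lz
    rng = np.random.default_rng(seed)
    frames = []
    for spec in class_specs:
        if spec.process == "csr":
            n = rng.poisson(spec.intensity * v)
            pos = rng.uniform(0, (lx, ly, lz), size=(n, 3))
        elif spec.process == "thomas":
            n_parents = rng.poisson(spec.parent_intensity * v)
            centers = rng.uniform(0, (lx, ly, lz), size=(n_parents, 3))
            offspring = rng.poisson(spec.mean_offspring, size=n_parents)
            parent_of = np.repeat(np.arange(n_parents), offspring)
            pos = centers[parent_of] + rng.normal(0, spec.dispersion, size=(parent_of.size, 3))
            inside = ((pos >= 0) & (pos < (lx, ly, lz))).all(axis=1)
            pos = pos[inside]
        else:  # hardcore-csr
            target = rng.poisson(spec.intensity * v)
            accepted: list[np.ndarray] = []
            budget = 100 * max(target, 1)
            tries = 0
            while len(accepted) < target and tries < budget:
                cand = rng.uniform(0, (lx, ly, lz), size=3)
                tries += 1
                if all(np.linalg.norm(cand - a) >= spec.min_separation for a in accepted):
                    accepted.append(cand)
            if len(accepted) < target:
                raise RuntimeError(
                    f"hard-core packing infeasible for class {spec.name!r}: achieved "
                    f"{len(accepted)} of {target} cells within the rejection budget"
                )
            pos = np.array(accepted) if accepted else np.zeros((0, 3))
        diam = _draw_diameters(rng, spec, len(pos))
        frames.append(
            pd.DataFrame(
                {
                    "cell_class": spec.name,
                    "x_um": pos[:, 0] if len(pos) else np.zeros(0),
                    "y_um": pos[:, 1] if len(pos) else np.zeros(0),
                    "z_um": pos[:, 2] if len(pos) else np.zeros(0),
                    "diameter_um": diam,
                },
                columns=TRUTH_COLUMNS,
            )
        )
    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRUTH_COLUMNS)
    return CellTruth(cells=cells, volume=(lx, ly, lz), class_specs=tuple(class_specs), seed=seed)


def slice_to_boxes(
    truth: CellTruth,
    calibration: Calibration,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> SliceResult:
    """Slice spherical cells into per-layer square boxes, then apply noise.

    Image planes sit at z = k · z_step for k = 0, 1, … within the volume.
    A plane intersects a cell when |z − z0| < D/2 (strict: a tangent plane
    leaves no box), giving a box of side equal to the sphere's chord there.
    Cells intersecting no plane (possible when D < z_step) are reported in
    ``unobservable``.  With zero noise the emitted boxes are a deterministic
    function of the geometry.
    """
    if noise is None:
        noise = NoiseModel()
    dz = calibration.z_step
    lx, ly, lz = truth.volume
    n_layers = int(np.floor(lz / dz)) + 1
    rng = np.random.default_rng(seed)

    boxes: list[DetectionBox] = []
    unobservable: list[int] = []
    for i, row in enumerate(truth.cells.itertuples(index=False)):
        r = row.diameter_um / 2.0
        k_lo = max(0, int(np.ceil((row.z_um - r) / dz)))
        k_hi = min(n_layers - 1, int(np.floor((row.z_um + r) / dz)))
        emitted = 0
        for k in range(k_lo, k_hi + 1):
            off = k * dz - row.z_um
            if abs(off) >= r:
                continue
            side = 2.0 * np.sqrt(r * r - off * off)
            if noise.miss_rate > 0 and rng.random() < noise.miss_rate:
                emitted += 1  # the cell was observable; the detector missed it
                continue
            cx = row.x_um + (rng.normal(0, noise.center_jitter_sd) if noise.center_jitter_sd else 0.0)
            cy = row.y_um + (rng.normal(0, noise.center_jitter_sd) if noise.center_jitter_sd else 0.0)
            w = side + (rng.normal(0, noise.size_jitter_sd) if noise.size_jitter_sd else 0.0)
            w = max(w, 0.5)
            conf = float(rng.beta(*noise.matched_confidence)) if noise.miss_rate or noise.fp_rate or noise.center_jitter_sd or noise.size_jitter_sd else 1.0
            boxes.append(
                DetectionBox(
                    cell_class=row.cell_class,
                    x_c=float(cx),
                    y_c=float(cy),
                    z_index=k,
                    width=float(w),
                    height=float(w),
                    confidence=conf,
                    mean_intensity=None,
                )
            )
            emitted += 1
        if emitted == 0:
            unobservable.append(i)

    if noise.fp_rate > 0:
        classes = [s.name for s in truth.class_specs]
        mean_per_layer = noise.fp_rate * (lx / 100.0) * (ly / 100.0)
        diam_of = {s.name: s.diameter_mean for s in truth.class_specs}
        for k in range(n_layers):
            for _ in range(rng.poisson(mean_per_layer)):
                cls = classes[rng.integers(len(classes))]
                side = max(0.5, 0.8 * diam_of[cls] * rng.uniform(0.5, 1.2))
                boxes.append(
                    DetectionBox(
                        cell_class=cls,
                        x_c=float(rng.uniform(0, lx)),
                        y_c=float(rng.uniform(0, ly)),
                        z_index=k,
                        width=float(side),
                        height=float(side),
                        confidence=float(rng.beta(*noise.spurious_confidence)),
                        mean_intensity=None,
                    )
                )
    return SliceResult(boxes=boxes, unobservable=unobservable)
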