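"""End-to-end orchestration: one config, one seed, one run directory.

A run executes simulate (optional) → aggregate → grid → spatial statistics
(Moran's I per class, density clusters, cluster-vs-surround permutation
tests with Holm correction, presence/absence models, quartile
neighborhoods) → evaluation (optional, simulated runs only), writing
``cells.csv``, ``cubes.csv``, ``clusters.csv``, ``report.json`` and the
resolved config next to them.  All randomness flows from the single
``seed``; identical config + seed gives byte-identical reports, and every
output records the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import aggregate3d, cube_grid, detections_io, evaluation, spatial_stats, synthetic

__all__ = ["DEFAULT_CONFIG", "resolve_config", "config_hash", "run_pipeline"]

log = logging.getLogger("cubicell")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "calibration": {"pixel_size_x": 1.0, "pixel_size_y": 1.0, "z_step": 5.0},
    "simulate": {
        "volume": [500.0, 500.0, 500.0],
        "classes": "default",
        "noise": {
            "miss_rate": 0.0,
            "fp_rate": 0.0,
            "center_jitter_sd": 0.0,
            "size_jitter_sd": 0.0,
        },
    },
    "input": None,
    "aggregate": {"distance_mode": "euclidean3d", "min_boxes_per_cell": 1},
    "grid": {"cube_size": 45.0, "mask": None, "origin": None},
    "stats": {
        "quantile": 0.75,
        "permutations": 5000,
        "reference_class": "AML",
        "presence_classes": ["CTL", "MK"],
    },
    "evaluate": {"enabled": True, "iou_threshold": 0.5},
}


def _merge(defaults: Mapping[str, Any], user: Mapping[str, Any], path: str = "") -> dict[str, Any]:
    """Overlay user keys onto defaults, rejecting keys the schema lacks."""
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], Mapping) and isinstance(value, Mapping):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def resolve_config(config: Mapping[str, Any] | str | Path | None) -> dict[str, Any]:
    """Load (YAML path or mapping) and validate a run config against the schema."""
    if config is None:
        user: Mapping[str, Any] = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = config
    resolved = _merge(DEFAULT_CONFIG, user)
    if resolved["simulate"] is None and resolved["input"] is None:
        raise ValueError("config must provide either a 'simulate' block or an 'input' block")
    return resolved


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of the resolved config."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _class_specs_from_config(spec_cfg) -> tuple[synthetic.ClassSpec, ...]:
    if spec_cfg == "default" or spec_cfg is None:
        return synthetic.default_class_specs()
    return tuple(
        synthetic.ClassSpec(name=name, **params) for name, params in spec_cfg.items()
    )


def run_pipeline(config: Mapping[str, Any] | str | Path | None, out_dir: str | Path) -> Path:
    """Execute the full workflow under one seed; returns the run directory."""
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": chash, **cfg}, fh, sort_keys=True)

    seed = cfg["seed"]
    ss = np.random.SeedSequence(seed)
    sim_seed, slice_seed, perm_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    calib = detections_io.Calibration(**cfg["calibration"])
    report: dict[str, Any] = {"config_hash": chash, "seed": seed}

    # -- inputs: simulate or load --------------------------------------
    truth = None
    stage = "simulate" if cfg["simulate"] else "input"
    try:
        if cfg["simulate"]:
            sim = cfg["simulate"]
            specs = _class_specs_from_config(sim["classes"])
            truth = synthetic.simulate_cells(tuple(sim["volume"]), specs, seed=sim_seed)
            truth.cells.to_csv(out / "truth.csv", index=False)
            noise = synthetic.NoiseModel(**(sim.get("noise") or {}))
            sliced = synthetic.slice_to_boxes(truth, calib, noise, seed=slice_seed)
            boxes = sliced.boxes
            report["simulate"] = {
                "n_true_cells": int(truth.n_cells),
                "n_true_by_class": {k: int(v) for k, v in truth.counts_by_class().items()},
                "n_boxes": len(boxes),
                "n_unobservable": len(sliced.unobservable),
            }
        else:
            inp = cfg["input"]
            if isinstance(inp, Mapping) and "manifest" in inp:
                boxes = detections_io.read_tile_detections(
                    inp["detections"], inp["manifest"], calib,
                    {int(k): v for k, v in inp["class_map"].items()},
                )
            else:
                path = inp["detections"] if isinstance(inp, Mapping) else inp
                boxes = detections_io.read_detection_table(path)
            report["input"] = {"n_boxes": len(boxes)}
        detections_io.write_detection_table(boxes, out / "detections.csv")

        stage = "aggregate"
        params = aggregate3d.AggregationParams(**cfg["aggregate"])
        agg = aggregate3d.aggregate_boxes(boxes, calib, params)
        aggregate3d.write_cells_table(agg.cells, out / "cells.csv")
        report["aggregate"] = {
            "n_cells": len(agg.cells),
            "n_discarded": len(agg.discarded),
            "n_by_class": dict(
                pd.Series([c.cell_class for c in agg.cells]).value_counts().astype(int)
            )
            if agg.cells
            else {},
        }

        stage = "grid"
        gcfg = cfg["grid"]
        mask = None
        if gcfg["mask"]:
            mask_path = str(gcfg["mask"])
            if mask_path.endswith((".tif", ".tiff")):
                mask = cube_grid.read_mask_tiff(
                    mask_path, gcfg["cube_size"], calib.pixel_size_x, calib.z_step
                )
            else:
                mask = cube_grid.read_mask_csv(mask_path)
        origin = tuple(gcfg["origin"]) if gcfg["origin"] else None
        grid = cube_grid.build_grid(
            agg.cells, cube_size=gcfg["cube_size"], mask=mask, origin=origin
        )
        grid.to_frame().to_csv(out / "cubes.csv", index=False)
        graph = cube_grid.neighbor_graph(grid)
        report["grid"] = {
            "cube_size": gcfg["cube_size"],
            "dims": list(grid.spec.dims),
            "n_in_mask": grid.n_nodes,
            "n_excluded": {k: int(v) for k, v in grid.n_excluded.items()},
        }

        stage = "stats"
        scfg = cfg["stats"]
        report["moran"] = {}
        for c in grid.classes:
            try:
                res = spatial_stats.morans_i(grid, graph, c)
                report["moran"][c] = {"I": res.I, "n": res.n, "sum_weights": res.sum_weights}
            except ValueError as exc:
                report["moran"][c] = {"error": str(exc)}

        report["clusters"] = {}
        clusterings = {}
        for c in grid.classes:
            clustering = spatial_stats.density_clusters(grid, graph, c, scfg["quantile"])
            clusterings[c] = clustering
            cell_totals = clustering.cluster_cell_counts(grid)
            total = int(grid.counts_in_mask(c).sum())
            report["clusters"][c] = {
                "q3_threshold": clustering.q3_threshold,
                "n_clusters": clustering.n_clusters,
                "cluster_cell_counts": [int(v) for v in cell_totals],
                "fraction_in_largest": (float(cell_totals[0]) / total)
                if clustering.n_clusters and total
                else None,
            }

        ref = scfg["reference_class"]
        presence = tuple(scfg["presence_classes"])
        report["permutation"] = {}
        report["glm"] = {}
        report["neighborhoods"] = {}
        if ref in clusterings and clusterings[ref].n_clusters > 0:
            ref_clustering = clusterings[ref]
            labels = ref_clustering.cluster_label.ravel(order="C")
            pd.DataFrame(
                {
                    "flat_index": np.flatnonzero(labels),
                    "cluster": labels[labels > 0],
                }
            ).to_csv(out / "clusters.csv", index=False)
            regions = spatial_stats.cluster_regions(ref_clustering, graph)
            for tested in presence:
                if tested not in grid.classes:
                    continue
                results = spatial_stats.permutation_suite(
                    grid, regions, tested, m=scfg["permutations"], seed=perm_seed
                )
                report["permutation"][tested] = [
                    {
                        "cluster_id": r.cluster_id,
                        "observed_M": r.observed_M,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "n_cluster": r.n_cluster,
                        "n_surround": r.n_surround,
                        "testable": r.testable,
                    }
                    for r in results
                ]
            if len(presence) == 2 and all(c in grid.classes for c in presence):
                for comp in ("first-only", "both", "second-only"):
                    try:
                        g = spatial_stats.presence_glm(grid, ref_clustering, comp, presence)
                        report["glm"][g.composition_label] = {
                            "coefficient": g.coefficient,
                            "odds_ratio": g.odds_ratio,
                            "std_error": g.std_error,
                            "p_value": g.p_value,
                            "separation": g.separation_flag,
                            "table": list(map(list, g.table)),
                        }
                    except ValueError as exc:
                        report["glm"][comp] = {"error": str(exc)}
        if len(presence) == 2 and ref in grid.classes and all(c in grid.classes for c in presence):
            nb = spatial_stats.quartile_neighborhoods(grid, ref, presence)
            nb.table.to_csv(out / "neighborhoods.csv", index=False)
            report["neighborhoods"] = {
                "quartile_edges": list(nb.quartile_edges),
                "category_counts": {k: int(v) for k, v in nb.category_counts.items()},
            }

        if cfg["evaluate"]["enabled"] and truth is not None:
            stage = "evaluate"
            match = evaluation.match_cells_3d(agg.cells, truth.cells)
            n_pred, n_true = len(agg.cells), truth.n_cells
            report["evaluate"] = {
                "n_matched_3d": len(match.pairs),
                "recall_3d": len(match.pairs) / n_true if n_true else None,
                "precision_3d": len(match.pairs) / n_pred if n_pred else None,
            }
    except Exception as exc:
        (out / "FAILED.txt").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    log.info("run complete: %s (config %s)", out, chash)
    return out
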