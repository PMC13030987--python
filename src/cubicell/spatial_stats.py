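"""Spatial statistics on cube grids.

The statistical core of the pipeline:

* **Moran's I** — global spatial autocorrelation of per-cube counts under
  binary face-adjacency weights.  I > 0: cells aggregate in common areas;
  I ≈ 0: random placement; I < 0: over-dispersion.
* **Density clustering** — a quartile-thresholded DBSCAN variant: a cube
  and its neighbors are marked high-density when their neighborhood mean
  count strictly exceeds the class's third quartile over all in-mask cubes;
  contiguous marked cubes merge into clusters, numbered by decreasing total
  cell count.
* **Cluster-vs-surround permutation test** — the statistic
  M = |mean count in the cluster − mean count in the adjacent shell| under
  random re-partitions of the pooled counts, with Holm-Bonferroni
  correction across clusters.
* **Presence/absence logistic models** — odds of a composition (e.g. cubes
  containing one companion class but not the other) inside vs outside
  dense regions of a reference class.
* **Quartile neighborhoods** — every cube labelled by reference-class
  density quartile × presence/absence of two companion classes: 16
  composition categories.

Quantiles use the type-7 (linear interpolation) convention throughout, and
density thresholds use a strict ``>``; toy grids are sensitive to both, so
they are fixed here once.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .cube_grid import CubeGrid, NeighborGraph

__all__ = [
    "MoranResult",
    "DensityClustering",
    "ClusterRegion",
    "PermutationResult",
    "GlmResult",
    "NeighborhoodTable",
    "morans_i",
    "density_clusters",
    "cluster_regions",
    "permutation_test",
    "permutation_suite",
    "holm_bonferroni",
    "presence_glm",
    "quartile_neighborhoods",
    "cluster_centroids",
    "points_in_clusters",
]


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoranResult:
    """Moran's I for one cell class on one grid."""

    cell_class: str
    I: float
    n: int
    sum_weights: int


def morans_i(grid: CubeGrid, graph: NeighborGraph, cell_class: str) -> MoranResult:
    """Global Moran's I of one class's per-cube counts.

    I = n · Σ_{i≠j} φ_ij (a_i − ā)(a_j − ā) / (Σ_i (a_i − ā)² · Σ_{i≠j} φ_ij)

    with sums over in-mask cubes and binary face-adjacency weights φ.

    Raises
    ------
    ValueError
        If fewer than 2 in-mask cubes, if the counts have zero variance
        (I is undefined, not NaN), or if the graph has no edges.
    """
    a = grid.counts_in_mask(cell_class).astype(float)
    n = a.size
    if n < 2:
        raise ValueError(f"Moran's I needs >= 2 in-mask cubes, got {n}")
    z = a - a.mean()
    s2 = float(z @ z)
    if s2 == 0.0:
        raise ValueError(f"Moran's I undefined: zero variance in {cell_class!r} counts")
    w = graph.sum_weights
    if w == 0:
        raise ValueError("Moran's I undefined: the neighbor graph has no edges")
    cross = float(z @ (graph.adjacency @ z))
    return MoranResult(cell_class=cell_class, I=n * cross / (s2 * w), n=n, sum_weights=w)


# ---------------------------------------------------------------------------
# Density clustering (quartile-thresholded DBSCAN variant)
# ---------------------------------------------------------------------------

@dataclass
class DensityClustering:
    """High-density marking and contiguous cluster labels for one class.

    ``high_density`` and ``cluster_label`` are arrays over the full grid
    shape; out-of-mask cubes are always False / 0.  Labels 1..n_clusters are
    assigned in decreasing order of total cell count within the cluster.
    """

    cell_class: str
    quantile: float
    q3_threshold: float
    high_density: np.ndarray
    cluster_label: np.ndarray
    n_clusters: int

    def member_flat_indices(self, label: int) -> np.ndarray:
        """Flat (C-order) cube indices belonging to one cluster."""
        return np.flatnonzero(self.cluster_label.ravel(order="C") == label)

    def cluster_cell_counts(self, grid: CubeGrid) -> np.ndarray:
        """Total cells of the clustered class per label, index 0 = label 1."""
        counts = grid.counts[self.cell_class].ravel(order="C")
        return np.array(
            [int(counts[self.member_flat_indices(lab)].sum()) for lab in range(1, self.n_clusters + 1)]
        )


def density_clusters(
    grid: CubeGrid,
    graph: NeighborGraph,
    cell_class: str,
    quantile: float = 0.75,
) -> DensityClustering:
    """Mark high-density neighborhoods and merge them into contiguous clusters.

    The threshold is the ``quantile`` (default third quartile) of the
    class's counts over *all* in-mask cubes, zero-count cubes included,
    using type-7 linear interpolation.  For each in-mask cube i, if the
    mean count over {i} ∪ N_i strictly exceeds the threshold, i and all of
    N_i are marked.  Clusters are the face-connected components of marked
    cubes, relabelled 1..k by descending total cell count (ties broken by
    smallest member flat index).
    """
    a = grid.counts_in_mask(cell_class).astype(float)
    threshold = float(np.quantile(a, quantile)) if a.size else 0.0
    adj = graph.adjacency
    neigh_sum = adj @ a
    neigh_mean = (a + neigh_sum) / (1.0 + graph.degrees)
    trigger = neigh_mean > threshold
    marked = trigger | (adj @ trigger.astype(np.int8) > 0)

    high_density = np.zeros(grid.spec.dims, dtype=bool)
    label_arr = np.zeros(grid.spec.dims, dtype=np.int64)
    n_clusters = 0
    if marked.any():
        sub_nodes = np.flatnonzero(marked)
        sub = adj[sub_nodes][:, sub_nodes]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        # Order labels by descending total class count, then smallest flat index.
        totals = np.zeros(n_comp)
        first_flat = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
        flat_of_sub = grid.node_flat_indices[sub_nodes]
        np.add.at(totals, comp, a[sub_nodes])
        np.minimum.at(first_flat, comp, flat_of_sub)
        order = np.lexsort((first_flat, -totals))
        rank = np.empty(n_comp, dtype=np.int64)
        rank[order] = np.arange(1, n_comp + 1)
        flat_mask = np.zeros(grid.mask.size, dtype=bool)
        flat_mask[flat_of_sub] = True
        high_density = flat_mask.reshape(grid.spec.dims)
        flat_label = np.zeros(grid.mask.size, dtype=np.int64)
        flat_label[flat_of_sub] = rank[comp]
        label_arr = flat_label.reshape(grid.spec.dims)
        n_clusters = int(n_comp)

    return DensityClustering(
        cell_class=cell_class,
        quantile=quantile,
        q3_threshold=threshold,
        high_density=high_density,
        cluster_label=label_arr,
        n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# Cluster regions and permutation tests
# ---------------------------------------------------------------------------

@dataclass
class ClusterRegion:
    """A cluster's cube set C_τ and its adjacent shell C_τ^c (flat indices)."""

    cluster_id: int
    members: np.ndarray
    adjacent: np.ndarray

    @property
    def testable(self) -> bool:
        return self.adjacent.size > 0

    @property
    def sizes(self) -> tuple[int, int]:
        return (int(self.members.size), int(self.adjacent.size))


def cluster_regions(
    clustering: DensityClustering,
    graph: NeighborGraph,
    exclude: str = "all_clusters",
) -> list[ClusterRegion]:
    """Identify each cluster's members and its adjacent (surround) cubes.

    The surround of a cluster is the set of in-mask cubes sharing a face
    with at least one member.  With ``exclude="all_clusters"`` (default) the
    surround excludes every high-density cube of the reference class, so it
    represents non-dense tissue; ``exclude="focal"`` removes only the focal
    cluster's own members.  A region whose surround is empty is emitted with
    an empty adjacent set and flagged untestable by its ``testable`` property.
    """
    if exclude not in ("all_clusters", "focal"):
        raise ValueError("exclude must be 'all_clusters' or 'focal'")
    grid = graph.grid
    label_flat = clustering.cluster_label.ravel(order="C")
    high_flat = clustering.high_density.ravel(order="C")
    regions = []
    for lab in range(1, clustering.n_clusters + 1):
        members = np.flatnonzero(label_flat == lab)
        member_nodes = graph.node_of[members]
        if (member_nodes < 0).any():
            raise ValueError("cluster member outside the in-mask graph")
        indicator = np.zeros(graph.n_nodes, dtype=np.int8)
        indicator[member_nodes] = 1
        touched = graph.adjacency @ indicator > 0
        touched[member_nodes] = False
        adj_flat = grid.node_flat_indices[np.flatnonzero(touched)]
        other = adj_flat[(label_flat[adj_flat] != lab) & (label_flat[adj_flat] > 0)]
        if other.size:
            # Marked cubes always carry their component's label; a face
            # contact between two different labels violates contiguity.
            raise ValueError(
                f"contiguity violated: cluster {lab} touches cluster(s) "
                f"{sorted(set(label_flat[other]))}"
            )
        if exclude == "all_clusters":
            adj_flat = adj_flat[~high_flat[adj_flat]]
        regions.append(ClusterRegion(cluster_id=lab, members=members, adjacent=adj_flat))
    return regions


@dataclass
class PermutationResult:
    """Cluster-vs-surround permutation test for one cluster and one class."""

    cluster_id: int
    tested_class: str
    observed_M: float | None
    n_permutations: int
    p_raw: float | None
    p_adjusted: float | None
    seed: int | None
    mode: str
    testable: bool = True
    n_cluster: int = 0
    n_surround: int = 0


def permutation_test(
    grid: CubeGrid,
    region: ClusterRegion,
    tested_class: str,
    m: int = 500_000,
    seed: int | None = None,
    mode: str = "montecarlo",
    exhaustive_bound: int = 2_000_000,
) -> PermutationResult:
    """Test whether a class's mean per-cube count differs between C_τ and C_τ^c.

    The observed statistic is M = |mean over C_τ − mean over C_τ^c|.  The
    pooled counts are re-partitioned into groups of the original sizes; the
    p-value is the upper tail of the absolute statistic (M is already an
    absolute difference, which is how the two-tailed test is realised).

    ``mode="montecarlo"`` draws ``m`` random permutations and uses the
    add-one estimator p = (1 + #{M_π ≥ M}) / (1 + m), which never returns 0.
    ``mode="exhaustive"`` enumerates all C(n, |C_τ|) distinct partitions
    (allowed while that count ≤ ``exhaustive_bound``) and returns the exact
    tail proportion.  Seeded runs are bit-reproducible.

    An untestable region (empty surround) yields an explicit skip record
    with ``p_raw=None``, never p = 1.
    """
    if mode not in ("montecarlo", "exhaustive"):
        raise ValueError("mode must be 'montecarlo' or 'exhaustive'")
    n1, n2 = region.sizes
    if n1 < 1 or not region.testable:
        return PermutationResult(
            cluster_id=region.cluster_id,
            tested_class=tested_class,
            observed_M=None,
            n_permutations=0,
            p_raw=None,
            p_adjusted=None,
            seed=seed,
            mode=mode,
            testable=False,
            n_cluster=n1,
            n_surround=n2,
        )
    counts_flat = grid.counts[tested_class].ravel(order="C").astype(float)
    a_in = counts_flat[region.members]
    a_out = counts_flat[region.adjacent]
    observed = abs(a_in.mean() - a_out.mean())
    pooled = np.concatenate([a_in, a_out])
    n = n1 + n2
    tol = 1e-12 * max(1.0, observed)

    if mode == "exhaustive":
        total = math.comb(n, n1)
        if total > exhaustive_bound:
            raise ValueError(
                f"exhaustive enumeration of C({n},{n1}) = {total} partitions exceeds the "
                f"bound {exhaustive_bound}; use montecarlo mode"
            )
        pooled_sum = pooled.sum()
        hits = 0
        for combo in itertools.combinations(range(n), n1):
            s = pooled[list(combo)].sum()
            stat = abs(s / n1 - (pooled_sum - s) / n2)
            if stat >= observed - tol:
                hits += 1
        p_raw = hits / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        chunk = max(1, int(2e7 // n))
        remaining = m
        while remaining > 0:
            k = min(chunk, remaining)
            block = np.broadcast_to(pooled, (k, n)).copy()
            block = rng.permuted(block, axis=1)
            s = block[:, :n1].sum(axis=1)
            stat = np.abs(s / n1 - (pooled.sum() - s) / n2)
            hits += int((stat >= observed - tol).sum())
            remaining -= k
        p_raw = (1 + hits) / (1 + m)
        n_perm = m

    return PermutationResult(
        cluster_id=region.cluster_id,
        tested_class=tested_class,
        observed_M=float(observed),
        n_permutations=n_perm,
        p_raw=float(p_raw),
        p_adjusted=None,
        seed=seed,
        mode=mode,
        testable=True,
        n_cluster=n1,
        n_surround=n2,
    )


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-adjusted p-values, returned in the input order.

    The k-th smallest p is multiplied by (m − k + 1), a running maximum
    enforces monotonicity, and values are capped at 1.  Inputs must lie in
    (0, 1].
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, alpha=0.05, method="holm")[1]


def permutation_suite(
    grid: CubeGrid,
    regions: Sequence[ClusterRegion],
    tested_class: str,
    m: int = 500_000,
    seed: int | None = None,
    mode: str = "montecarlo",
) -> list[PermutationResult]:
    """Run the permutation test over all regions and Holm-correct across them.

    The correction family is all testable clusters for the one tested class.
    Each region receives an independent child seed spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(regions))
    results = []
    for region, child in zip(regions, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(
            permutation_test(grid, region, tested_class, m=m, seed=child_seed, mode=mode)
        )
    testable = [r for r in results if r.testable]
    if testable:
        adjusted = holm_bonferroni([r.p_raw for r in testable])
        for r, adj in zip(testable, adjusted):
            r.p_adjusted = float(adj)
    return results


# ---------------------------------------------------------------------------
# Presence/absence logistic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmResult:
    """Binomial-logit fit of dense-region membership on cube composition.

    With a single binary predictor the coefficient equals the log odds
    ratio of the 2×2 (composition × in-cluster) table.  Under complete or
    quasi-separation (a zero cell in that table) ``separation_flag`` is set
    and the non-finite estimate is reported as such, never fabricated.
    """

    composition_label: str
    coefficient: float
    odds_ratio: float
    std_error: float
    p_value: float
    separation_flag: bool
    table: tuple[tuple[int, int], tuple[int, int]] = field(default=((0, 0), (0, 0)))


_COMPOSITIONS = ("first-only", "second-only", "both")


def presence_glm(
    grid: CubeGrid,
    clustering: DensityClustering,
    composition: str,
    other_classes: tuple[str, str],
) -> GlmResult:
    """Odds of a cube composition inside vs outside dense reference regions.

    The response is whether an in-mask cube belongs to any dense cluster of
    the reference class; the single binary predictor is whether the cube
    matches ``composition`` over ``other_classes`` — ``"first-only"``
    (contains the first class and not the second), ``"second-only"``, or
    ``"both"``.
    """
    if composition not in _COMPOSITIONS:
        raise ValueError(f"composition must be one of {_COMPOSITIONS}")
    c1, c2 = other_classes
    y = clustering.cluster_label.ravel(order="C")[grid.node_flat_indices] > 0
    if y.all() or not y.any():
        raise ValueError("both response levels (in/out of cluster) must be present")
    p1 = grid.counts_in_mask(c1) > 0
    p2 = grid.counts_in_mask(c2) > 0
    if composition == "first-only":
        x = p1 & ~p2
        label = f"{c1}-only"
    elif composition == "second-only":
        x = ~p1 & p2
        label = f"{c2}-only"
    else:
        x = p1 & p2
        label = f"{c1}-and-{c2}"

    n11 = int((x & y).sum())      # composition present, in cluster
    n01 = int((~x & y).sum())     # composition absent, in cluster
    n10 = int((x & ~y).sum())     # composition present, outside
    n00 = int((~x & ~y).sum())    # composition absent, outside
    table = ((n11, n01), (n10, n00))

    if min(n11, n01, n10, n00) == 0:
        warnings.warn(
            f"separation in presence model {label!r}: a zero cell in the 2x2 table; "
            "reporting a non-finite estimate",
            stacklevel=2,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            log_or = np.log(n11 * n00) - np.log(n01 * n10) if (n11 * n00 or n01 * n10) else np.nan
        coef = float(log_or) if not np.isnan(log_or) else float("nan")
        return GlmResult(
            composition_label=label,
            coefficient=coef,
            odds_ratio=float(np.exp(coef)) if np.isfinite(coef) else (0.0 if coef == -np.inf else float("inf")),
            std_error=float("nan"),
            p_value=float("nan"),
            separation_flag=True,
            table=table,
        )

    import statsmodels.api as sm

    exog = sm.add_constant(x.astype(float))
    fit = sm.GLM(y.astype(float), exog, family=sm.families.Binomial()).fit(
        tol=1e-10, maxiter=200
    )
    coef = float(fit.params[1])
    return GlmResult(
        composition_label=label,
        coefficient=coef,
        odds_ratio=float(np.exp(coef)),
        std_error=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        separation_flag=bool(abs(coef) > 20),
        table=table,
    )


# ---------------------------------------------------------------------------
# Quartile neighborhoods
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodTable:
    """Per-cube composition categories: density quartile × two presence flags."""

    reference_class: str
    presence_classes: tuple[str, str]
    quartile_edges: tuple[float, float, float]
    table: pd.DataFrame
    categories: tuple[str, ...]

    @property
    def category_counts(self) -> pd.Series:
        counts = self.table["category"].value_counts()
        return counts.reindex(self.categories, fill_value=0)


def quartile_neighborhoods(
    grid: CubeGrid,
    reference_class: str,
    presence_classes: tuple[str, str],
) -> NeighborhoodTable:
    """Classify every in-mask cube into one of 16 composition categories.

    Cubes are binned into quartiles of the reference class's counts (type-7
    edges at Q1, Q2, Q3; ties go to the lowest qualifying bin) and flagged
    for the presence (count > 0) of each of the two companion classes.
    The 4 × 2 × 2 = 16 category labels partition the in-mask cubes.
    """
    c1, c2 = presence_classes
    ref = grid.counts_in_mask(reference_class).astype(float)
    q1, q2, q3 = (float(np.quantile(ref, q)) for q in (0.25, 0.5, 0.75))
    bins = 1 + (ref > q1).astype(int) + (ref > q2).astype(int) + (ref > q3).astype(int)
    f1 = grid.counts_in_mask(c1) > 0
    f2 = grid.counts_in_mask(c2) > 0

    def cat_label(b: int, a: bool, bb: bool) -> str:
        return f"Q{b}|{c1}{'+' if a else '-'}|{c2}{'+' if bb else '-'}"

    categories = tuple(
        cat_label(b, a, bb)
        for b in (1, 2, 3, 4)
        for a in (True, False)
        for bb in (True, False)
    )
    flat = grid.node_flat_indices
    dims = grid.spec.dims
    ix, iy, iz = np.unravel_index(flat, dims)
    table = pd.DataFrame(
        {
            "ix": ix,
            "iy": iy,
            "iz": iz,
            "quartile": bins,
            f"has_{c1}": f1,
            f"has_{c2}": f2,
            "category": [cat_label(b, a, bb) for b, a, bb in zip(bins, f1, f2)],
        }
    )
    return NeighborhoodTable(
        reference_class=reference_class,
        presence_classes=(c1, c2),
        quartile_edges=(q1, q2, q3),
        table=table,
        categories=categories,
    )


# ---------------------------------------------------------------------------
# Cross-resolution helpers
# ---------------------------------------------------------------------------

def cluster_centroids(clustering: DensityClustering, grid: CubeGrid) -> dict[int, tuple[float, float, float]]:
    """Geometric centroid (μm, cube centres) of each cluster's member cubes."""
    out = {}
    for lab in range(1, clustering.n_clusters + 1):
        flat = clustering.member_flat_indices(lab)
        ix, iy, iz = np.unravel_index(flat, grid.spec.dims)
        t = grid.spec.cube_size
        x0, y0, z0 = grid.spec.origin
        out[lab] = (
            float(x0 + (ix + 0.5).mean() * t),
            float(y0 + (iy + 0.5).mean() * t),
            float(z0 + (iz + 0.5).mean() * t),
        )
    return out


def points_in_clusters(
    clustering: DensityClustering, grid: CubeGrid, points: np.ndarray
) -> np.ndarray:
    """True where a μm point falls inside any cube of a nonzero cluster label."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    idx = np.floor((points - np.asarray(grid.spec.origin)) / grid.spec.cube_size).astype(int)
    dims = np.asarray(grid.spec.dims)
    ok = (idx >= 0).all(axis=1) & (idx < dims).all(axis=1)
    result = np.zeros(len(points), dtype=bool)
    inside = idx[ok]
    result[ok] = clustering.cluster_label[inside[:, 0], inside[:, 1], inside[:, 2]] > 0
    return result
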