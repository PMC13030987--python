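# Methods

This note records the models, conventions and numerical choices behind
`cubicell`, and what the synthetic experiments do and do not demonstrate.

## 3D aggregation of 2D detections

A cell imaged at a fixed z-step leaves a stack of roughly concentric boxes
on consecutive layers.  Aggregation processes each class's boxes in a
static lexicographic order — maximum box diameter descending, mean
fluorescence intensity descending, confidence descending, input position
ascending — and greedily absorbs, for each unassigned seed box, every
unassigned same-class box whose centre lies within half the seed's maximum
diameter of the seed centre.  Intensity affects only the ordering and is
never thresholded, so dim cells are linked exactly like bright ones.
Choices worth making explicit:

* **Distance rule.** The default is full 3D Euclidean distance (z in μm),
  which simultaneously merges stacked slices of one cell and duplicate
  detections from overlapping mosaic tiles.  An alternative
  `xy_plus_z_window` mode (xy distance < d/2 *and* |Δz| < d/2) is available
  for anisotropic use cases.
* **d for rectangles** is max(width, height) of the seed box.
* **Strict inequality**: a box at exactly d/2 is not absorbed.
* Boxes need not occupy consecutive layers, so a single missed detection
  inside a stack does not split a cell into two pieces unless the remaining
  boxes fall outside the seed's radius.
* The deterministic final tiebreak makes the output invariant to input
  permutation; `min_boxes_per_cell` (default 1) optionally discards
  single-box specks, which are reported separately rather than dropped
  silently.
* Tile-overlap duplicates are intentionally *not* removed at read time; the
  d/2 rule absorbs them during aggregation.

A geometric consequence of the d/2 rule worth knowing: with a 5 μm z-step,
a sphere of diameter below ≈11.2 μm slices into adjacent-layer boxes that
are 5 μm apart while d/2 < 5, so its stack fragments into per-layer cells;
diameters between ≈19 and 21 μm place the outermost slice exactly two
steps (10 μm) from the seed while d/2 < 10, which also splits.  The
synthetic presets use 12 μm and 25 μm diameters so that a noiselessly
sliced sphere always re-aggregates into exactly one cell.

## Cube grid and neighborhood

Cells are binned into θ-sided cubes over half-open intervals
[origin + kθ, origin + (k+1)θ); the default θ = 45 μm keeps a handful of
cells of the dominant class per occupied cube while the grid stays small
enough to enumerate.  The grid origin defaults to the componentwise data
minimum and can be pinned to the image origin.  A cube's coordinate
(u, v, z) is the midpoint of its lowest-z face.  Two cubes are neighbors
iff they share a face (centroid distance exactly θ): interior cubes have
6 neighbors, a 7-cube neighborhood with the centre.  An optional marrow
mask (per-cube CSV or a majority-vote-downsampled TIFF label stack)
restricts counts and the graph; cells, not cubes, are the unit of
exclusion.

## Moran's I

Global autocorrelation with binary face-adjacency weights, computed over
in-mask cubes.  Zero variance raises an explicit "undefined" error rather
than returning NaN.  The implementation is cross-checked in the test suite
against an O(n²) double-loop oracle (1e-12 relative) and against the
permutation-null expectation E[I] = −1/(n−1).

## Density clustering

The third quartile of a class's per-cube counts — over *all* in-mask
cubes, zeros included — is computed with the type-7 (linear interpolation)
quantile convention.  A cube whose 7-cube neighborhood mean strictly
exceeds that threshold marks itself and its whole neighborhood as
high-density; face-connected components of marked cubes are the clusters,
labelled in decreasing order of contained cell count (ties broken by
lowest cube index).  Both the quantile convention and the strict
inequality matter on small grids and are therefore fixed here and
exercised by worked examples in the tests.  Component labelling uses
sparse connected components; an independent mark-then-flood-fill oracle in
the test suite verifies the partition on fuzzed grids.

A direct consequence of this rule: for a class so sparse that more than
75 % of cubes are empty, the threshold is zero and *every* neighborhood
containing at least one cell is marked.  Sparse near-random classes
therefore produce clusters — typically small halos around isolated cells
that can percolate into larger components — rather than none.  A minimum
cluster size or a positive threshold floor would change this, but the rule
is kept as stated; interpret cluster counts for very sparse classes
accordingly (the cluster *content*, reported per label, distinguishes a
halo around one cell from a genuine aggregate).

## Permutation tests

For each cluster C_τ, the surround C_τᶜ is the set of in-mask cubes
sharing a face with the cluster, excluding by default every high-density
cube of the reference class so the surround represents non-dense tissue
(excluding only the focal cluster is available as an option).  The test
statistic is the absolute difference of per-cube means; because M is
already absolute, the two-tailed test is realised as the upper tail of M.
Monte Carlo mode draws m random re-partitions (Fisher–Yates shuffles of
the pooled counts, one seeded generator per run, chunked for memory) and
uses the add-one estimator p = (1 + #{M_π ≥ M}) / (1 + m), which never
returns zero.  Exhaustive mode enumerates all C(n, |C_τ|) partitions when
that count is below a configurable bound and returns the exact tail
proportion.  Ties at the observed statistic count as exceedances (a 1e-12
relative tolerance guards against float noise).  A cluster with an empty
surround yields an explicit skip record, never p = 1.  Holm-Bonferroni is
applied across all testable clusters for one tested class; the default of
m = 500,000 permutations follows common practice for resolving p-values
after correction across tens of clusters, and smaller m is used in the
bundled demos for speed.

## Presence/absence models

Each in-mask cube contributes one observation: the response is membership
of any dense reference-class cluster; the single binary predictor is a
composition over the two companion classes ("first-only", "second-only",
or "both", with presence meaning count > 0).  Three separate
single-predictor binomial-logit models are fitted (IRLS, tolerance 1e-10)
rather than one multi-predictor model, so each coefficient equals the
closed-form log odds ratio of its 2×2 table — a property the tests assert
to 1e-8.  A zero cell in that table means complete or quasi-separation:
the result is flagged and the non-finite estimate reported as such, never
replaced by a fabricated finite number.

## Quartile neighborhoods

Cubes are binned by the reference class's count quartiles (type-7 edges at
Q1, Q2, Q3; ties fall to the lowest qualifying bin) and flagged for
presence of each companion class, yielding 4 × 2 × 2 = 16 categories that
partition the in-mask cubes.  With heavily zero-inflated counts the lower
edges coincide (Q1 = Q2 = 0 puts all empty cubes in bin 1 and empties
bin 2); this is the documented tie rule, not a defect.

## Synthetic tissue

`simulate_cells` places spherical cells by class: homogeneous Poisson
(CSR), Thomas (Poisson parents, Poisson offspring counts, isotropic
Gaussian displacement, offspring outside the volume discarded), or
hard-core-thinned CSR (sequential rejection; an exhausted budget raises an
error reporting the achieved count).  The default presets emulate an
infiltrated marrow in 500³ μm³: ≈5,000 strongly clustered cells (Thomas,
σ = 30 μm, Ø 12 μm), ≈500 weakly clustered cells (Thomas, σ = 40 μm,
Ø 12 μm — the dispersion is set so this class's Moran's I lands in the
intermediate regime ≈0.3, clearly separated from the clustered ≈0.6 and
random ≈0 classes), and ≈100 near-random large cells (hard-core CSR,
30 μm separation, Ø 25 μm).  Diameters are clipped at ±2 sd to stay inside
the aggregation-safe ranges described above.

`slice_to_boxes` intersects each sphere with the image planes
(z = k·z-step), emitting a square box with the chord side
2·sqrt((D/2)² − Δz²) for each plane with |Δz| < D/2 (strict: tangent
planes leave nothing).  Cells intersecting no plane are reported as
unobservable.  The noise model drops boxes with probability `miss_rate`,
jitters centres and sides with Gaussian noise, and adds spurious boxes at
`fp_rate` per layer per 100×100 μm², with Beta-distributed confidences
(high for true boxes, low for spurious ones).  Everything is
bit-reproducible for a fixed seed.

What the simulator does *not* emulate: irregular (non-spherical) cell
shapes, anisotropic point-spread blur, intensity gradients with depth,
stitching artefacts at tile seams, and spatial correlation between
classes (classes are placed independently, so cross-class statistics have
no built-in effect; tests that pass on synthetic data therefore validate
the statistical machinery, not any biological claim about attraction or
exclusion between cell types).

## Evaluation

2D matching is greedy, one-to-one, in descending confidence order, each
prediction taking the highest-IOU unmatched truth box of its class and
layer at or above the threshold.  The PR sweep uses the distinct
confidences descending; average precision integrates the curve with
precision interpolated as the running maximum to the right, evaluated at
the distinct-threshold points so that the order of equal-confidence
predictions cannot change AP.  3D cells are matched by centroid distance
within the truth cell's radius.  Region count comparisons use half-open
bounds; overlapping regions warn but are still reported.

## Pipeline and problem sizes

`run_pipeline` chains simulate → aggregate → grid → statistics →
evaluation under one seed (child seeds spawned per stage), validates the
YAML config against a closed schema, stamps every run with a config hash,
and writes deterministic, byte-identical reports for identical
config + seed.  The bundled demos and the acceptance script run the full
three-class 500³ μm³ volume (≈5,600 cells, ≈12,000 boxes, 12³ cubes) in a
few seconds on one CPU; permutation counts in the demos (10³–10⁵) are
chosen to keep runs short while the library default remains 500,000.

## Known limitations

* The density-clustering rule flags any occupied neighborhood when >75 %
  of cubes are empty (see above); cluster counts for very sparse classes
  need the per-cluster content to be interpretable.
* The greedy d/2 aggregation can fragment cells whose geometry places a
  slice at or beyond half the seed diameter (quantified above); fragment
  counts can exceed the truth at moderate miss rates, which is why
  recovery is benchmarked both as raw counts and as truth-matched counts.
* Permutation tests treat cubes as exchangeable under the null; spatial
  autocorrelation within the tested class makes them anti-conservative in
  principle, as for any quadrat-based permutation scheme.
* The logistic models use one predictor at a time by design; they report
  marginal, not mutually adjusted, composition effects.
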