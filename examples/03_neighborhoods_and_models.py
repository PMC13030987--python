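"""Composition of cellular neighborhoods relative to the dominant class.

Classifies every cube by the reference class's density quartile and the
presence of the two companion classes (16 categories), and fits
presence/absence logistic models for membership of dense regions.  An
odds ratio below 1 means the composition is depleted inside dense regions.
"""

from cubicell import (
    Calibration,
    aggregate_boxes,
    build_grid,
    default_class_specs,
    density_clusters,
    neighbor_graph,
    presence_glm,
    quartile_neighborhoods,
    simulate_cells,
    slice_to_boxes,
)

calib = Calibration(1.0, 1.0, 5.0)
truth = simulate_cells((500.0, 500.0, 500.0), default_class_specs(), seed=1)
cells = aggregate_boxes(slice_to_boxes(truth, calib, seed=2).boxes, calib).cells
grid = build_grid(cells, cube_size=45.0, origin=(0, 0, 0), dims=(12, 12, 12))
graph = neighbor_graph(grid)
clustering = density_clusters(grid, graph, "AML")

nb = quartile_neighborhoods(grid, "AML", ("CTL", "MK"))
print("cube counts by AML-density quartile and CTL/MK presence:")
for category, count in nb.category_counts.items():
    print(f"  {category:<14} {count:>5}")
print(f"  total          {nb.category_counts.sum():>5}  (= in-mask cubes)")

print("\nodds of compositions inside vs outside dense AML regions:")
for comp in ("first-only", "both", "second-only"):
    fit = presence_glm(grid, clustering, comp, ("CTL", "MK"))
    flag = "  [separation]" if fit.separation_flag else ""
    print(
        f"  {fit.composition_label:<12} OR = {fit.odds_ratio:6.3f} "
        f"(p = {fit.p_value:.3g}){flag}"
    )
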