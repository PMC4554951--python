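"""Extract and measure the vascular network of a whole fruit.

Generates a scaled-down whole-fruit phantom (radius 11 mm, 0.16 mm voxels)
with a known branching bundle tree, then runs the automated pipeline:
edge-preserving smoothing, region segmentation, top-hat vessel
enhancement, skeletonization to a centerline graph, pruning, and network
metrics, compared against the generator's exact centerlines.
"""

from pomoct import (
    FruitSpec,
    make_fruit,
    network_metrics,
    prune_network,
    radial_branch_distribution,
    segment_fruit_regions,
    skeletonize_network,
    smooth_edge_preserving,
    tophat_vessels,
)
from pomoct.vasculature import RegionParams

spec = FruitSpec(seed=42)
volume, truth = make_fruit(spec)

smoothed = smooth_edge_preserving(volume, sigma=1.0, edge_stop=40)
regions = segment_fruit_regions(
    smoothed, RegionParams(dilate_px=spec.region_dilate_vox, erode_px=spec.region_erode_vox))
vessel_mask = tophat_vessels(smoothed, regions, se_width=4, height=4)
network = skeletonize_network(vessel_mask)
network = prune_network(network, min_branch_mm=2 * 4 * volume.voxel_size_mm)

total_m, density, mean_radius = network_metrics(network, regions)
print(f"fruit radius R         {regions.R_mm:6.2f} mm")
print(f"total vessel length    {total_m:6.3f} m    (truth {truth.true_total_length_m:.3f} m)")
print(f"length density         {density:6.2f} cm per cm^3 of fruit")
print(f"mean local radius      {mean_radius:6.3f} mm  (bundle incl. perivascular tissue)")
print(f"branch points          {len(network.branch_points):4d}      (truth {truth.n_branch_points})")

profile = radial_branch_distribution(network, regions, n_bins=5)
print("branch points per r/R shell (0->1):",
      " ".join(f"{int(c):3d}" for c in profile.values),
      "- branching sits at and beyond the primary-bundle ring")
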