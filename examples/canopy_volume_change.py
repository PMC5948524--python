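"""Measure harvest-induced canopy loss on a synthetic transect.

Runs the full chain twice — before harvest and after pruning 5% of each
crown's outer shell — for both scanner orientations and both scan sides:
build, align, merge, crop to the 30 cm box-anchored region of interest,
then convex-hull and minimal-alpha alpha-shape volumes.  The before-minus-
after differences are the biomass-loss indicators: a positive volume drop
and a positive point-density drop for each scanner.
"""

import olivescan as ov
from olivescan.pipeline import PHASES, SIDES, run_transect

scene = ov.generate_hedgerow(ov.SceneConfig(transect_length=8.0, seed=3))
scenes = {"before": scene, "after": ov.prune_scene(scene, 0.05)}
box_a, box_b = scene.reference_boxes
mid = scene.config.transect_length / 2

sweeps, poses, corrs = {}, {}, {}
for sensor in (1, 2):
    for side in SIDES:
        pose = ov.table_pose(sensor, side)
        poses[(sensor, side)] = pose
        for phase in PHASES:
            seed = sensor * 100 + SIDES.index(side) * 10 + PHASES.index(phase)
            sweeps[(sensor, side, phase)] = ov.simulate_lidar_pass(
                scenes[phase], pose, seed=seed)
            corrs[(sensor, side, phase)] = ov.box_corner_correspondences(
                scenes[phase], pose, seed=SIDES.index(side))

result = run_transect(sweeps, poses, corrs,
                      box_a.upper_inner_corners(mid)[0],
                      box_b.upper_inner_corners(mid)[0],
                      transect_id="example")

for sensor, name in ((1, "lateral"), (2, "upward")):
    block = result["sensors"][sensor]
    before, change = block["before"], block["change"]
    print(f"sensor {sensor} ({name}): convex hull {before.convex_hull_volume:.2f} m^3, "
          f"alpha shape {before.alpha_volume:.2f} m^3 at alpha* {before.alpha_star:.2f}")
    print(f"   harvest change: volume -{change.delta_volume:.2f} m^3, "
          f"points -{change.delta_density} "
          f"(per side: {change.per_side_delta_density})")
print("positive drops on both sensors = the harvester removed biomass; the\n"
      "alpha-shape figure is the damage indicator (the hull overstates volume\n"
      "because it cannot follow the hedge's concavities).")
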