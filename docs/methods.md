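# Methods

This note records the models, conventions, numerical choices and
limitations behind `olivescan`, in the order data flows through the
pipeline.

## Acquisition geometry

Each scanner records **271 beams spanning exactly 270°**, i.e. 1.0° between
recorded beams (the sweep-log dialect `r_000…r_270` fixes the count; the
device's native half-degree resolution is assumed subsampled by the
acquisition program). Ranges outside the operational gate (0.5, 20] m are
dropped; beams with no return carry a 21 m sentinel in the logs.

**Frames.** Sensor frame: beams in the native (x, y) plane, beam *i* along
(cos γᵢ, sin γᵢ, 0), γᵢ = `fov_start` + i·1°. Row frame: x = travel,
z = up, ground at z = 0. Mounting orientation is applied as
R = R_z(ψ)·R_y(θ)·R_x(φ). Under the four reference mountings
(sideways/upward × left/right, quarter-turn angles) every beam lands in the
vertical (y, z) cross-section plane — the defining property of a
cross-section scanner on a moving platform, and the criterion that fixed
this frame convention; the chosen matrices are pinned by unit tests.

**Field-of-view placement.** The 270° window leaves a 90° blind cone. Its
direction is set per mounting so the geometry is physically sensible:
`fov_start = −45°` everywhere except the sideways scanner on the right
side (`fov_start = 135°`, the unit remounted rotated half a turn). With
these values the sideways scanner's blind cone faces away from the row and
the upward scanner's faces straight down — which is what produces the
under-canopy occlusion of the upward unit: crown flanks below roughly
`mount_height − (lateral clearance)` are invisible to it, so its cropped
cloud, hull and alpha-shape volume run slightly smaller than the lateral
scanner's.

**Odometry.** The per-sweep encoder count (3 mm/pulse default) shifts all
271 beams of that sweep uniformly along x; no intra-sweep motion correction
is applied (at 2 km/h the platform moves ~11 mm per 20 ms sweep, below the
range noise). Negative counts (wheel rollback) are rejected.

## Synthetic scenes

The generator emulates the field layout: trees every 1.35 m over a 15 m
transect (11 crowns), crown height 2.45 ± 0.25 m and width 1.45 ± 0.25 m
(drawn per tree; the two varieties' stated envelopes, 2.4–2.5 m by
1.4–1.5 m, bracket these defaults), sampled as **filled ellipsoids**
truncated at the ground — the simplest solid matching the stated
height/width envelope. Crown point density defaults to 1500 points/m³
(~centimetre surface sampling at desk scale; the real campaign's clouds are
denser, which only sharpens every contrast tested here). Each tree uses its
own child generator, so removing a tree from the layout leaves the others
point-for-point identical. Two 0.30 m reference boxes sit just outside the
tree span with surface samples so they appear in scans; a ground strip
(40 pts/m²) provides the returns the ROI crop must remove.

The **ray model** is nearest-point-in-angular-bin: per sweep, scene points
within a 2 cm slab of the scan plane are binned by direction and the
nearest per bin returns (single-echo shadowing — foreground foliage hides
the interior, as a first-return scanner does). Gaussian range noise
(default σ = 1 cm, a mid-range figure for this sensor class) is added to
hits. The platform passes at 2 km/h (0.556 m/s) by default, from half a
metre before the first box to half a metre past the second.

**Pruning** removes round(f·n) points per tree, outermost normalised
ellipsoidal radius first (the harvester beats the canopy surface); a
seeded uniform mode exists for sensitivity checks. The removed-biomass
fraction is a free parameter — the campaign never measured ground-truth
removal — and the end-to-end checks use f = 0.05.

**Accelerometer bursts** rest at a 1 g gravity baseline on a random fixed
axis, then a √sin envelope raises the vector magnitude from the detection
threshold (2 g) at the burst edges to the requested peak mid-burst, so the
supra-threshold extent equals the requested duration by construction.
Output is quantised to 2048 counts/g and clipped at ±16 g (requesting a
larger peak yields a 16 g burst, as the hardware would).

## Registration

Alignment is least-squares rigid (Kabsch via SVD; scipy's
`Rotation.align_vectors`) on **explicitly named reference-box corners** —
no ICP, mirroring a manual-picking workflow on known immutable points. At
least 3 non-collinear pairs are required; collinear sets raise. A uniform
Procrustes scale is available behind `allow_scale` for parity with manual
workflows, but the default is rigid: encoder-calibrated clouds are metric,
and scaling would mask odometry miscalibration. Merging refuses transforms
with fit RMS above the 3 cm gate.

Corner-picking error in the simulator is 5 mm per coordinate. In the
end-to-end campaign the picking offset is drawn **once per scan side of a
transect and shared by the four clouds that use those corners** (the same
operator interprets the same physical corner the same way in every cloud),
while the registration-quality experiment draws fresh noise every trial.
This matters quantitatively: the references span only 0.3 m in (y, z), so
independent corner noise tilts each alignment about the row axis and the
tilt extrapolates to centimetres at crown height — immutable references
exist precisely so that before/after differences cancel such systematics.

## Region of interest

A pre-filter (|y| ≤ 2 m, z ≤ 8 m) strips the neighbouring row (3.75 m
away) before alignment. The crop then keeps x between the boxes' upper
inner corners and z in (z_floor, z_max], with z_floor taken from the
corners themselves (warning if > 2 cm off the nominal 0.30 m). The floor
interval is half-open so points exactly at box-top height count as ground —
a deterministic tie-break.

## Volume estimation

The alpha complex is the circumradius filtration of the Delaunay
tetrahedralisation (built once per cloud; each α query is an array
reduction). α has length units (metres here). Volume = Σ volumes of kept
tetrahedra; α → ∞ reproduces the convex hull exactly and volume is
monotone in α by construction. "Closed" is operationalised strictly:
**watertight** (every boundary edge shared by exactly two boundary faces —
pinched edges disqualify), **single component** (face-adjacency of kept
tetrahedra), and **enclosing every input point** (every point a vertex of
some kept tetrahedron). α\* is found by ascending grid scan, step 0.05 m
over [0.5, 10] m by default — the granularity the field workflow reported;
fully noise-free synthetic scans can defeat the watertightness test through
exactly-degenerate tetrahedra, so simulations keep a nonzero range noise.

Clouds are segmented at empty along-row gaps ≥ 1 m (below a missing tree's
1.35 m slot, above foliage gaps) before the α search; each group is closed
independently and volumes are summed, preventing the shape from bridging a
missing tree's slot. Groups under 20 points are stray returns (noise-lifted
ground or box-edge points): they stay in the point count but carry no
volume.

"Point-cloud density" follows the field convention used alongside these
volumes: the **total point count** of the transect cloud (the published
magnitudes, ~10⁶ per transect, are counts, not per-m³ densities). Volume
deltas are computed from unrounded values and rounded to 2 decimals only at
serialisation — which is why a printed per-row delta can differ from the
difference of the printed volumes by 0.01 m³.

On synthetic transects at the default density, α\* lands near the 0.5 m
bracket floor; sparser or noisier clouds push it up. Published field values
sit near 3 m — whole-transect meshes over ~10⁶-point clouds need junction
tetrahedra far larger than a desk-scale ellipsoid hedge requires — so α\*
should be read as cloud-specific, not transferable.

## Vibration

The working series is the per-sample Euclidean norm of the three axes —
the only reading of a combined "vector sum" that is invariant to device
orientation, which is the stated reason the axes are combined at all. A
windowed-RMS variant is provided for sensitivity analysis. Gravity is not
subtracted by default (the series rests at ~1 g); `remove_baseline`
subtracts the pre-event median. Event detection: spans of magnitude ≥
threshold (default 2 g — above the 1 g baseline, below observed 4–8 g
beating peaks), merging sub-threshold dips shorter than `min_gap`
(default 0.5 s); duration is first-to-last supra-threshold sample; the
event maximum is independent of `min_gap` by construction. The detection
rule and defaults are this package's choice — the field protocol did not
publish one — and both are configurable.

## Fruit metrics

CI and BI are direct formula evaluations. Harvest efficiency expresses
removal as the detached share of total production (so removal % +
left-on-tree % = 100 exactly), and scales the 6.25 m² ground-frame sample
weight linearly to the row footprint; ground loss is reported relative to
total production (the alternative — relative to removed fruit — differs by
< 3% at observed removal rates and is noted in output metadata as a
convention choice).

## Problem sizes

Defaults are chosen so a full synthetic campaign (11 trees, 2 scanners × 2
sides × before/after, ~80 k points per merged cloud) completes in well
under a minute per transect on one core; the bundled tests run the whole
suite, including the end-to-end campaign and the 1000-trial registration
experiment, in about a minute.

## What passing tests do and do not show

The simulator reproduces the acquisition geometry, occlusion structure,
odometry, quantisation and noise scales of the field system, so passing
tests validate the *pipeline*: geometry inversion, alignment, cropping,
volume estimation and event detection. It does not emulate foliage-level
structure (leaves, branches, wind motion), multi-echo returns, intensity,
variable ground, or harvester-specific damage patterns; absolute field
volumes and their seasonal meaning are therefore outside what the synthetic
checks can certify. The published survey tables are bundled for the
arithmetic-level checks (differencing, treatment means), not as
re-derivable quantities — their raw clouds were never deposited.
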