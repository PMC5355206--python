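# Methods

## Survey design model

A down-looking camera at altitude *h* (meters above the seafloor, not depth)
with angular field of view β images a ground footprint *b* = 2*h* tan(β/2).
Imaging sensors are not square, so across-track and along-track fields of
view (and footprints) are treated separately. Overlap requirements are
expressed as a target number of views *n* of every scene point: along track
this fixes the speed *s* = *b*<sub>along</sub>/(*nT*) at frame period *T*;
across track it fixes the trackline spacing *b*<sub>across</sub>/*n*.
*n* is allowed to be non-integer in the solvers — the design equations are
continuous — and is only treated as a count where a count is meant.

A swimmer keeping tension on a line of length *M* unwinding from a fixed
drum of radius *R* traces the involute of a circle. With α the unwound angle
along the drum circumference, the tip sits at *r* = *R*√(1+α²),
φ = α − arctan α; the arc length is *L* = *R*α²/2, the line runs out at
α<sub>M</sub> = *M*/*R* (identically √((r<sub>M</sub>/R)² − 1) with
r<sub>M</sub> = √(M²+R²)), and the duration at speed *s* is *M*²/(2*Rs*).
Successive revolutions are asymptotically spaced by the drum circumference
2π*R*, which is what makes the drum diameter the spacing-design knob.
Line thickness is neglected (the effective drum radius does not shrink as
the line pays out). The "surveyed area" convention is the disc of the
maximum radius, π(M²+R²), which is how the area of a full spiral is usually
quoted; the outermost revolution's footprint extends slightly beyond it.

Coordinates: right-handed x–y plane in meters, pole (the drum's stake) at
the origin, involute starting at (R, 0) and unwinding counter-clockwise.
Handedness is a free choice and is recorded in trajectory metadata. Angles
are radians everywhere in the library; the CLI and config files use degrees,
the field convention.

## Trajectory simulation

Poses are emitted at the camera frame period with constant path speed.
For the spiral this uses the exact arc-length inversion α(t) = √(2st/R);
pose radii therefore satisfy the involute equation to machine precision,
and the frame count is ⌊t<sub>M</sub>/T⌋ + 1. Headings are the path
tangent, which for the involute is simply α (mod 2π). The survey starts at
α = 0 with the tip at the drum surface. Note that *chord* lengths between
consecutive poses are slightly shorter than the arc step s·T — markedly so
near the pole where the curvature radius Rα is small; the sum of chords
converges to M²/(2R) as T → 0 and is within 1% of it at T = 0.5 s for the
reference design.

The lawnmower pattern is a boustrophedon: legs along y at x = i·spacing,
joined by semicircular end turns of radius spacing/2 swum at the same
speed. Turn poses are emitted and flagged `turn` so evaluation can include
or exclude them (default: include; whether turn frames belong in the field
metric is not knowable from the survey description, so both are supported).
Coverage defects are injected per leg over a half-open along-leg interval
(start, end]: either the frames are dropped or the path is displaced
laterally. With the interval start aligned to a frame position a dropped
stretch of width w removes exactly ⌊w/(sT)⌋ poses; for unaligned starts the
count can be one higher. Because legs alternate direction, the along-leg
coordinate of odd legs is mirrored (u = leg_length − y); a spatially
coherent multi-leg hole must mirror its intervals accordingly (the fixture
generator does).

Spoke passes are straight diameters through the survey center at evenly
spaced orientations (k·π/n), sampled at the frame period with time
continuing across passes, concatenable after a spiral.

### Disturbance model

Swell and currents are emulated by stationary AR(1) noise: cross-track
position and altitude each receive e<sub>t</sub> = ρ e<sub>t−1</sub> +
√(1−ρ²)·σ·z<sub>t</sub> with e<sub>0</sub> ~ N(0, σ²), so the stationary
standard deviation is σ exactly. AR(1) is the simplest stationary model
with frame-to-frame correlation; defaults σ_cross = 0.1 m,
σ_altitude = 0.05 m, ρ = 0.9 at 2 Hz give meter-scale swell excursions with
a few-second correlation time. For the spiral the line constrains motion
*outward* only, so the radial perturbation is applied inward (−|e|),
keeping the pose radius at or inside the taut-line radius; lawns and spokes
get signed two-sided cross-track noise. All noise is drawn from a seeded
generator: identical inputs and seed give bit-identical pose tables.

The simulator emulates geometry and timing only. It does not model line
tension dynamics, swimmer kinematics, visibility, lighting, or the image
content that real feature matching depends on — so passing tests show that
the *patterns and the metric* behave as designed, not that any particular
seafloor would yield matchable imagery.

## Link graph and survey-consistency metric

Each pose's footprint is an oriented rectangle (along-track side aligned
with the heading) at the pose's own altitude. Two cameras are *linked* when
their footprint intersection area, divided by the smaller footprint's area,
reaches a threshold — a purely geometric proxy for "enough shared scene to
match features". Normalizing by the smaller area keeps the fraction
meaningful across altitude differences. The default threshold 0.15 is a
deliberately permissive lower bound for matchable overlap; it is exposed as
a parameter. Candidate pairs are pruned with a k-d tree at the footprint
diagonal (beyond which overlap is impossible); pruning cannot change the
result.

The consistency metric: take the median Euclidean length of all links
(midpoint of the two central values for an even count); define the
neighborhood radius as twice that median; for every ordered pair of
cameras within that planar distance record the shortest-path length in
links between them (unweighted BFS); pool the lengths into a histogram
normalized over reachable pairs. Pairs with no connecting path are counted
separately rather than binned at an arbitrary value. Ordered pairs are
pooled — each unordered pair contributes twice, symmetrically — so the
normalized histogram is identical under unordered pooling. Deriving the
radius from the link lengths makes the histogram invariant to uniform
geometric scaling of the survey (footprint size / imaging altitude), which
the tests verify to 1e-9 per bin. Distances use planar (x, y) positions,
appropriate for near-constant-depth surveys.

A healthy survey concentrates mass at path lengths 1–2. Coverage holes —
regions where nearby images lack usable overlap — force detours of three or
more links or leave pairs unreachable. A frame-drop on a *single* leg of a
tightly spaced lawn is bridged laterally by the adjacent legs and does not
degrade the metric; a genuine hole, as seen in field lawn surveys, spans a
region wider than the footprint in both directions, which the fixture
generator reproduces by dropping coincident intervals on two adjacent legs.

## Fixtures and problem sizes

The paired scenario set used by the tests and examples: the reference
spiral (1501 poses, 225 m, 750 s), a swell-disturbed variant, and a
lawnmower survey of the same ~113 m² swath (21 legs x 11.1 m at the 0.51 m
design spacing, ~1660 poses) with and without two 2.5 m x 2 leg frame-drop
holes. These sizes keep a full link-graph build and metric evaluation at a
few seconds each on one CPU while matching the reference design exactly.
On these fixtures the ideal spiral holds all nearby pairs within two links
(mass(1,2) = 1.0) while the holed lawn leaks ~0.15% of its mass to 3–4-link
detours and has maximum path length 4 — the scaled-down analogue of the
spiral-vs-lawn contrast seen in field comparisons, where field lawns (with
far worse spacing control than the simulator's) show much heavier tails.

## Numerical notes and limitations

- Grid operations return raw matrices (NaN marks infeasible cells, e.g. a
  requested area smaller than the drum disc); contouring/plotting is
  presentation-layer and untested by design.
- The quoted 0.81 m/s design speed follows from the *rounded* 1.22 m
  along-track footprint; the unrounded value is 0.8133... ≈ 0.81.
- Median of an even number of link lengths is the midpoint of the two
  central values.
- BFS hop counts are computed with a sparse all-pairs pass (fast, C-level);
  tests cross-check against per-source BFS from an independent graph
  library.
- Degenerate inputs raise `ValueError` early: non-positive altitudes,
  speeds or dimensions, fields of view outside (0, π), unwinding times
  shorter than one frame period, edgeless graphs (median undefined).
- No lens distortion, refraction beyond the effective in-water field of
  view, stereo baselines, feature matching, bundle adjustment or
  reconstruction — the link criterion is geometric overlap only.
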