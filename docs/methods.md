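# Methods

## Coordinate frame and sign convention

All lengths are micrometres, all interface angles degrees. The block frame
is right-handed: X along the positioning-plate border, Y perpendicular to it
through the plate end (the origin), Z along the cutting-forward (specimen
feed) direction. A target's `z` is its depth below the block bottom face,
the face mounted toward the blade and cut first.

At the bench the coordinates are read off in the negative sense (a target is
recorded as (−X_a, −Y_a, −Z_a)); `sectplan` stores positive magnitudes and
keeps the sign convention in the frame. This avoids double-negation bugs and
matches how the run tables print measured magnitudes.

Because the block is mounted bottom-face-out, section images are viewed
mirror-reversed; `mirror_x` reflects across the Y–Z plane through the origin
(X re-referenced as `2·origin_x − x`, Y and Z preserved). The transform is
an involution and preserves pairwise distances. The same convention is
applied symmetrically when rendering sections and when registering them, so
the mirror cancels in a consistent pipeline; the flag is exposed for data
that arrives in only one of the two orientations.

## Planes and the needle-guide construction

The *expected sectioning plane* is the plane through the three target
centers (orthogonal least squares for more than three; identical to the
exact construction at n = 3). Planes are stored as unit normal + point, the
normal oriented with positive Z component; a plane whose normal has no Z
component cannot be realized by the blade and is rejected as degenerate.

With `Z_b = max_i z_i` (the deepest target; ties broken by input order, the
result depending only on the `Z_b` value), the needle at target i has tip
height `2·Z_b − z_i`, protruding from the cut face. In depth coordinates the
tips sit at `z_i − 2·Z_b`, i.e. the *virtual sectioning plane* through the
tips is the expected plane translated `2·Z_b` against the feed direction.
Expected, suppositional (`−Z_b`) and virtual (`−2·Z_b`) planes are therefore
parallel with equal spacing. The minimum tip height is always `Z_b`,
attained by the deepest target; heights are non-negative by construction.

## Advance scale and the cutting-forward distance

A blade plane moves only by translation along the feed axis Z. The advance
origin is the **virtual-plane start position** (blade aligned to the needle
tips): the physical specimen-holder counter zero of the original bench
protocol is not recoverable from the available description, so all advances
the planner reports are relative to this well-defined start. The
suppositional-plane point b′ of the deepest target lies exactly on the
bottom face and is swept at advance `Z_b`; the target plane is reached at
`2·Z_b` (for a tilted plane, advance = perpendicular distance / cos(tilt)).

`cutting_forward_distance(plane, mark, frame, start)` measures the advance
from `start` until the blade passes through the point of the target `plane`
vertically above the 2D `mark` labelled on the block bottom. With the mark
at the deepest target's footprint this is the advance that puts the blade
through *all* target centers simultaneously (they are coplanar by
construction) — the planner's core guarantee, checked by direct point-plane
arithmetic in the tests. Negative advances (mark behind the start plane) and
non-parallel start/target planes are rejected.

## Feasibility

The cryostat can set a cutting angle only within its capacity (default 20°,
configurable; the boundary is inclusive since the stated range is closed).
For an infeasible tilt the verdict suggests a pre-trim wedge of
`tilt − capacity` degrees: trimming the block face at that incline brings
the residual alignment within capacity (e.g. an 81°-to-bottom pre-trim
corresponds to a 9° wedge).

## Sectioning simulation

Targets are spheres (the physical phantoms' target size is not specified;
the default radius of 500 µm gives ~10 positive sections under a 100 µm
survey). A section is represented by its mid-plane: a 7 µm slab is thin
relative to any realistic target, so presence, centroid and cross-section
radius are evaluated there — present iff the perpendicular center-to-plane
distance `d` is below the radius `r`, cross-section radius `sqrt(r² − d²)`,
centroid the orthogonal projection of the center (verified against direct
projection arithmetic).

Two schedules implement the bench protocol:

* `plan_schedule(expected, trim=20, fine=7, margin=1000)` — 20 µm trims
  until `expected − margin` (never crossing it), then 7 µm collected
  sections until `expected + margin`.
* `plan_serial_survey(height, fine=7, interval=100)` — one collected 7 µm
  section per 100 µm of advance, trims filling the gaps. The stated interval
  is interpreted as mid-plane spacing (whether the original protocol counts
  from section start or end is unstated); collected mid-planes sit at
  `k·interval − fine/2`, which introduces a constant sub-grid offset of at
  most half an interval into localized depths — visible as the +46.5 µm in
  the worked example, and well inside the measurement grid's half-width.

Sections are indexed 1-based in advance order, as histologists count them.

## Localization

Per section, the target "central point" is the cross-section disk center
(no intensity weighting). Readings are quantized to the 100 µm grid of the
coordinate paper *at measurement time* (ties round away from zero;
quantization error ≤ grid/2); the section's Z is its mid-plane advance and
is not re-quantized, since it comes from the cut schedule rather than the
image. The center estimate is the unweighted per-axis mean over all
sections where the target appears — peripheral sections with small
cross-sections included, as in the original averaging rule; the estimate is
permutation-invariant over sections. A target never observed is omitted
with a warning.

## Validation statistics

The coefficient of variation uses the sample (n−1) standard deviation of
coordinate magnitudes divided by the absolute mean; the "total" CV is the
unweighted mean of the component CVs. Both conventions were fixed by
verifying that they reproduce every printed per-coordinate and total CV of
the bundled run tables exactly. Accuracy is the Pearson correlation between
pooled foreknown and measured values (scipy.stats.pearsonr); recomputed
from the bundled table it is 0.998681 with N = 36. Expected-vs-actual
cutting-forward distances are compared with Student's paired t-test
(scipy.stats.ttest_rel; df = n−1, two-tailed), giving t = 1.389, df = 11,
p = 0.192 on the bundled 12 pairs. Multiple-comparison procedures (Tukey
HSD) are deliberately left to standard implementations.

## Synthetic phantoms: what they emulate and what they do not

`make_three_target_model()` reproduces the position-known three-target
phantom (Red/Green/Blue at (2000, 1000, 4000) / (8000, 3000, 5000) /
(5000, 7000, 6000) µm, 10 × 10 × 8 mm frame — sized to hold the targets
with margin; expected-plane tilt 17.1°, inside capacity).
`make_random_block(seed=...)` draws reproducible random phantoms for
property sweeps: targets uniform in the frame with margin, pairwise 3D
separation ≥ 2.5 mm, footprint-triangle area ≥ 2 mm², depths in
3–6.5 mm — chosen once as a realistic envelope of the phantom geometry that
keeps the defined plane well-conditioned. Organ presets carry the
organ-scale frames (aortic root 6 × 6 × 5 mm with three valve midpoints,
orbit 12 × 8 × 6 mm with the two optic-nerve endpoints, thorax
25 × 25 × 17 mm with two tracheal points); their target placements are
plausible in-frame geometry fixtures, not anatomical claims.

Measurement noise is Gaussian jitter (default sweeps use sd = 50 µm)
followed by 100 µm grid quantization, applied to section X/Y readings only.
The simulator deliberately omits section compression, tearing, tape
transfer, knife marks, staining variability and photographic distortion;
passing tests demonstrate the *geometric* soundness of the planning chain
under reading noise, not robustness to those physical artifacts, nor to
between-animal differences between data-out and data-in blocks.

End-to-end validation (also run by `scripts/acceptance.py`): 200 seeded
random blocks planned from true centers put every target within half a
section thickness (3.5 µm) of the blade plane; 100 seeded
localize-plan-cut round trips with radius-250 µm targets under grid +
jitter noise are scored on whether a single delivered section (the
collected section nearest the expected advance) contains all three targets.
Problem sizes (200/100 runs, ~80-section surveys) were chosen as the
smallest sweeps that exercise the full geometry envelope; both complete in
seconds.

## Numerical choices

Absolute tolerance for point/plane predicates: 1e-6 µm; unit-normal
tolerance 1e-9; plane-parallelism tolerance 1e-6 rad. Degenerate inputs
(collinear or coincident targets, vertical planes, zero-variance
statistics, zero-mean CVs) raise typed exceptions rather than returning
NaNs. Outputs carry a provenance block (version, config hash, seed) and no
timestamps, so identical inputs give byte-identical files.

## Known limitations

* The planner assumes the data-in block is geometrically identical to the
  data-out block; biological pairing error is outside the model.
* Targets are spheres; elongated structures are represented by their
  endpoint/midpoint landmarks only.
* The advance scale is defined relative to the virtual-plane start; absolute
  specimen-holder readings from other protocols must be re-referenced.
* Blocks larger than the cryostat envelope (~25 mm cube) and section
  thicknesses below 5 µm are physically out of range for the instrument the
  protocol was designed around, though the geometry itself has no such limit.
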