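# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer should know about.

## DS-TWR ranging

Timestamps are continuous seconds (real numbers), not radio tick counts;
the estimator is therefore exact by the algebraic identity

((2τ+Da)(2τ+Dt) − Da·Dt) / (4τ + 2Da + 2Dt) = τ

for time of flight τ and reply delays Da (anchor), Dt (tag) under ideal
clocks, and the implementation is tested against that identity to 1e-9 m.
The anchor-side timestamp roles are Ti1 = poll received, Ti2 = response
transmitted, Ti3 = final received — the only assignment under which the
estimator cancels both reply delays, which we verified symbolically before
adopting it. A clock running at rate (1+e) biases the estimate; the bias
grows monotonically in |e| (property-tested over ±50 ppm) and its
distance-dependent residue is what the calibration network removes.

The interval sum in the denominator equals (T4−T0) + (Ti3−Ti1), so it is
strictly positive for any exchange that satisfies the ordering
invariants; the degenerate-exchange error is defensive. Negative distance
estimates (possible under heavy noise, since the numerator may go
negative) are clamped to zero and flagged rather than raised — the
downstream least-squares solver tolerates them.

Speed of light: 299,792,458 m/s exactly.

## Range-error calibration

Architecture: 1 input → h tanh hidden units → 1 linear output. This is
the smallest faithful three-layer topology; h defaults to 6 and is
selected in practice by sweeping 4–9 and taking the width with the lowest
held-out RMSE (ties to the smaller width, favouring the simpler model).
Input and target are min–max normalised to [−1, 1] — necessary for
stable gradient descent when distances span 20 m.

Optimiser: full-batch gradient descent with classical momentum and an
adaptive step size (the variable-learning-rate backprop heuristic):
after each epoch the step is accepted and the rate grown by `lr_up`
(1.05) if the loss grew by less than `max_error_growth` (4%), otherwise
the step is rejected, the rate shrunk by `lr_down` (0.7) and the
momentum buffer cleared. Plain fixed-rate gradient descent proved
unreliable on this problem — at small rates it fails to converge within
a practical epoch budget, at large ones it diverges, and no single rate
works across weight initialisations — while the adaptive variant
converges robustly from any tested seed. Defaults: learning_rate 0.1,
momentum 0.9, max_epochs 5000, tolerance 1e-9 with a 200-epoch patience
window (single-epoch improvement is noisy under adaptive stepping), seed
0. Training raises a divergence error naming the learning rate if the
loss ever leaves the finite range.

The corrector is shared across anchors (a single static sweep trains it);
its input is the raw DS-TWR distance alone. Predictions are clamped at
zero. Models persist as JSON (weights, normalisation, metadata).

## Trilateration

Subtracting the last circle equation from the others gives the linear
system 2(x_K−x_i)x + 2(y_K−y_i)y = d_i²−d_K² + x_K²−x_i² + y_K²−y_i²,
solved by `numpy.linalg.lstsq` — exact for three non-collinear anchors
with consistent distances, well-defined under noise, and unchanged for
more than three anchors. On noisy instances the solution agrees with a
brute-force grid minimiser of the nonlinear range residual to grid
resolution (the linearisation error is second-order in the noise).
Collinearity is rejected when the smallest singular value of the centred
anchor matrix is below 1e-9 of the largest. Positioning is strictly 2-D;
no Z coordinate is modelled, so anchor and tag heights are assumed
coplanar. Each fix carries the Euclidean norm of its per-anchor range
residuals as a quality indicator.

RMSE conventions: `rmse_1d` for ranging (scalar differences), `rmse_2d`
for positions (per-point squared error is the squared planar distance).
Both are symmetric in their arguments.

## Image-to-world registration

The homography is estimated by the direct linear transform: with c33
fixed to 1, the four correspondences give an 8×8 linear system solved
exactly. Fixing c33 excludes the (irrelevant for floor-plane mappings)
configurations where the true c33 is zero. Pixel convention: origin
top-left, x right, y down, continuous coordinates. `z` in the homogeneous
triple is always 1. The scale (pixels per cm, default 30) plus an
optional world-frame offset converts rectified pixels to barn metres; the
four destination points may equally be declared directly in barn
centimetres, which is how the simulator anchors its arena. Points mapping
to the line at infinity (|w| < 1e-12) raise a horizon error. Whole-image
warping is deliberately absent: the pipeline transforms points, not
rasters.

## Identity association

Candidate gate: world distance between fix and detection centre ≤ margin
(default 1.4 m) AND the fix lies inside the detection's world-mapped
footprint (boundary counts as inside; shapely point-in-polygon). The
margin absorbs the 1.2 m head-to-body-centre offset plus posture
variation without attempting to subtract the offset directionally — a
single fix carries no heading information. The footprint reading of "the
range must stay within the detected box" is the default; the alternative
reading, distance ≤ the footprint's longer side, is selectable
(`containment="box-size"`).

Resolution is greedy nearest-first, which is optimal for the
well-separated scenes this system targets; Hungarian assignment
(`method="optimal"`) is available for dense scenes. Temporal pairing
uses, per image, each tag's fix nearest the image timestamp within a
window (default 2.5 s, half the 5 s ranging interval); without image
timestamps all fixes are eligible.

A tie between two tags and one detection is broken by distance (nearest
candidate pair first); exact ties fall back to list order.

## Scene simulator

What it emulates: a 12 m × 9 m pen with three non-collinear anchors; an
oblique camera whose model *is* the ground-plane homography (detections
are drawn in world coordinates and mapped into the 900×780 px image
through its inverse); adult cows of 2.5 m length and 1.0 m width placed
uniformly with rejection until pairwise body-centre separations reach
`min_separation_m` (3.0 m default), random headings, head tags offset
1.2 m along the heading; one DS-TWR exchange per tagged cow per frame,
frames 5 s apart, tags staggered 0.1 s within a round.

Clock and noise model: per-device rate error (default 10 ppm tag and
anchor), additive Gaussian jitter on the three receive timestamps
(default 1.1e-10 s, which propagates to ≈2 cm of ranging noise — the
linearised propagation gain is √(1/4 + ((τ+Dt)/S)² + ((τ+Da)/S)²) with S
the interval sum, verified against Monte-Carlo), and an affine
systematic range bias (default slope 1.002, intercept 0.15 m, giving the
~0.17 m uncorrected ranging RMSE the corrector is meant to remove). The
calibration sweep holds 10 repeated measurements at each metre from 1 to
20 m (200 pairs).

Detection boxes are the world-frame hull of the animal — torso rectangle
plus the head region in front (head offset + 0.25 m head radius) —
mapped through the inverse homography, axis-aligned in pixels, with
Gaussian corner jitter (2 px default). Enclosing the head matters: a
detector's box contains the whole animal, and the association gate tests
whether the head-tag fix falls inside it.

Not emulated: photorealistic imagery, occlusion, motion within a frame,
multipath/NLOS radio propagation, calf-sized animals, battery effects,
anchor height (everything is coplanar). Passing the end-to-end suite
therefore shows the fusion logic is correct under the stated geometric
and noise conditions, not that any particular detector or radio performs
to spec in a real barn.

Determinism: one seeded generator per scene; the same seed reproduces
byte-identical output files; the seed is recorded in the output manifest.

## Numerical and formatting choices

- Ranging logs are written at %.17g so nanosecond-scale intervals
  round-trip exactly; fix/detection CSVs use 6/4 decimals.
- Report tables round to 3 decimals in metres; machine outputs keep full
  precision.
- Anchor clock offsets are supported (`anchor_clock_offset_s`) but
  default to 0: DS-TWR is insensitive to them, and a large offset only
  costs floating-point resolution in the timestamp differences.
- Problem sizes in the validation harness (1000 random ranging/geometry
  draws, 10 calibration seeds, 20 end-to-end scenes) were chosen as the
  smallest suites whose worst-case statistics are stable across seeds.

## Known limitations

- The association rule assumes at most one tag per detection footprint;
  two cows within one margin of the same box can swap under greedy
  matching (use `method="optimal"` and tighter margins in dense pens).
- The calibration network extrapolates poorly outside the 1–20 m training
  span; predictions there are bounded (tanh saturation) but unvalidated.
- The homography-only camera model cannot represent animals' height above
  the floor plane; box centres of tall subjects project with a systematic
  forward shift a real deployment would need to calibrate.
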