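# uwbid — UWB + vision fusion for individual livestock identification

Camera-based monitoring of dairy cows can detect *a* cow, but not *which*
cow: visually similar animals defeat appearance-based re-identification.
`uwbid` fuses two independent sensing channels to close that gap — an
ultra-wideband (UWB) radio tag worn on each cow's head, localised against
fixed anchors, and bounding-box detections from an external object
detector — so each detected animal can be labelled with its farm-registry
code.

It is written for researchers and engineers in precision livestock
farming who have (a) raw UWB ranging logs, (b) anchor positions, (c)
per-image detection files, and (d) a handful of camera calibration
points, and want reproducible identity assignments plus the accuracy
numbers to report. A full synthetic-scene simulator with ground truth is
included, so every stage can be exercised and validated without hardware.

## The method

**Ranging.** Tag–anchor distances come from double-sided two-way ranging
(DS-TWR). One exchange yields six timestamps — poll transmit `T0`,
response receive `Ti`, final transmit `T4` on the tag's clock; poll
receive `Ti1`, response transmit `Ti2`, final receive `Ti3` on anchor
*i*'s clock — and the time of flight

```
tof = [ (Ti−T0)(Ti3−Ti2) − (Ti2−Ti1)(T4−Ti) ]
      / [ (Ti−T0) + (Ti3−Ti2) + (Ti2−Ti1) + (T4−Ti) ],      d_i = c · tof
```

which cancels both devices' reply delays exactly and suppresses
first-order clock offset, so no synchronisation is needed.

**Range calibration.** Residual systematic error (crystal drift, antenna
delay) is removed by a 1-input/1-output feed-forward network with one
tanh hidden layer, trained by backpropagation gradient descent on a
static sweep of (measured, true) pairs from 1 to 20 m. The hidden width
is selected by a 4–9 node sweep on a 70/30 train/test split.

**Trilateration.** With anchors at known `(x_i, y_i)`, the circle system
`‖p − a_i‖² = d_i²` is linearised by subtracting the last equation and
solved by least squares for the planar tag position `p = (x, y)`.

**Image registration.** Four pixel↔world point correspondences (no three
collinear) determine a 3×3 homography `C` with `c33 = 1`; image points
map through `(u, v, w) = C·(x, y, 1)` and perspective division, then a
pixels-per-centimetre scale converts rectified pixels to metres.

**Association.** The tag gives the cow's *head* position; a detection's
box centre stands in for the *body centre* (≈1.2 m apart in an adult
cow). A (tag, detection) pair is a candidate when their world distance is
within a margin (default 1.4 m) **and** the fix lies inside the box's
world-mapped footprint; candidates are resolved one-to-one, nearest
first. Accuracy is reported as the planar RMSE

```
RMSE = sqrt( (1/n) Σ_i [ (x_i − x̂_i)² + (y_i − ŷ_i)² ] )
```

## Worked example

Simulate a 12 m × 9 m pen with two cows, one of them tagged; train the
range corrector on a simulated 1–20 m sweep; run identification:

```sh
$ uwbid simulate --out scene --seed 7 --n-cows 2 --n-tagged 1
scene written to scene

$ uwbid calibrate --out model.json --seed 7
 hidden_nodes  train_rmse_m  test_rmse_m
            4      0.020138     0.019113
            5      0.019157     0.019332
            6      0.039620     0.035014
            7      0.020774     0.018125
            8      0.020719     0.019730
            9      0.021053     0.020044
selected hidden size: 7
train RMSE 0.0208 m, test RMSE 0.0181 m -> model.json

$ uwbid identify --scene scene --model model.json --out run
1 assignments across 1 images -> run
```

The sweep table shows held-out ranging RMSE per hidden width — about
2 cm after correction, down from the ~0.17 m uncorrected systematic
error. The run directory contains per-stage intermediates plus one JSON
per image; here the tagged cow was pinned to its detection 1.11 m from
the box centre (the head-to-body offset), and the untagged cow is
correctly reported unmatched:

```json
{
 "image_id": "frame_0000",
 "assignments": [
  {"cow_code": "COW001",
   "bbox_px": [446.9, 464.2, 567.2, 687.6],
   "world_xy_m": [7.153, 7.168],
   "distance_m": 1.108}
 ],
 "unmatched_tags": [],
 "unmatched_detections": [1]
}
```

Other subcommands: `locate` (fixes from a ranging log), `register`
(print the homography), `evaluate` (before/after RMSE table),
`show-config` (simulator defaults).

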