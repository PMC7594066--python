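# leafscan

3D localization of plant leaves from a single camera moved in a straight
line — detection grouping plus motion-parallax depth estimation, with a
synthetic scan simulator for desk-scale validation.

## The problem

Leaf-level phenotyping (e.g. positioning a chemical sensor on a leaf)
needs the 3D position of every leaf of a potted plant. Depth cameras
struggle with foliage: infrared meshes wash out under ambient light,
time-of-flight sensors average over a wide cone, and stereo block matching
fails on many small, similar, overlapping leaves. An alternative needs only
a single ordinary camera on a linear actuator: take N images at equally
spaced positions along a line, run an object detector on each image, and
turn the per-image bounding boxes into per-leaf 3D positions. `leafscan`
implements everything downstream of the detector, with the detector itself
replaced by either real detection files (COCO-style JSON or CSV) or a
built-in simulator.

## The method

**Grouping.** Detections of the same leaf in consecutive images are linked
with the match probability

    P = 1 / (ks·Bs + kp·Bp)

where `Bs` is the summed absolute width/height difference of the two boxes
and `Bp` the absolute difference of their centres on the axis *transverse*
to the camera motion (the along-motion drift is the parallax signal, so it
is not penalized). Each detection in image k greedily inherits the leaf ID
of its best match in image k−1 if `P` exceeds a threshold, otherwise it
starts a new leaf; duplicate claims within an image are resolved against
the track's most recent detection. Post-processing removes detections far
off a track's straight-line motion fit, bridges tracks split by missed
detections via linear extrapolation, and drops tracks too short to carry a
depth estimate.

**Depth and position.** A leaf at depth `D` below the camera drifts `px`
pixels per camera step `cx` (mm); the two are related by the calibrated
power law

    D = (px / (a·cx))^b        (bench-calibrated: a = 381, b = −0.95)

fitted in log-log space from a two-point calibration bench. Given the
depth, a pixel offset `pd` from the image centre converts to a metric
offset through the angular model

    Ld = D · tan(asin(pd · sin φ / pm))

with `φ` the half field-of-view angle and `pm` the half frame extent in
pixels. Combining both axes and the known camera position per image turns
each track into an (x, y, depth) estimate in mm.

**Simulator.** Leaves are planar rectangles parallel to the image plane,
projected corner-wise through the exact inverse of the angular model, with
Gaussian box-coordinate noise, a per-image detection probability, an
occlusion rule (a leaf is missed when its projected centre falls inside a
shallower leaf's box), and Poisson false positives — every detection
carries a ground-truth label so grouping and positioning can be scored.

## Worked example

```sh
python examples/01_simulate_and_reconstruct.py
```

```
rendered 40 detections over 8 images
grouping: precision=1.00 recall=1.00, 5/5 leaves recovered

leaf        true (x, y, D) mm        estimate (x, y, D) mm  err mm
   0 (  11.88,  -36.00,  225.0)   (  11.87,  -35.95,  225.2)   0.221
   1 (  12.37,  -18.00,  150.0)   (  12.36,  -17.88,  150.3)   0.290
   2 (  11.99,    0.00,  300.0)   (  11.98,    0.00,  300.6)   0.558
   3 (   9.39,   18.00,  187.5)   (   9.40,   17.95,  187.8)   0.291
   4 (  10.52,   36.00,  262.5)   (  10.52,   35.96,  263.0)   0.489

mean 3D error: 0.370 mm (depth RMS 0.387 mm)
```

Five synthetic leaves at depths 150–300 mm are scanned noise-free, grouped
perfectly, and recovered to sub-millimetre accuracy with a camera
calibrated from the simulated bench — the noise-free pipeline is exact up
to the projection model's small-angle curvature. The other examples cover
the calibration fit (`02`), grouping on a dense 18-leaf artificial plant
with occlusion (`03`, typically 12–17 of 18 leaves recovered, median 13),
and the depth-error pixel budget (`04`: with the step that makes 20 mm of
depth error cost 15 px at 150 mm depth, the same error costs only 4 px at
300 mm).

The same stages are available as a CLI:

```sh
leafscan simulate --seed 3 --output dets.json --ground-truth truth.csv --scene scene.json
leafscan calibrate bench.csv --output camera.yaml
leafscan reconstruct --input dets.json --ground-truth truth.csv --output pos.csv
leafscan evaluate pos.csv scene.json
```

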