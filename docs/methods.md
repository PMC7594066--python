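# Methods

## Scan model and coordinate conventions

A single downward-facing camera is translated along a straight horizontal
line, taking one image every `step_mm` (the camera step, written `cx`).
The world frame has its origin on the first camera position's optical axis:
world x is the scan axis (camera i sits at `x = i·step_mm`), world y the
transverse horizontal axis, and depth `D > 0` is the distance below the
camera plane. Pixels are 0-based, origin top-left, x right, y down; boxes
are anchored at their top-left corner. The image centre is `(image_w/2,
image_h/2)` — (320, 240) for the default 640×480 frame — so the half frame
extents `pm` are exactly `(image_w/2, image_h/2)` pixels, matching the
definition of `pm` as "pixels between centre and edge" used by the angular
offset model.

## Detection grouping

Associating detections across images is tracking-by-detection with a
one-term motion model: under linear camera motion a leaf's image drifts
along the motion axis only, so two detections of one leaf should agree in
box size and in transverse centre position. The match score between
detections is

    P = 1 / (ks·Bs + kp·Bp)

with `Bs = |Δw| + |Δh|`, `Bp = |Δ transverse centre|`, and per-pixel gains
`ks`, `kp`. `P` is a scoring heuristic, not a calibrated probability; only
its ordering and one threshold matter. Implementation note: orderings and
the threshold are evaluated on the *denominator* (`accept ⇔ ks·Bs + kp·Bp
< 1/P_thresh`), so the perfect-match case `Bs = Bp = 0` (`P = ∞`) needs no
float special-casing.

Defaults `ks = kp = 1` and `P_thresh = 1/60`: only the gains' ratio and
their product with the threshold are identifiable, so a single pixel scale
is used — a pair is accepted when its combined size-plus-transverse
mismatch is below 60 px on a 640×480 frame. All three are configurable.

The sweep is greedy and causal: image-0 detections seed fresh leaf IDs
(one leaf cannot appear twice in an image); each detection of image k
takes the ID of its best-scoring image-(k−1) detection if above threshold,
else a fresh ID. When two detections of one image claim the same ID, the
claimant scoring best against the track's most recent prior detection
keeps it (nearest image = least extrapolation) and the rest get fresh IDs;
score ties break to the lower detection ID. Permuting detections within an
image changes nothing else.

Post-processing, in order:

1. **Outlier removal.** Per track with ≥ 3 detections, fit both centre
   coordinates linearly against image index and iteratively drop the worst
   detection while its Euclidean residual exceeds `outlier_tol_px`
   (default 15 px).
2. **Gap bridging.** Two tracks with disjoint image ranges separated by at
   most `max_gap` missing images (default 2) merge when the linear fit of
   one, extrapolated to the other's nearest image, lands within
   `merge_tol_px` (default 15 px) of the detection centre there and the
   mean box-size difference is within the `Bs` the threshold would accept.
   Candidates are processed in order of increasing extrapolation distance,
   to a fixed point. Two single-detection tracks cannot be bridged (no
   side has a slope); if only one side has ≥ 2 detections its line is
   extrapolated toward the other. Fully general non-consecutive grouping
   is out of scope (combinatorially expensive); linear-extrapolation
   bridging covers the short occlusion gaps that actually occur.
3. **Filtering.** Tracks shorter than `min_track_len` (default 2 — the
   minimum for any parallax) are dropped.

The outlier and merge tolerances are this package's own operational
definitions; the reference procedure states only that missed detections
are bridged and outliers removed.

## Depth from parallax

A track's per-step parallax is the absolute least-squares slope of its
motion-axis centre versus image index — identical to the mean consecutive
difference when no image is missing, and correctly normalized across
bridged gaps. Depth follows from the power law

    D = (px / (a·cx))^b

with constants from a two-point calibration: points a known distance apart
(the spacing stands in for `cx` — two points seen from one position are
geometrically one point seen from two positions) are imaged at known
depths and `log(px/cx)` is regressed on `log D`; the slope is `1/b` and
the intercept `log a`. The regression runs from the exactly-known depths
to the noisy measured separations — the reverse direction would put the
measurement noise in the regressor, attenuating `b` and biasing `a`
upward. Rows are weighted by their separation because additive pixel noise
is relatively much larger on small separations. `a` extrapolates the fit
to `log D = 0`, so it is only well determined when the calibration depths
span a wide range; the bench constants `a = 381`, `b = −0.95` are close to
an ideal pinhole (`a = focal length in px`, `b = −1`).

Lateral position uses the angular model

    Ld = sign(pd) · D · tan(asin(|pd|·sin φ / pm))

per image axis, with `φ` the half view angle (defaults: `φ_x = 28°`, `φ_y`
from the 4:3 aspect under a rectilinear assumption, both configurable —
the physical camera's angle is not documented) and `pd` the signed pixel
offset of the box centre from the image centre. Each detection contributes
`camera position + offsets`; the reported (x, y) is the mean over the
track, and `residual_px` (RMS of the motion-axis linear fit) is kept as a
dispersion diagnostic. Centres that noise pushes nominally outside the
frame are clipped to the frame edge before the arcsin. Depth is reported
positive (below the camera); plotting uses `z = −D`.

## Small-angle validity envelope

The power law maps one number (`px` per step) to depth, but the true
projection `pd = pm·sin(atan(L/D))/sin φ` is nonlinear in the offset `L`.
For a box centre the measured slope is attenuated by roughly
`(1 + u²)^(−3/2)` at angular offset `u = L/D`, and the box's own half-width
contributes to the effective `u`; since `D ∝ px^b` with `b ≈ −1`, the
relative depth bias is ≈ `1.5·⟨u²⟩` (weighted by the regression's
emphasis on extreme frames). Numerically: a 40–60 mm leaf on a 70 mm
traverse at `D = 150 mm` carries a bias of several percent (+3.5 % to
+6.6 % observed noise-free), while 20–30 mm leaves on a 21 mm traverse
stay below ~1 %. The noise-free oracle scenes therefore use the latter
geometry — the check probes the implementation, not the model's documented
curvature error — and the noisy accuracy trial deliberately uses the
former, where the bias contributes the same positive depth-error skew the
physical bench showed.

## Simulator

Leaves are planar axis-aligned rectangles parallel to the image plane
(the method's own flat-leaf assumption); the four box corners are
projected exactly through the inverse of the lateral-offset model, so
simulation and reconstruction share one geometry and the noise-free round
trip is an oracle. The detector emulation has four knobs: independent
Gaussian noise (`sigma_px`) on each box coordinate; a per-image detection
probability (default 0.69, the observed probability of re-detecting a leaf
in another image); an occlusion rule — a leaf is missed in an image when
its projected centre lies inside a shallower leaf's projected box (the
reference observations report only *that* obstructed leaves are missed,
not a model; centre-in-box is the simplest rule with the right phenome-
nology); and Poisson false positives with uniform boxes. False positives
carry unique negative ground-truth labels so they can never form "true"
pairs. One private RNG per render; unit noise draws are consumed whether
or not a detection is kept, so renders differing only in `sigma_px` see
identical detection patterns — noise sweeps are paired comparisons.

What the simulator does **not** model: perspective foreshortening beyond
corner projection, leaf tilt/curvature (boxes never change shape with
viewing angle except through projection), lens distortion, lighting, and
detector behaviour correlated across frames or with appearance. Passing
tests therefore validate the grouping/geometry pipeline under its own
assumptions, not detector robustness on real plants.

### Artificial-plant generator

The dense-plant stress test places 18 leaves with lengths uniform in
55–115 mm (second extent 0.5–0.9 of the length), depths uniform in
90–340 mm, and horizontal positions uniform over a 250 mm scan area,
rejection-sampling size, depth and position *jointly* until each leaf
(a) fits fully inside the frame in ≥ 2 of the 9 scan images and (b) keeps
at least one unoccluded image without fully hiding any leaf placed before
it. The conditioning mirrors how the physical reference plant was built
and labelled: only leaves visible somewhere in the scan exist as labels at
all (a 115 mm leaf 90 mm under a 28° half-angle camera can never fit the
frame), while leaves visible in only one or two images remain — exactly
the ones the pipeline may fail to localize. Scan geometry: 9 positions at
31.25 mm steps (250 mm of travel). Under these conditions the pipeline
recovers a usable track for 12–17 of 18 leaves (median 13 over seeds 0–4),
with the occlusion-imposed ceiling at 13–17.

### Accuracy-trial conditions

The simulated analogue of the printed-leaf bench places 30 leaves in 10
scenes of three (as on the physical bench), depths uniform in 150–300 mm,
scanned in 8 images at a 10 mm step with a self-consistently calibrated
camera. The bench used a single clear printed leaf precisely so that box
placement — not missed detections — limited accuracy, so `detect_prob = 1`
and all error enters as box jitter; `sigma_px = 8` is calibrated so the
depth errors span roughly −20…+40 mm (observed −35…+47, 2.5/97.5
percentiles −21/+42), with depth RMS ≈ 18 mm against transverse RMS
≈ 2 mm and a mean total 3D error ≈ 15 mm. These are property-level
analogues: the physical 20/52/8 mm figures include hardware and detector
effects no desk-scale simulation reproduces.

Self-consistent calibrations for simulator experiments use spacings
{10, 20, 40} mm at depths {150, 200, 250, 300} mm — matched to the camera
steps the scans use, since the spacing plays the role of `cx`; the
physical bench grid {25, 50, 100} mm remains the default of
`make_calibration_table`.

## Numerical and degenerate-input choices

- Score comparisons use denominators; exact ties break to the lower
  detection ID everywhere, making the pipeline deterministic given inputs.
- `pixels_per_step = 0` (no parallax) is an error for direct calls and a
  skip inside `reconstruct` (a stationary cluster, e.g. repeated false
  positives, has no depth).
- Tracks of length 2 are fit exactly (zero residual) and are never
  outlier-pruned; pruning stops at 3 detections.
- Calibration requires ≥ 2 distinct depths and a negative fitted exponent.
- Empty inputs flow through: empty series → no tracks → no positions.
- Seeds: every stochastic component takes an explicit seed; derived seeds
  stay below 2³¹.

## Known limitations

- The depth model's curvature bias (above) makes depth estimates of large
  and/or off-axis leaves systematically high by a few percent; a
  calibration with per-angle terms or an exact-projection inversion would
  remove it but is deliberately out of scope (the power law *is* the
  method).
- Grouping has no appearance model; leaves closer than the noise scale in
  transverse position and size can swap identities, which the threshold
  and post-processing mitigate but cannot exclude.
- The evaluation matches tracks to true leaves by plurality label; a track
  that is half one leaf and half another counts for neither.
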