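"""How many pixels of detection error produce 20 mm of depth error?

Inverts the calibrated depth power law px(D) = a*cx*D^(1/b) (a=381,
b=-0.95).  The camera step cx is fixed so that a +20 mm depth change at
150 mm depth corresponds to 15 px of separation error; the same +20 mm at
300 mm then costs only ~4 px.  Deeper leaves drift fewer pixels per camera
step, so each pixel of detector error buys more depth error — depth
estimates degrade with distance even under constant pixel noise.
"""

from leafscan.experiments import sensitivity_pixels
from leafscan.geometry import CameraModel, depth_error_sensitivity

out = sensitivity_pixels()
print(f"camera step solving the 15 px budget at 150 mm: cx = {out['cx_mm']:.2f} mm")
print(f"pixel budget for +20 mm at 300 mm: {out['px_error']:.2f} px "
      f"(rounded: {out['px_error_rounded']:.0f})\n")

model = CameraModel()
print(f"{'depth (mm)':>10} {'px per +20 mm':>14}")
for depth in (150, 200, 250, 300):
    px = depth_error_sensitivity(depth, 20.0, out["cx_mm"], model)
    print(f"{depth:>10} {px:>14.2f}")
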