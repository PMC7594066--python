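"""Calibrate the power-law depth model from a simulated two-point bench.

Two points a known distance apart (25/50/100 mm) are imaged at known depths;
the pixel separation between them plays the role of the per-step parallax.
A log-log least-squares fit gives the constants (a, b) of

    D = (px / (a * cx)) ** b

The fitted exponent lands close to the ideal pinhole value -1; `a` is
roughly the focal length in pixels of the simulated camera.  The second
block fits data generated directly from the bench-measured constants
(a=381, b=-0.95) and recovers them to machine precision — the fit itself is
exact on noise-free power-law data.
"""

import math

from leafscan.geometry import CalibrationTable, default_camera, fit_power_calibration
from leafscan.simulate import make_calibration_table

camera = default_camera()  # 28 deg half-angle, 640x480
table = make_calibration_table(camera, depths=[150, 200, 250, 300],
                               spacings=[25, 50, 100])
a, b = fit_power_calibration(table)
print(f"simulated bench ({len(table)} rows): a = {a:.2f}, b = {b:.4f}")
print(f"(pinhole reference: a = pm/sin(phi) = "
      f"{camera.pm_x / math.sin(camera.phi_x):.2f}, b = -1)\n")

a0, b0 = 381.0, -0.95
rows_d, rows_sep, rows_s = [], [], []
for d in (150, 200, 250, 300):
    for s in (25, 50, 100):
        rows_d.append(d)
        rows_s.append(s)
        rows_sep.append(a0 * s * d ** (1 / b0))
fa, fb = fit_power_calibration(CalibrationTable(rows_d, rows_sep, rows_s))
print(f"power-law data generated with a=381, b=-0.95 -> fit a = {fa:.6f}, b = {fb:.6f}")
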