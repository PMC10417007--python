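"""Vessel tortuosity index of analytic curves.

Builds a straight line, a circular arc and two sinusoids, computes the
tortuosity metrics for each, and prints them.  The straight line scores
exactly zero; the constant-curvature arc scores ~zero because its
tangent angle turns at a constant rate; the sinusoids score higher the
more turns they pack along the same chord.
"""

import numpy as np

from octavti import compute_vti, make_curve

curves = {
    "straight line": make_curve("line", {"x0": 0, "y0": 0, "x1": 500, "y1": 0}, 1000),
    "semicircular arc (r=80)": make_curve("circular_arc", {"radius": 80, "angle": np.pi}, 2000),
    "sine, 2 periods": make_curve("sine", {"amplitude": 25, "period": 250, "n_periods": 2}, 4000),
    "sine, 4 periods": make_curve("sine", {"amplitude": 25, "period": 125, "n_periods": 4}, 4000),
}

print(f"{'curve':28s} {'L_A':>8s} {'L_C':>8s} {'N':>3s} {'SD_theta':>9s} {'M':>7s} {'VTI':>7s}")
for name, curve in curves.items():
    m = compute_vti(curve.points)
    print(
        f"{name:28s} {m.arc_length:8.1f} {m.chord_length:8.1f} {m.n_critical:3d} "
        f"{m.sd_theta:9.4f} {m.mean_piece_ratio:7.4f} {m.vti:7.4f}"
    )

print(
    "\nL_A/L_C is the arc/chord ratio, N the number of critical points of the\n"
    "chord-framed centerline, SD_theta the spread of tangent-angle steps in\n"
    "degrees, M the mean arc/chord ratio between critical points, and\n"
    "VTI = 0.1 * M * N * SD_theta * (L_A/L_C)."
)
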