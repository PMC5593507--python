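"""From paired 340/380 nm image stacks to ratio traces and cell sizes.

Renders synthetic 16-bit stacks for two elliptical cells, recomputes the
ratio stack with background subtraction and denominator thresholding,
extracts the ROI-mean traces, and measures Feret's diameter of each ROI.
"""

import numpy as np

from trpquant import (
    CellEllipse,
    CellTrace,
    FieldGeometry,
    RoiDefinition,
    compute_ratio_stack,
    extract_roi_trace,
    feret_diameter,
    render_image_stacks,
)

time = np.arange(30) * 5.0
flat = CellTrace("flat", time, np.full(30, 0.8))
burst = CellTrace("burst", time, np.where((time >= 50) & (time <= 100), 1.6, 0.8))

geometry = [
    CellEllipse("flat", 30.0, 32.0, 10.0, 7.0, 0.4),
    CellEllipse("burst", 85.0, 60.0, 12.0, 8.0, 1.2),
]
stack340, stack380, roi_table = render_image_stacks(
    [flat, burst], geometry, FieldGeometry(128, 96, um_per_px=1.0)
)
print(f"stacks: {stack340.shape} uint16, 340 and 380 nm channels")

ratio = compute_ratio_stack(
    stack340, stack380, background_method=100.0, intensity_threshold=50.0
)
for ellipse, original in zip(geometry, (flat, burst)):
    roi = RoiDefinition(
        ellipse.roi_id, ellipse.center_x_px, ellipse.center_y_px,
        ellipse.semi_axis_a_px, ellipse.semi_axis_b_px, ellipse.orientation_rad,
    )
    trace = extract_roi_trace(ratio, roi)
    err = np.abs(trace.ratio - original.ratio).max()
    d = feret_diameter(roi, um_per_px=1.0)
    print(f"ROI {roi.roi_id:6s}: peak ratio {np.nanmax(trace.ratio):.3f}, "
          f"max round-trip error {err:.2e}, Feret diameter {d:.1f} um")
print("\nRound-trip errors are bounded by the 16-bit quantization of the")
print("rendered intensities; the Feret diameter equals each ellipse's major")
print("axis (2 x semi-axis a).")
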