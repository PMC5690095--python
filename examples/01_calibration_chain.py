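"""Full EPID dose-calibration chain on simulated inputs.

Builds dark/flood/reference images for the default 512x384 panel, runs the
dark/flood correction, restores the beam horns with the diagonal profile,
establishes the CU scale from the 100 MU 10x10 cm^2 reference, and shows
that the reference itself then reads 1 CU on the central axis.
"""

from epidqa import (
    CalibrationSet,
    SimConfig,
    calibrate_cu,
    central_axis_value,
    dose_calibrate,
    golden_beam_profile,
    make_calibration_inputs,
    process_portal_image,
)

config = SimConfig()
dark, flood, reference = make_calibration_inputs(config)
cal = CalibrationSet(dark=dark, flood=flood, beam_profile=golden_beam_profile(config))

processed = process_portal_image(reference, cal, to_cu=False)
cal = calibrate_cu(processed, cal)
cu_image = dose_calibrate(processed, cal)

print(f"panel: {flood.n_x}x{flood.n_y} px, pitch {flood.pitch_mm:.5f} mm "
      f"({flood.extent_x_cm:.0f}x{flood.extent_y_cm:.0f} cm)")
print(f"CU scale factor: {cal.cu_scale:.6f} (reciprocal of the reference CAX signal)")
print(f"reference central-axis dose: {central_axis_value(cu_image):.9f} CU")
print("-> 1 CU is, by definition, the CAX signal of the processed 100 MU 10x10 delivery.")
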