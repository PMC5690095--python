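"""Derive the 1D diagonal-profile correction and verify it closes the loop.

Uses a controlled simulator (over-response on, every other distortion off):
a 38x28 cm^2 field is measured through the uncorrected chain, the
measured/predicted diagonal ratio is fitted with a 4th-order polynomial to
22 cm, and the resulting correction is compared against the injected
over-response.  The injected curve spans -0.4% to +9.9% over the window.
"""

import numpy as np

from epidqa import SimConfig, correction_factor
from epidqa.experiment import build_scenario_calibration

config = SimConfig(
    backscatter_amplitude=0.0,
    scatter_fraction=0.0,
    sensitivity_amplitude=0.0,
    noise_sigma=0.0,
    dark_level=0.0,
    dark_jitter=0.0,
)
cal, corr = build_scenario_calibration(config, "inhouse_40x30")

r = np.linspace(0.0, 22.0, 441)
injected = config.overresponse_values(r) - 1.0
recovered = correction_factor(corr, r)

print(f"mode {corr.mode}: order {corr.order}, fit 0-{corr.r_fit_max_cm:.0f} cm, "
      f"applied to {corr.r_apply_max_cm:.0f} cm, R^2 = {corr.r_squared:.4f}")
print(f"injected over-response range : {injected.min()*100:+.2f}% .. {injected.max()*100:+.2f}%")
print(f"recovered correction range   : {recovered.min()*100:+.2f}% .. {recovered.max()*100:+.2f}%")
print(f"worst recovery error         : {np.abs(recovered-injected).max()*100:.4f} percentage points")
print("-> the fitted polynomial reproduces the detector's off-axis over-response,")
print("   so dividing it out of the calibration profile cancels the discrepancy.")
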