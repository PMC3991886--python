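"""Native mass and oligomeric state from gel-filtration calibration.

Four standards (29-200 kDa) define a log10(mass)-vs-retention line; a
sample's retention time then reads off its native mass, and the ratio to
the sequence-derived monomer mass calls the assembly state. Bacterial SSBs
are homotetramers, so the ratio should land near 4.
"""

from ssbkit import estimate_native_mass, fit_calibration, oligomer_state
from ssbkit.calibration import retention_for_mass
from ssbkit.synth import generate_calibration

standards = generate_calibration(jitter_min=0.0)
curve = fit_calibration(standards)
print(f"calibration: log10(kDa) = {curve.slope:.3f} * t + {curve.intercept:.2f}"
      f"  (R^2 = {curve.r_squared:.3f})")

# DpsSSB elutes where a 59 kDa particle would; its monomer is 15.6 kDa.
retention = retention_for_mass(curve, 59.0)
estimate = estimate_native_mass(curve, retention)
call = oligomer_state(estimate.mass_kda, 15.6)
print(f"sample at {retention:.1f} min -> native mass {estimate.mass_kda} kDa")
print(f"native/monomer ratio {call.ratio} -> {call.state_label}")
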