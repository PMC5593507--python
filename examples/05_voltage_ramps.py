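"""Analyze a whole-cell voltage-ramp recording of channel inhibition.

Simulates an outwardly rectifying current activated by an agonist and
suppressed to 10% during an inhibitor application, extracts currents at
-80 and +80 mV (after the 15 mV liquid-junction-potential correction),
converts to current densities, applies the minimum-response QC gate and
computes percent inhibition at both potentials.
"""

import numpy as np

from trpquant import (
    RampSimParams,
    baseline_subtract_currents,
    ephys_inhibition,
    extract_currents,
    generate_ramp_recording,
    qc_min_response,
)

params = RampSimParams(
    conductance_ns=4.0, inhibitor_scale=0.1, noise_pa=0.5,
    capacitance_pf=12.0, seed=5,
)
series = generate_ramp_recording(params)
print(f"{len(series.sweep_times)} ramp sweeps, command "
      f"{series.command_voltage_mv[0]:.0f}..{series.command_voltage_mv[-1]:.0f} mV "
      f"(corrected {series.corrected_voltage_mv[0]:.0f}.."
      f"{series.corrected_voltage_mv[-1]:.0f} mV after 15 mV LJP)")

tc = extract_currents(series, (-80.0, 80.0))
tc = baseline_subtract_currents(tc, baseline_window=(0.0, 20.0))
dens = tc.density_pa_pf
peak = np.abs(dens).max(axis=0)
print(f"peak |current density|: {peak[0]:.1f} pA/pF at -80 mV, "
      f"{peak[1]:.1f} pA/pF at +80 mV")

passed = qc_min_response(tc, agonist_window=(30.0, 150.0), direction="inward")
print(f"minimum-response QC (>10 pA inward): {'pass' if passed else 'fail'}")

inh = ephys_inhibition(tc, eval_times=(60.0, 90.0, 140.0))
print(f"inhibition: {inh[-80.0]:.1f}% at -80 mV, {inh[80.0]:.1f}% at +80 mV")
print("Near-identical inhibition at both potentials indicates the block is")
print("voltage-independent, as expected for a G-protein-mediated mechanism.")
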