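"""Measure PFR from short-axis volumetry with parabolic peak fitting.

Volumes at five or six phases around the peak-filling phase (located on the
velocity-mapped series) are differenced into a rate curve; the vertex of a
least-squares parabola through those points gives PFR and peak filling time.
"""

from pfrkit import (PhantomSpec, find_visual_peak, global_indices,
                    make_volume_waveform, pfr_ssfp, render_pc_series,
                    render_ssfp_stack, true_pfr)

spec = PhantomSpec()
truth = true_pfr(make_volume_waveform(spec))

series = render_pc_series(spec)
pc_peak = find_visual_peak(series, series.ground_truth_roi, (26, 51))
stack = render_ssfp_stack(spec, mode="raster")

res = pfr_ssfp(stack, pc_peak)
print(f"peak phase on velocity map : {pc_peak} (of {spec.n_phases_pc})")
print(f"volumetric phase window    : {res.diagnostics['phase_window']}")
print(f"volumes in window (mL)     : "
      + ", ".join(f"{v:.1f}" for v in res.diagnostics['volumes_ml']))
print(f"SSFP PFR                   : {res.pfr:.1f} mL/s at {res.peak_filling_time:.0f} ms")
print(f"true PFR                   : {truth:.1f} mL/s "
      f"(deficit {100 * (truth - res.pfr) / truth:.1f} %)")

gi = global_indices(stack, height_cm=169.5, weight_kg=60.2)
print(f"EDV {gi.edv:.1f} mL, ESV {gi.esv:.1f} mL, EF {gi.ef:.1f} %, "
      f"BSA {gi.bsa:.2f} m^2, EDV/BSA {gi.edv_per_bsa:.1f} mL/m^2")

# The parabola vertex sits a few percent below the true peak: the 40 ms
# acquisition window plus inter-phase differencing smooth the rate curve.
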