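"""Build the synthetic heart and look at its ground truth.

The phantom is a periodic LV volume curve (EDV 150 mL, ESV 65 mL at 62 bpm)
whose filling rate has a known closed-form peak — the quantity both imaging
pathways try to recover.
"""

import numpy as np

from pfrkit import PhantomSpec, make_volume_waveform, temporal_blur, true_pfr

spec = PhantomSpec()
wf = make_volume_waveform(spec)

print(f"RR interval            : {wf.rr_ms:7.1f} ms")
print(f"V(0) = EDV             : {wf(0.0):7.1f} mL")
print(f"min V over cycle = ESV : {wf(np.linspace(0, wf.rr_ms, 20001)).min():7.1f} mL")
print(f"true PFR (ground truth): {true_pfr(wf):7.1f} mL/s at t = {wf.e_peak_ms:.0f} ms")

# the finite acquisition window of a segmented cine scan blurs the peak:
for width in (40.0, 43.2, 100.8):
    blurred = temporal_blur(wf.rate, width)
    peak = blurred(np.linspace(*wf.e_window_ms, 2001)).max()
    print(f"peak of rate blurred over a {width:5.1f} ms window: {peak:6.1f} mL/s "
          f"({100 * (1 - peak / true_pfr(wf)):.1f} % below truth)")

# Longer acquisition windows lose more of the sharp early-filling peak —
# this is why true temporal resolution, not reconstructed phase spacing,
# limits PFR measurement.
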