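"""Method-comparison statistics on simulated paired PFR measurements.

Simulates a small cohort by varying the phantom's stroke volume, measures
PFR with the volumetric and both velocity-encoded pathways, and runs the
comparison suite: regression, Fisher-z CI, Bland-Altman, underestimation.
"""

import numpy as np

from pfrkit import (PhantomSpec, bland_altman, find_visual_peak,
                    linear_regression, pearson_ci, pfr_from_three_phases,
                    pfr_ssfp, relative_underestimation, render_pc_series,
                    render_ssfp_stack)

rng = np.random.default_rng(7)
esvs = rng.uniform(50.0, 80.0, 6)  # six synthetic subjects, EDV fixed

ssfp, temporal = [], []
for i, esv in enumerate(esvs):
    spec = PhantomSpec(esv=float(esv), matrix=96, seed=i)
    series = render_pc_series(spec)
    k = find_visual_peak(series, series.ground_truth_roi, (26, 51))
    temporal.append(pfr_from_three_phases(series, series.ground_truth_roi, k).pfr)
    ssfp.append(pfr_ssfp(render_ssfp_stack(spec, mode="exact"), k).pfr)

ssfp, temporal = np.array(ssfp), np.array(temporal)
reg = linear_regression(ssfp, temporal)
ci = pearson_ci(reg.r, len(ssfp))
ba = bland_altman(temporal, ssfp)
pct, pct_round = relative_underestimation(ssfp.mean(), temporal.mean())

print("subject PFRs (mL/s), volumetric vs velocity-encoded:")
for a, b in zip(ssfp, temporal):
    print(f"  {a:6.1f}  {b:6.1f}")
print(f"regression: slope {reg.slope:.3f}, intercept {reg.intercept:.1f}, "
      f"r {reg.r:.3f} (95 % CI {ci.ci_low:.3f} to {ci.ci_high:.3f})")
print(f"Bland-Altman: bias {ba.bias:.1f} mL/s, "
      f"limits of agreement {ba.loa_low:.1f} to {ba.loa_high:.1f} mL/s")
print(f"mean underestimation vs volumetric: {pct:.1f} % (~{pct_round} %)")

# The velocity-encoded pathway tracks the volumetric one tightly across
# subjects (r near 1 here because the phantom has no observer variability);
# its small negative bias is the temporal-blur deficit.
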