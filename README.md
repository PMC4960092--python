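# pfrkit

Tools for measuring the **left-ventricular peak filling rate (PFR)** — the
maximum rate of early-diastolic LV volume increase, in mL/s, a standard
indicator of diastolic function — from cine cardiovascular MR, two ways:

* **Velocity-encoded (phase-contrast) pathway.** On a slice at the mitral
  valve orifice, pixel phase is proportional to through-plane velocity
  (full scale = VENC, here 150 cm/s). Transmitral flow at a reconstructed
  phase is `Q = A · |v̄|` (ROI area in cm² times absolute mean velocity in
  cm/s, giving mL/s), and PFR is the maximum flow over the visually picked
  peak-filling phase and its two immediate neighbours.
* **Volumetric (SSFP) pathway.** Short-axis cavity areas are summed into
  volumes `V = Σ Aₛ·Δz`; around the peak-filling phase a 5- or 6-point
  time–volume curve is differenced into rates `(Vᵢ₊₁−Vᵢ)/(tᵢ₊₁−tᵢ)` at
  interval midpoints, a parabola `r(t) = a t² + b t + c` is least-squares
  fitted to those points, and PFR and peak filling time are read off the
  vertex `(−b/2a, c − b²/4a)`.

Because real hearts have no known ground truth, the package includes a
**synthetic phantom**: a periodic LV volume curve with raised-cosine E/A
filling lobes whose peak dV/dt is known in closed form, rendered both as a
velocity-encoded image series and as a segmentation stack. The finite data
acquisition window of a segmented cine scan (true temporal resolution,
`TR×VPS×2` for velocity-encoded, `TR×VPS` for balanced cine) is modeled as a
boxcar average — which reproduces the characteristic underestimation of the
peak and its dependence on the acquisition window, not on the reconstructed
phase spacing. A statistics module covers the method-comparison toolkit:
OLS regression, Fisher-z CIs for r, Bland–Altman limits of agreement with
t-based CIs, ICC(2,1)/ICC(3,1), one-way ANOVA.

## Worked example

```bash
python examples/02_pc_pathway.py
```

```
temporal_pc  (blur  43.2 ms): PFR  451.8 mL/s at 544.4 ms (  2.8 % below the true 464.7)
spatial_pc   (blur 100.8 ms): PFR  412.0 mL/s at 544.4 ms ( 11.4 % below the true 464.7)
```

The default phantom (EDV 150 mL, ESV 65 mL, 62 bpm) has a true PFR of
464.7 mL/s. The high-temporal-resolution protocol (43.2 ms acquisition
window) recovers it within a few percent; the high-spatial-resolution
protocol (100.8 ms window) underestimates several times more, although both
reconstruct the same 64 phases. The other scripts in `examples/` walk
through the phantom (`01`), the volumetric pathway (`03`, including
EDV/ESV/EF and Du Bois BSA indexing), the timing calculators (`04`), and a
simulated-cohort method comparison (`05`).

A thin CLI mirrors the library: `pfrkit simulate | pc-pfr | ssfp-pfr |
timing | compare | run` (NIfTI + JSON in, JSON out; `pfrkit run` executes
the whole simulate→measure→compare pipeline with provenance).

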