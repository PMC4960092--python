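# Methods

## The measurement problem

Early-diastolic LV filling is fast: the transmitral E wave rises from zero
to several hundred mL/s in under 100 ms. Any cine acquisition that builds a
cardiac phase from data gathered over a finite window averages the signal
over that window, so the sharper the filling peak, the more a long window
shaves off it. The package's purpose is to implement two independent PFR
measurement pathways, quantify that attenuation on a phantom with known
truth, and provide the statistics used to compare the pathways on real
cohorts.

## Phantom model

**Volume curve.** dV/dt over one RR interval is a sum of compactly
supported lobes: a negative raised-cosine ejection lobe on
[0, systole_end], an asymmetric E lobe built from two half-cosines (rising
on [e_onset, e_peak], falling on [e_peak, e_end]), and a symmetric
raised-cosine A lobe on [a_onset, a_end]. Lobe amplitudes are fixed by
volume conservation: the ejection lobe integrates to −SV, and the E and A
lobes split +SV in the ratio `e_to_a_volume_ratio`. Consequences used
throughout the tests: V is C¹, exactly periodic, V(0)=EDV, min V=ESV, and
the true PFR has the closed form `2·Vol_E/(e_end−e_onset)` (the E-lobe
half-cosines meet at the peak value). `true_pfr` nevertheless locates the
maximum by dense grid search plus bounded refinement, so it remains correct
for any future waveform family.

**Default parameters.** 62 bpm, EDV 150 mL, ESV 65 mL — a healthy adult
heart. Shape fractions (systole ends at 0.38 RR; E wave 0.45–0.72 RR
peaking at 0.55; A wave 0.82–0.97; E/A volume ratio 2.5) were chosen from
textbook physiology of young adults; with them the true PFR is 464.7 mL/s
and the peak orifice velocity 93 cm/s, comfortably below the 150 cm/s
velocity-encoding limit (no aliasing by default; a wrap mode exists for
studying it). Velocity noise defaults to 2 cm/s SD per pixel; magnitude
images carry no noise model because they serve only as a tracing aid.

**Acquisition model.** Retrospective gating is idealized: reconstructed
phase j (1-based) sits exactly at (j−1)·RR/n. This convention (phase 1 at
t = 0) is what makes volumetric phase n and velocity-map phase 2n−1
simultaneous when the velocity map reconstructs twice as many phases — the
premise of the 5/6-phase window rule. The true-temporal-resolution effect
is modeled purely as a centered boxcar average of width equal to the
acquisition window (43.2/100.8 ms for the two velocity-encoded protocols,
40 ms for the volumetric one), applied to the filling-rate signal before
velocity encoding and to V(t) before slicing. The boxcar is evaluated by
composite trapezoidal quadrature with 2048 panels — for these
piecewise-smooth signals the quadrature error is far below every tolerance
used.

**Rasterization.** Disc ROIs (mitral orifice; spheroid slice
cross-sections) are realized as the N pixels nearest the disc center with
N = round(area/pixel area), ties broken by distance then row-major index.
This keeps rasterized areas within half a pixel of nominal, so the
area × mean-velocity product reproduces the painted flow to well under 1 %,
and volumetry errors are dominated by nothing at all in exact-area mode
(analytic slice areas are carried alongside the masks) and stay below 2 %
in raster mode. The velocity painted in the ROI is the blurred filling rate
divided by the *nominal* orifice area, so decode-then-average round-trips
to within one quantization step (VENC/phase_scale, default 150/4096 ≈
0.037 cm/s).

**What the phantom does not emulate.** No k-space, coil sensitivities,
banding, flow-profile curvature (a uniform orifice profile is the default —
it makes ROI-mean × area exact; a parabolic profile would change only the
ROI mean's interpretation, not the flow integral), no beat-to-beat RR
variability, no respiratory motion, and no observer variability in
contours. Passing recovery tests therefore demonstrates correctness of the
measurement chain and of the temporal-resolution physics, not robustness to
segmentation error or arrhythmia.

## Measurement pathways

**Velocity-encoded.** `decode_velocity` inverts the linear stored-phase map;
`roi_flow` takes the absolute mean velocity so the slice orientation can
never flip the sign of PFR. The three-phase rule takes the maximum flow at
the picked phase and its two neighbours; ties go to the center phase, and
indices at the sequence boundary raise rather than wrap (early filling
never abuts phase 1 physiologically, so wraparound would always be a bug in
the caller). `find_visual_peak` automates the operator's visual pick as the
flow argmax over a user-supplied early-filling window, earliest phase
winning ties.

**Volumetric.** `stack_volume` sums slice areas × (thickness + gap). An
optional `basal_fraction` in (0, 1] scales the basal slice's contribution,
standing in for the long-axis landmark processing that splits atrium from
ventricle in that slice; it defaults to 1 (the phantom has no atrium). The
quadratic fit centers times at their mean before calling the LS solver —
mathematically transparent (tests verify coefficient identity with a raw
normal-equations solve in extended precision) but necessary because raw
normal equations in ms² are ill-conditioned. A fitted curvature that is
non-negative, or indistinguishable from zero at scale-relative tolerance
1e-10·max|rate|/span², raises `NoConcavePeakError` instead of reporting a
spurious vertex. Phase windows that would extend past either end of the
volumetric sequence raise rather than clamp: a one-sided window would bias
the vertex.

**Timing.** `TR×VPS×2` vs `TR×VPS`, and RR/n. The RR interval is 60000/HR
with no beat-to-beat variability, consistent with the idealized gating.

## Statistics

Limits of agreement use exactly 1.96·SD (sample SD, n−1). Confidence
intervals for the bias use SE = sd/√n and for each limit the approximate
SE = sd·√(3/n), both with a t(n−1) quantile — with n = 10 this reproduces
published small-cohort intervals that a z quantile misses by several mL/s.
The Fisher-z interval for r uses half-width z_crit/√(n−3). ICC defaults to
ICC(2,1) (two-way random, absolute agreement, single measures) with
ICC(3,1) available, computed via pingouin and cross-checked in tests
against a direct mean-squares decomposition. `linear_regression` reports
slope 0 and r = 0 for constant y (documented convention) and refuses
constant x. A summary mode for Bland–Altman (bias and SD in, limits out)
supports auditing published tables when raw pairs are unavailable.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at its native resolution
(64/32 phases; 96–256 pixel matrices — the smaller matrix is used where
only ROI statistics matter, since the orifice disc fits either way). The
recovery experiment uses the default phantom; the noise-free variant
isolates the blur physics. Quadrature: 2048-panel trapezoid for blurring;
adaptive quadrature (`scipy.integrate.quad`) only in test oracles.
Tie-breaks: center phase (three-phase rule), earliest phase (window
search), row-major pixel order (rasterization) — all deterministic.
Degenerate inputs are first-class: flat hearts yield zero PFR from
`true_pfr` and a `NoConcavePeakError` from the parabola pathway, which is
the correct scientific answer in both representations.

## Known limitations

* The phantom's E/A morphology is stylized (cosine lobes); real inflow
  profiles have longer deceleration tails, so absolute deficit percentages
  on real data will differ from the phantom's even at matched temporal
  resolution.
* LV mass is not computed (needs epicardial contours and a density
  convention); echocardiographic comparison and valve tracking are out of
  scope.
* The ICC forms assume a complete subjects × raters table; missing cells
  are rejected, not imputed.
* DICOM ingestion of real scanner series is not implemented; NIfTI + JSON
  sidecar is the interchange format.
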