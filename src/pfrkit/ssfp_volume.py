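"""SSFP volumetric pathway: slice-summation volumetry and parabolic peak fitting.

LV volume at a phase is the Simpson-type sum of per-slice cavity areas times
the slice spacing. A short time-volume curve is built over five or six
phases centered on the peak-filling phase seen on the velocity-mapped
series (the odd/even phase-correspondence rule for a 2:1 phase-count
ratio), differenced between consecutive phases, and a parabola is fitted to
the resulting rate points; the vertex gives PFR and peak filling time,
preserving temporal resolution while damping contour-tracing jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, NoConcavePeakError
from .pc_flow import PFRResult
from .phantom import SegmentationStack

__all__ = [
    "TimeVolumeCurve",
    "DerivativeCurve",
    "ParabolaFit",
    "GlobalIndices",
    "stack_volume",
    "phase_window_from_pc_peak",
    "derivative_curve",
    "fit_parabola",
    "pfr_ssfp",
    "global_indices",
    "du_bois_bsa",
]


@dataclass
class TimeVolumeCurve:
    phase_times: np.ndarray    # ms
    volumes: np.ndarray        # mL
    phase_indices: np.ndarray  # 1-based SSFP phase indices

    def __post_init__(self):
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.phase_indices = np.asarray(self.phase_indices, dtype=int)
        if np.any(np.diff(self.phase_times) <= 0):
            raise InputError("phase_times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise InputError("volumes must be positive")


@dataclass
class DerivativeCurve:
    """Volume change rates between consecutive phases, plotted at interval midpoints."""

    midpoint_times: np.ndarray  # ms
    rates: np.ndarray           # mL/s


@dataclass
class ParabolaFit:
    """rate = a t^2 + b t + c with t in ms; vertex at (-b/2a, c - b^2/4a)."""

    a: float
    b: float
    c: float
    vertex_time: float   # ms
    vertex_rate: float   # mL/s
    rss: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * t * t + self.b * t + self.c


@dataclass
class GlobalIndices:
    edv: float           # mL
    esv: float           # mL
    ef: float            # %
    bsa: float           # m^2
    edv_per_bsa: float   # mL/m^2
    esv_per_bsa: float   # mL/m^2


def stack_volume(stack: SegmentationStack, phase_index: int,
                 basal_fraction: float = 1.0) -> float:
    """LV volume (mL) at a 1-based phase: sum of slice areas x slice spacing.

    Areas come from ``analytic_slice_areas`` when present (exact-area mode),
    else from mask pixel counts. ``basal_fraction`` scales the first
    (most basal) slice's contribution, standing in for the long-axis
    landmark processing that separates atrium from ventricle there.
    """
    if not (1 <= phase_index <= stack.n_phases):
        raise InputError(f"phase {phase_index} outside stack of {stack.n_phases} phases")
    if not (0.0 < basal_fraction <= 1.0):
        raise InputError("basal_fraction must be in (0, 1]")
    if stack.analytic_slice_areas is not None:
        areas = stack.analytic_slice_areas[phase_index - 1].copy()  # mm^2
    else:
        counts = stack.masks[phase_index - 1].sum(axis=(1, 2))
        areas = counts * stack.pixel_size ** 2
    areas[0] *= basal_fraction
    dz = stack.slice_thickness + stack.slice_gap
    return float(areas.sum() * dz / 1000.0)  # mm^3 -> mL


def phase_window_from_pc_peak(pc_peak_index: int, n_pc: int, n_ssfp: int) -> list[int]:
    """SSFP phase window centered on the velocity-map peak-filling phase.

    With twice as many velocity-map phases as volumetric phases, volumetric
    phase n is simultaneous with velocity-map phase 2n-1. An odd peak 2n-1
    maps to the five phases n-2..n+2; an even peak 2n falls between
    volumetric phases n and n+1 and maps to the six phases n-2..n+3.
    """
    if n_pc != 2 * n_ssfp:
        raise InputError(f"phase-correspondence rule needs n_pc = 2 x n_ssfp, "
                         f"got {n_pc} and {n_ssfp}")
    if not (1 <= pc_peak_index <= n_pc):
        raise InputError(f"pc_peak_index {pc_peak_index} outside 1..{n_pc}")
    if pc_peak_index % 2 == 1:
        n = (pc_peak_index + 1) // 2
        window = list(range(n - 2, n + 3))
    else:
        n = pc_peak_index // 2
        window = list(range(n - 2, n + 4))
    if window[0] < 1 or window[-1] > n_ssfp:
        raise InputError(
            f"phase window {window} for peak {pc_peak_index} extends outside "
            f"1..{n_ssfp}; refusing to clamp (an asymmetric window would bias the fit)")
    return window


def derivative_curve(tvc: TimeVolumeCurve) -> DerivativeCurve:
    """First-derivative curve: consecutive-phase volume change rates at midpoints."""
    if len(tvc.volumes) < 2:
        raise InputError("need at least two time-volume points")
    dt = np.diff(tvc.phase_times)
    if np.any(dt == 0):
        raise InputError("duplicate phase times")
    rates = np.diff(tvc.volumes) / dt * 1000.0  # mL/ms -> mL/s
    mids = (tvc.phase_times[:-1] + tvc.phase_times[1:]) / 2.0
    return DerivativeCurve(midpoint_times=mids, rates=rates)


def fit_parabola(dc: DerivativeCurve) -> ParabolaFit:
    """Least-squares quadratic through the derivative curve; vertex = (time, PFR).

    Times are centered at their mean before solving (conditioning only; the
    returned coefficients are in raw ms). An upward-opening or flat fit has
    no concave peak and raises.
    """
    t = np.asarray(dc.midpoint_times, dtype=float)
    y = np.asarray(dc.rates, dtype=float)
    if t.size < 3:
        raise InputError("parabola fit needs at least three rate points")
    tm = t.mean()
    A, B, C = np.polyfit(t - tm, y, 2)
    a = A
    b = B - 2.0 * A * tm
    c = C - B * tm + A * tm * tm
    # curvature indistinguishable from zero (relative to the data scale) has no peak
    a_tol = 1e-10 * (np.max(np.abs(y)) + 1.0) / (np.ptp(t) ** 2)
    if a >= -a_tol:
        raise NoConcavePeakError(
            f"fitted quadratic does not open downward (a={a:.3g}): no concave filling peak")
    vertex_time = -b / (2.0 * a)
    vertex_rate = c - b * b / (4.0 * a)
    resid = y - (a * t * t + b * t + c)
    return ParabolaFit(a=float(a), b=float(b), c=float(c),
                       vertex_time=float(vertex_time),
                       vertex_rate=float(vertex_rate),
                       rss=float(resid @ resid))


def pfr_ssfp(stack: SegmentationStack, pc_peak_index: int,
             basal_fraction: float = 1.0) -> PFRResult:
    """Full SSFP pathway: window -> volumes -> derivative -> parabola vertex."""
    window = phase_window_from_pc_peak(pc_peak_index, 2 * stack.n_phases, stack.n_phases)
    vols = np.array([stack_volume(stack, p, basal_fraction) for p in window])
    times = stack.phase_times[[p - 1 for p in window]]
    tvc = TimeVolumeCurve(phase_times=times, volumes=vols,
                          phase_indices=np.array(window))
    dc = derivative_curve(tvc)
    fit = fit_parabola(dc)
    return PFRResult(
        pfr=fit.vertex_rate,
        peak_filling_time=fit.vertex_time,
        method="ssfp",
        diagnostics={
            "phase_window": window,
            "volumes_ml": vols.tolist(),
            "derivative_rates_ml_per_s": dc.rates.tolist(),
            "fit": fit,
        },
    )


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area (m^2): 0.007184 * H^0.725 * W^0.425."""
    if height_cm <= 0 or weight_kg <= 0:
        raise InputError("height and weight must be positive")
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


def global_indices(stack: SegmentationStack, height_cm: float, weight_kg: float,
                   basal_fraction: float = 1.0) -> GlobalIndices:
    """EDV, ESV, EF and BSA-indexed volumes from a full-cycle stack."""
    vols = np.array([stack_volume(stack, p, basal_fraction)
                     for p in range(1, stack.n_phases + 1)])
    if np.any(vols <= 0):
        raise InputError("non-positive LV volume in stack")
    edv = float(vols.max())
    esv = float(vols.min())
    ef = 100.0 * (edv - esv) / edv
    bsa = du_bois_bsa(height_cm, weight_kg)
    return GlobalIndices(edv=edv, esv=esv, ef=ef, bsa=bsa,
                         edv_per_bsa=edv / bsa, esv_per_bsa=esv / bsa)
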