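"""Phase-contrast pathway: decode velocities, ROI flow, and the three-phase PFR rule.

Transmitral flow (mL/s) at a reconstructed phase is the ROI area times the
absolute mean decoded velocity over the ROI. The peak filling rate is the
maximum flow among the visually identified peak-filling phase and its two
immediate neighbours, which guards against an off-by-one in the visual pick
without smoothing the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import InputError
from .phantom import VelocityEncodedSeries

__all__ = [
    "FlowCurve",
    "PFRResult",
    "decode_velocity",
    "roi_flow",
    "find_visual_peak",
    "pfr_from_three_phases",
]


@dataclass
class FlowCurve:
    """Transmitral flow (mL/s, absolute) at the evaluated reconstructed phases."""

    phase_times: np.ndarray            # ms
    flows: np.ndarray                  # mL/s, >= 0
    evaluated_phase_indices: np.ndarray  # 1-based

    def __post_init__(self):
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        self.evaluated_phase_indices = np.asarray(self.evaluated_phase_indices, dtype=int)
        if np.any(np.diff(self.phase_times) <= 0):
            raise InputError("phase_times must be strictly increasing")
        if np.any(self.flows < 0):
            raise InputError("flows are absolute values and must be non-negative")


@dataclass
class PFRResult:
    """A peak filling rate with its timing, the producing method, and diagnostics."""

    pfr: float                 # mL/s
    peak_filling_time: float   # ms from cycle start
    method: str                # 'ssfp' | 'temporal_pc' | 'spatial_pc'
    diagnostics: dict[str, Any] = field(default_factory=dict)


def decode_velocity(phase_image: np.ndarray, venc: float, phase_scale: int) -> np.ndarray:
    """Map stored phase values to velocities: v = stored / phase_scale * VENC (cm/s)."""
    if phase_scale <= 0:
        raise InputError("phase_scale must be positive")
    phase_image = np.asarray(phase_image)
    if np.any(np.abs(phase_image) > phase_scale):
        raise InputError("stored phase values exceed phase_scale")
    return phase_image.astype(float) / phase_scale * venc


def roi_flow(velocity_map: np.ndarray, roi: np.ndarray, pixel_size: float) -> float:
    """Flow through an ROI: area (cm^2) x |mean velocity| (cm/s) -> mL/s."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise InputError("ROI is empty")
    if pixel_size <= 0:
        raise InputError("pixel_size must be positive")
    area_cm2 = roi.sum() * pixel_size ** 2 / 100.0
    return float(area_cm2 * abs(np.asarray(velocity_map)[roi].mean()))


def _flows(series: VelocityEncodedSeries, roi: np.ndarray,
           indices: Sequence[int]) -> np.ndarray:
    out = np.empty(len(indices))
    for k, j in enumerate(indices):
        v = decode_velocity(series.phase_images[j - 1], series.venc, series.phase_scale)
        out[k] = roi_flow(v, roi, series.pixel_size)
    return out


def find_visual_peak(series: VelocityEncodedSeries, roi: np.ndarray,
                     early_filling_window: tuple[int, int]) -> int:
    """Automated stand-in for the operator's visual pick of the peak-filling phase.

    Returns the 1-based phase index with maximal ROI flow inside the window
    (inclusive bounds); ties go to the earliest phase.
    """
    lo, hi = early_filling_window
    if not (1 <= lo <= hi <= series.n_phases):
        raise InputError(
            f"window {early_filling_window} outside series of {series.n_phases} phases")
    idx = list(range(lo, hi + 1))
    flows = _flows(series, roi, idx)
    return idx[int(np.argmax(flows))]


def pfr_from_three_phases(series: VelocityEncodedSeries, roi: np.ndarray,
                          visual_peak_index: int, method: str = "temporal_pc") -> PFRResult:
    """PFR as the max flow over the visual peak phase and its two neighbours.

    Ties are broken toward the center (visually picked) phase. The early
    filling peak never abuts the cycle boundary physiologically, so boundary
    indices raise rather than wrap.
    """
    k = int(visual_peak_index)
    if not (2 <= k <= series.n_phases - 1):
        raise InputError(
            f"visual peak index {k} must leave one neighbour on each side "
            f"(2..{series.n_phases - 1}); phases do not wrap across the cycle boundary")
    idx = [k - 1, k, k + 1]
    flows = _flows(series, roi, idx)
    best = max(range(3), key=lambda i: (flows[i], i == 1))  # center wins ties
    times = series.phase_times[[j - 1 for j in idx]]
    curve = FlowCurve(phase_times=times, flows=flows, evaluated_phase_indices=np.array(idx))
    return PFRResult(
        pfr=float(flows[best]),
        peak_filling_time=float(times[best]),
        method=method,
        diagnostics={
            "evaluated_phase_indices": idx,
            "flows_ml_per_s": flows.tolist(),
            "selected_phase_index": idx[best],
            "flow_curve": curve,
        },
    )
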