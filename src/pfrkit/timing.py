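"""Acquisition-timing calculators for segmented, retrospectively gated cine MR.

True temporal resolution is the actual data-acquisition window per cardiac
phase: TR x VPS for a balanced cine acquisition and TR x VPS x 2 for
velocity-encoded imaging, where each view is acquired twice (flow-encoded
and flow-compensated). Apparent temporal resolution is only the interval
between reconstructed phases, RR / n_phases, and can be much finer than the
true one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["AcquisitionParams", "true_temporal_resolution", "apparent_temporal_resolution"]


@dataclass(frozen=True)
class AcquisitionParams:
    tr: float             # ms
    vps: int              # views per segment
    n_recon_phases: int
    heart_rate: float     # beats/min
    sequence_kind: str    # 'pc' | 'ssfp'

    def validate(self) -> "AcquisitionParams":
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.vps < 1:
            raise ParameterError("vps must be >= 1")
        if self.n_recon_phases < 1:
            raise ParameterError("n_recon_phases must be >= 1")
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be positive")
        if self.sequence_kind not in ("pc", "ssfp"):
            raise ParameterError(f"unknown sequence_kind {self.sequence_kind!r}")
        return self

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate


def true_temporal_resolution(params: AcquisitionParams) -> float:
    """TR x VPS x 2 (velocity-encoded) or TR x VPS (balanced cine), in ms."""
    params.validate()
    factor = 2.0 if params.sequence_kind == "pc" else 1.0
    return params.tr * params.vps * factor


def apparent_temporal_resolution(params: AcquisitionParams) -> float:
    """Interval between adjacent reconstructed phases: RR / n_recon_phases, in ms."""
    params.validate()
    return params.rr_ms / params.n_recon_phases
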