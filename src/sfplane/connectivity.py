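"""Phase-interaction and Pearson connectomes from BOLD time series.

The phase pipeline is: band-pass the ROI signals to the low-frequency band
(0.04-0.07 Hz by default), take the instantaneous phase phi_i(t) of each
region via the Hilbert transform, form the instantaneous phase-coherence
P_ij(t) = cos(phi_i(t) - phi_j(t)), and average over time to obtain the
phase-interaction matrix <P>. Two regions score near 1 when in phase, 0 when
in quadrature, and -1 when in anti-phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ConnectivityMatrix, SubjectTimeSeries, ValidationError


@dataclass
class BandpassSpec:
    """Band edges (Hz) and Butterworth order for the zero-phase band-pass.

    The filter is applied forward-backward (``sosfiltfilt``), so the effective
    attenuation is the squared magnitude response and the phase response is
    exactly zero — important because the instantaneous phases are the signal
    of interest downstream.
    """

    low: float = 0.04
    high: float = 0.07
    order: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValidationError(
                f"band edges must satisfy 0 < low < high, got ({self.low}, {self.high})"
            )
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")

    def validate_for_tr(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if self.high >= nyquist:
            raise ValidationError(
                f"high edge {self.high} Hz is at or above the Nyquist frequency "
                f"{nyquist:.4g} Hz for tr = {tr} s; check the repetition time"
            )

    def sos(self, tr: float) -> np.ndarray:
        self.validate_for_tr(tr)
        return signal.butter(
            self.order, [self.low, self.high], btype="bandpass", fs=1.0 / tr, output="sos"
        )


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, in (-pi, pi]) per timepoint and region."""

    subject_id: str
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValidationError("phases must be a 2-D (timepoints x ROIs) array")
        if np.max(self.phases) > np.pi + 1e-12 or np.min(self.phases) <= -np.pi - 1e-12:
            raise ValidationError("phases must lie in (-pi, pi]")


def bandpass_filter(ts: SubjectTimeSeries, spec: BandpassSpec | None = None) -> SubjectTimeSeries:
    """Zero-phase band-pass of every ROI column."""
    spec = spec or BandpassSpec()
    sos = spec.sos(ts.tr)
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return SubjectTimeSeries(subject_id=ts.subject_id, values=filtered, tr=ts.tr)


def instantaneous_phase(ts: SubjectTimeSeries) -> PhaseSeries:
    """Phase of the analytic (Hilbert) signal per region.

    The input is expected to be narrowband (already band-passed); this is
    documented rather than enforced, since the analytic signal is defined for
    any series.
    """
    zero_cols = np.where(np.all(ts.values == 0, axis=0))[0]
    if zero_cols.size:
        raise ValidationError(
            f"phase undefined for all-zero ROI column(s) {zero_cols.tolist()}"
        )
    analytic = signal.hilbert(ts.values, axis=0)
    phases = np.angle(analytic)
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    phases[phases == -np.pi] = np.pi
    return PhaseSeries(subject_id=ts.subject_id, phases=phases)


def phase_interaction_matrix(ph: PhaseSeries, trim: int = 0) -> ConnectivityMatrix:
    """Time-averaged phase coherence <P>_ij = mean_t cos(phi_i(t) - phi_j(t)).

    ``trim`` drops that many samples at each end of the series before
    averaging; Hilbert phases are unreliable near the boundaries.
    """
    phases = ph.phases
    if trim < 0:
        raise ValidationError("trim must be non-negative")
    if trim:
        if phases.shape[0] - 2 * trim < 3:
            raise ValidationError("trim leaves fewer than 3 samples")
        phases = phases[trim : phases.shape[0] - trim]
    t = phases.shape[0]
    # mean_t cos(phi_i - phi_j) = Re[ (1/T) sum_t e^{i phi_i} e^{-i phi_j} ]
    z = np.exp(1j * phases)
    p = (z.conj().T @ z).real / t
    p = np.clip((p + p.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(subject_id=ph.subject_id, weights=p, kind="phase_interaction")


def pearson_connectivity(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Plain Pearson correlation matrix of the ROI columns."""
    variances = ts.values.var(axis=0)
    dead = np.where(variances == 0)[0]
    if dead.size:
        raise ValidationError(
            f"zero-variance ROI column(s) {dead.tolist()}: correlation undefined"
        )
    r = np.corrcoef(ts.values.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, weights=r, kind="pearson")


def phase_pipeline(
    ts: SubjectTimeSeries, spec: BandpassSpec | None = None, trim: int = 0
) -> ConnectivityMatrix:
    """Full filter -> Hilbert phase -> time-averaged coherence pipeline."""
    return phase_interaction_matrix(instantaneous_phase(bandpass_filter(ts, spec)), trim=trim)
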