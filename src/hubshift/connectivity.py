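"""Temporal bandpass filtering and pairwise Pearson functional connectivity.

The analysis band is 0.009-0.1 Hz, the standard resting-state window that
removes scanner drift (below) and respiratory/cardiac leakage (above). Two
filter designs are provided:

``butterworth_zero_phase`` (default)
    order-2 Butterworth bandpass applied forward-backward
    (``sosfiltfilt``), so the filter is zero-phase and introduces no
    lag-induced correlation bias;
``fft_hard``
    an ideal brick-wall mask in the frequency domain, useful when an exact
    passband is wanted in tests.

Connectivity is raw Pearson r (no Fisher z), so every edge weight lies in
[-1, 1]. Series are demeaned by the filter (DC is outside the passband) and
again implicitly by the correlation itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DegenerateSeriesError, ParameterError, ShapeError
from .types import BOLDSession, ConnectivityMatrix

log = logging.getLogger(__name__)

DEFAULT_LOW_HZ = 0.009
DEFAULT_HIGH_HZ = 0.1


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass parameters: cutoffs in Hz plus the filter family."""

    low_cutoff: float = DEFAULT_LOW_HZ
    high_cutoff: float = DEFAULT_HIGH_HZ
    design: str = "butterworth_zero_phase"
    order: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise ParameterError(
                f"need 0 < low ({self.low_cutoff}) < high ({self.high_cutoff})"
            )
        if self.design not in ("butterworth_zero_phase", "fft_hard"):
            raise ParameterError(f"unknown filter design {self.design!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")

    def validate_for(self, sampling_interval: float) -> None:
        nyq = 0.5 / sampling_interval
        if self.high_cutoff >= nyq:
            raise ParameterError(
                f"high cutoff {self.high_cutoff} Hz >= Nyquist {nyq} Hz"
            )

    def as_meta(self) -> dict:
        return {
            "filter_low_hz": self.low_cutoff,
            "filter_high_hz": self.high_cutoff,
            "filter_design": self.design,
            "filter_order": self.order,
        }


def bandpass(session: BOLDSession, spec: FilterSpec = FilterSpec()) -> BOLDSession:
    """Bandpass every region series of a session; returns a new session."""
    spec.validate_for(session.sampling_interval)
    x = session.signals - session.signals.mean(axis=1, keepdims=True)
    fs = 1.0 / session.sampling_interval
    if spec.design == "butterworth_zero_phase":
        sos = signal.butter(
            spec.order, [spec.low_cutoff, spec.high_cutoff],
            btype="bandpass", fs=fs, output="sos",
        )
        # sosfiltfilt needs a minimum signal length for its edge padding
        padlen = 3 * (2 * sos.shape[0] + 1)
        if session.n_volumes <= padlen:
            raise ShapeError(
                f"{session.n_volumes} volumes too short for order-{spec.order} "
                f"zero-phase filter (needs > {padlen})"
            )
        y = signal.sosfiltfilt(sos, x, axis=1)
    else:  # fft_hard
        freqs = np.fft.rfftfreq(session.n_volumes, d=session.sampling_interval)
        mask = (freqs >= spec.low_cutoff) & (freqs <= spec.high_cutoff)
        y = np.fft.irfft(np.fft.rfft(x, axis=1) * mask, n=session.n_volumes, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return replace(session, signals=y)


def pearson_connectivity(session: BOLDSession) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of all region series of one session."""
    sd = session.signals.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateSeriesError(
            f"zero-variance region series at node(s) {dead.tolist()} "
            f"in session {session.subject_id}/{session.timepoint}"
        )
    r = np.corrcoef(session.signals)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    return ConnectivityMatrix(
        values=r, subject_id=session.subject_id, timepoint=session.timepoint
    )


def cohort_connectivity(
    sessions: list[BOLDSession], spec: FilterSpec = FilterSpec()
) -> list[ConnectivityMatrix]:
    """Filter + correlate every session of a cohort, preserving order."""
    if not sessions:
        log.warning("cohort_connectivity called with an empty session list")
        return []
    n_regions = sessions[0].n_regions
    out = []
    for s in sessions:
        if s.n_regions != n_regions:
            raise ShapeError(
                f"session {s.subject_id}/{s.timepoint} has {s.n_regions} regions, "
                f"expected {n_regions}"
            )
        cm = pearson_connectivity(bandpass(s, spec))
        cm.meta.update(spec.as_meta())
        log.info("connectivity: subject=%s timepoint=%s band=%g-%g Hz",
                 s.subject_id, s.timepoint, spec.low_cutoff, spec.high_cutoff)
        out.append(cm)
    return out
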