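"""Autonomic indices: event-locked SCR amplitude, mean heart rate,
high-frequency HRV power, and the short-term detrended-fluctuation
scaling exponent DFA-alpha1.

Conventions follow standard HRV-analysis practice: the HF band is
0.15-0.40 Hz, the RR tachogram is resampled to 4 Hz with cubic
interpolation before Welch spectral estimation, and DFA-alpha1 uses box
sizes of 4-16 beats.  SCR amplitude is the mean base-to-peak difference in
a 15 s post-onset window, with "base" taken as the trace value at window
start and each event's amplitude floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .simulate import RRSeries, ScrTrace

__all__ = [
    "AutonomicIndices",
    "scr_event_amplitude",
    "mean_heart_rate",
    "hf_power",
    "dfa_alpha1",
    "compute_indices",
]

HF_BAND = (0.15, 0.40)
DFA_SCALES = tuple(range(4, 17))


@dataclass
class AutonomicIndices:
    scr_amplitude: float  # µS
    heart_rate: float  # beats/min
    hf_power: float  # ms^2
    dfa_alpha1: float  # dimensionless

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.hf_power < 0:
            raise ValueError("hf_power must be >= 0")
        if not np.isfinite(self.dfa_alpha1):
            raise ValueError("dfa_alpha1 must be finite")


def scr_event_amplitude(
    trace: ScrTrace, onsets: Sequence[float], window_s: float = 15.0
) -> float:
    """Mean base-to-peak SCR amplitude over events.

    Per onset: max(trace within [onset, onset+window]) minus the trace value
    at the window start, floored at 0; returns the mean across onsets.
    """
    fs = trace.sampling_rate
    amps = []
    for onset in onsets:
        start = int(round(onset * fs))
        stop = int(round((onset + window_s) * fs))
        if start < 0 or stop > trace.samples.size:
            raise ValueError(f"onset {onset} s with {window_s} s window exceeds trace bounds")
        seg = trace.samples[start:stop]
        amps.append(max(0.0, float(seg.max() - seg[0])))
    if not amps:
        raise ValueError("no onsets given")
    return float(np.mean(amps))


def mean_heart_rate(rr: RRSeries) -> float:
    """60000 / mean(RR in ms), in beats per minute."""
    return 60000.0 / float(np.mean(rr.rr_intervals))


def hf_power(
    rr: RRSeries,
    band: tuple[float, float] = HF_BAND,
    resample_hz: float = 4.0,
    detrend: bool = True,
) -> float:
    """Spectral power of the RR tachogram in the HF band, ms^2.

    The unevenly sampled RR series is cubic-interpolated onto a uniform
    grid, linearly detrended, and Welch-integrated over ``band``.
    """
    times = rr.beat_times
    span = times[-1] - times[0]
    min_span = 2.0 / band[0]
    if span < min_span:
        raise ValueError(f"series too short for {band[0]} Hz resolution (need >= {min_span:.0f} s)")
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    tachogram = CubicSpline(times, rr.rr_intervals)(grid)
    if detrend:
        coeffs = np.polyfit(grid, tachogram, 1)
        tachogram = tachogram - np.polyval(coeffs, grid)
    nperseg = min(tachogram.size, int(256 * resample_hz / 4))
    freqs, psd = welch(tachogram, fs=resample_hz, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))


def dfa_alpha1(rr: RRSeries, scales: Sequence[int] = DFA_SCALES) -> float:
    """Short-term detrended fluctuation scaling exponent.

    Integrate the mean-centered series; for each box size n, compute the
    RMS residual around per-box linear fits, F(n); alpha1 is the slope of
    log F(n) against log n.
    """
    x = rr.rr_intervals
    if x.size < 100:
        raise ValueError("DFA needs at least 100 beats")
    max_scale = max(scales)
    if x.size < 4 * max_scale:
        raise ValueError(f"series shorter than 4x the largest scale ({max_scale} beats)")
    profile = np.cumsum(x - x.mean())
    log_n, log_f = [], []
    for n in scales:
        n_boxes = profile.size // n
        boxes = profile[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        basis = np.column_stack([t, np.ones(n)])
        coef, *_ = np.linalg.lstsq(basis, boxes.T, rcond=None)
        resid = boxes.T - basis @ coef
        f_n = np.sqrt(np.mean(resid**2))
        log_n.append(np.log(n))
        log_f.append(np.log(f_n))
    slope = np.polyfit(log_n, log_f, 1)[0]
    return float(slope)


def compute_indices(
    rr: RRSeries,
    scr: ScrTrace,
    onsets: Sequence[float],
    hf_band: tuple[float, float] = HF_BAND,
    dfa_scales: Sequence[int] = DFA_SCALES,
    scr_window_s: float = 15.0,
) -> AutonomicIndices:
    """All four indices for one subject-condition."""
    return AutonomicIndices(
        scr_amplitude=scr_event_amplitude(scr, onsets, scr_window_s),
        heart_rate=mean_heart_rate(rr),
        hf_power=hf_power(rr, hf_band),
        dfa_alpha1=dfa_alpha1(rr, dfa_scales),
    )
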