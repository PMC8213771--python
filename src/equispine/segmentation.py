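"""Stride segmentation from the tubera sacrale vertical signal.

In trot the croup shows two vertical oscillations per stride (one per diagonal
stance), so stride events are the local maxima of the zero-lag high-pass
filtered tubera sacrale height, and the stride frequency is half the dominant
frequency of that signal.  Left/right hind stance at each event is read from
the sign of the band-passed pelvis roll oscillation; one stride runs from each
second event to the event two later, starting at the first detected event
(any fixed whole-cycle convention leaves stride means and ROM unchanged, and
anchoring on the event sequence rather than on one stance side makes the
intervals invariant under a left-right mirror of the scene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import MarkerTrajectorySet
from .kinematics import pelvis_roll_lab

FILTER_ORDER = 4  # forward-backward Butterworth (effective order 8)
CUTOFF_FACTOR = 0.7  # high-pass cut-off as a fraction of stride frequency
MIN_STRIDE_S = 0.4
MAX_STRIDE_S = 1.2
FREQ_SEARCH_HZ = (1.0, 5.0)  # plausible trot vertical-oscillation band


class StrideDetectionError(RuntimeError):
    pass


@dataclass
class StrideSegmentation:
    """Ordered half-open stride intervals with stance-side labels."""

    strides: list[tuple[int, int]]
    start_side: list[str]
    f_hat: float  # estimated stride frequency [Hz]
    cutoff: float  # applied high-pass cut-off [Hz]
    rate: float
    events: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    event_sides: list[str] = field(default_factory=list)

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    @property
    def median_stride_duration(self) -> float:
        """Median stride duration in seconds (falls back to 1/f_hat)."""
        if not self.strides:
            return 1.0 / self.f_hat
        durations = [(e - s) / self.rate for s, e in self.strides]
        return float(np.median(durations))


def estimate_stride_frequency(z: np.ndarray, rate: float) -> float:
    """Stride frequency [Hz]: half the dominant frequency of the mean-removed
    vertical signal (periodogram peak restricted to the trot band)."""
    z = np.asarray(z, dtype=float)
    if z.size < 3 * rate:
        raise StrideDetectionError("cannot estimate stride frequency: signal too short")
    x = z - np.nanmean(z)
    if not np.any(np.abs(x) > 1e-12):
        raise StrideDetectionError("cannot estimate stride frequency: constant signal")
    freqs, power = signal.periodogram(x, fs=rate)
    band = (freqs >= FREQ_SEARCH_HZ[0]) & (freqs <= FREQ_SEARCH_HZ[1])
    if not band.any() or not np.any(power[band] > 0):
        raise StrideDetectionError("cannot estimate stride frequency: no spectral peak")
    dominant = freqs[band][np.argmax(power[band])]
    f = dominant / 2.0
    if not 0.5 <= f <= 2.5:
        raise StrideDetectionError(
            f"cannot estimate stride frequency: estimate {f:.2f} Hz outside [0.5, 2.5]"
        )
    return float(f)


def _butter_sos(cutoff: float, rate: float, btype: str):
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz, got {cutoff}")
    return signal.butter(FILTER_ORDER, cutoff / nyq, btype=btype, output="sos")


def highpass_zero_lag(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth high-pass filter."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 6 * FILTER_ORDER:
        raise ValueError("series too short for zero-lag filtering")
    return signal.sosfiltfilt(_butter_sos(cutoff, rate, "highpass"), x, axis=0)


def lowpass_zero_lag(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth low-pass filter."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 6 * FILTER_ORDER:
        raise ValueError("series too short for zero-lag filtering")
    return signal.sosfiltfilt(_butter_sos(cutoff, rate, "lowpass"), x, axis=0)


def segment_strides(t: MarkerTrajectorySet) -> StrideSegmentation:
    """Detect stride intervals and stance sides for one measurement.

    Events are local maxima of the high-pass filtered tubera sacrale height
    (prominence >= 25% of the filtered signal RMS, spacing >= 0.3 / f_hat);
    each event is labelled by the sign of the pelvis-roll stride oscillation
    (band-passed between the segmentation cut-off and 2 x f_hat, which removes
    the body-lean mean that would otherwise dominate on the circle).  Strides
    run from each second event to the event two later.
    """
    t.require(("tuber_sacrale", "tuber_coxae_left", "tuber_coxae_right"))
    z = t["tuber_sacrale"][:, 2]
    f_hat = estimate_stride_frequency(z, t.rate)
    cutoff = CUTOFF_FACTOR * f_hat
    zf = highpass_zero_lag(z, cutoff, t.rate)

    rms = float(np.sqrt(np.mean(zf**2)))
    min_dist = max(1, int(round(0.3 / f_hat * t.rate)))
    peaks, _ = signal.find_peaks(zf, prominence=0.25 * rms, distance=min_dist)
    if peaks.size < 3:
        raise StrideDetectionError("no strides detected")

    roll = pelvis_roll_lab(t)
    roll_band = lowpass_zero_lag(highpass_zero_lag(roll, cutoff, t.rate), 2.0 * f_hat, t.rate)
    sides = ["left" if roll_band[p] < 0 else "right" for p in peaks]

    strides: list[tuple[int, int]] = []
    start_side: list[str] = []
    for k in range(0, len(peaks) - 2, 2):
        a, b = peaks[k], peaks[k + 2]
        dur = (b - a) / t.rate
        if MIN_STRIDE_S <= dur <= MAX_STRIDE_S:
            strides.append((int(a), int(b)))
            start_side.append(sides[k])
    if not strides:
        raise StrideDetectionError("no strides detected")
    return StrideSegmentation(
        strides=strides,
        start_side=start_side,
        f_hat=f_hat,
        cutoff=cutoff,
        rate=t.rate,
        events=peaks,
        event_sides=sides,
    )
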