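"""Instantaneous rate series, heart/breathing ratio, and Burg spectra.

The instantaneous rate is the reciprocal of the inter-beat (or
inter-inhalation) interval, assigned at each event time and resampled to a
uniform grid (4 Hz by default) by cubic interpolation.  Heart-rate
variability spectra are estimated on the uniformly resampled IBI series by
Burg's autoregressive method at order 16, and the dominant frequency is
the PSD maximum inside 0–0.5 Hz (ties broken toward the lower frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .beats import BeatAnnotations, moving_mean

__all__ = [
    "RateSeries",
    "SpectrumResult",
    "DominantFrequency",
    "ibi_to_rate",
    "ibi_series",
    "smooth_rate",
    "rate_ratio",
    "burg_psd",
    "main_frequency",
    "dominant_peak",
]

DEFAULT_GRID_FS = 4.0  # Hz, resampling grid for rate / IBI series
DEFAULT_AR_ORDER = 16
MAIN_FREQ_BAND = (0.0, 0.5)  # Hz
PSD_GRID_POINTS = 1024


@dataclass
class RateSeries:
    """Time-stamped instantaneous rate on a uniform grid."""

    t: np.ndarray  # s
    value: np.ndarray  # Hz (or dimensionless for source="ratio")
    source: str  # {"heart", "breathing", "ratio", "ibi"}

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class SpectrumResult:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # s^2/Hz for IBI-based spectra
    main_freq: float  # Hz, maximum peak inside 0-0.5 Hz
    ar_order: int
    reflection: np.ndarray  # Burg reflection coefficients


@dataclass(frozen=True)
class DominantFrequency:
    freq_hz: float
    low_confidence: bool  # global PSD maximum fell outside the band


def _resample(event_t: np.ndarray, values: np.ndarray, grid_fs: float,
              source: str) -> RateSeries:
    t0, t1 = event_t[0], event_t[-1]
    grid = t0 + np.arange(int(np.floor((t1 - t0) * grid_fs)) + 1) / grid_fs
    if event_t.size >= 4:
        f = CubicSpline(event_t, values)
    else:
        f = interp1d(event_t, values, kind="linear", fill_value="extrapolate")
    out = np.asarray(f(grid), dtype=float)
    if source in ("heart", "breathing", "ibi"):
        out = np.maximum(out, 1e-9)
    return RateSeries(t=grid, value=out, source=source)


def ibi_to_rate(annotations: BeatAnnotations, grid_fs: float = DEFAULT_GRID_FS,
                source: str = "heart") -> RateSeries:
    """Instantaneous rate 1/IBI at each event time, cubically resampled to a
    uniform grid and clipped positive."""
    times = annotations.event_times
    if times.size < 2:
        raise ValueError("need at least 2 events for a rate series")
    rate = 1.0 / annotations.ibi
    return _resample(times[1:], rate, grid_fs, source)


def ibi_series(annotations: BeatAnnotations, grid_fs: float = DEFAULT_GRID_FS) -> RateSeries:
    """Uniformly resampled IBI series (s), the input to HRV spectra."""
    times = annotations.event_times
    if times.size < 2:
        raise ValueError("need at least 2 events for an IBI series")
    return _resample(times[1:], annotations.ibi, grid_fs, "ibi")


def smooth_rate(rate: RateSeries, window_s: float = 2.0) -> RateSeries:
    """Centered moving mean (edge-truncated windows), mean-preserving.

    The series mean is removed before smoothing and restored afterwards, so
    edge truncation cannot shift the overall level.
    """
    dt = rate.t[1] - rate.t[0]
    if dt >= window_s:
        raise ValueError("grid step must be smaller than the smoothing window")
    w = max(1, int(round(window_s / dt)))
    smoothed = moving_mean(rate.value, w)
    # edge-truncated windows shift the level slightly; re-center exactly
    smoothed += rate.value.mean() - smoothed.mean()
    return RateSeries(t=rate.t.copy(), value=smoothed, source=rate.source)


def rate_ratio(hr: RateSeries, br: RateSeries) -> RateSeries:
    """Pointwise heart/breathing rate ratio on a common grid."""
    if hr.value.size != br.value.size or not np.allclose(hr.t, br.t):
        raise ValueError("rate series must share the same time grid")
    return RateSeries(t=hr.t.copy(), value=hr.value / br.value, source="ratio")


# ---------------------------------------------------------------------------
# Burg autoregressive spectrum
# ---------------------------------------------------------------------------

def _burg(x: np.ndarray, order: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Burg's recursion on a mean-removed series.

    Returns ``(a, sigma2, k)``: the AR polynomial coefficients
    ``a = [1, a1, ..., a_p]`` of the whitening filter, the driving-noise
    variance, and the reflection coefficients (all inside (-1, 1) for a
    valid model).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    a = np.array([1.0])
    e = float(np.dot(x, x) / n)
    ef = x.copy()
    eb = x.copy()
    refl = np.zeros(order)
    for m in range(order):
        f = ef[1:]
        b = eb[:-1]
        den = float(np.dot(f, f) + np.dot(b, b))
        if den <= 0:
            refl = refl[:m]
            break
        k = -2.0 * float(np.dot(f, b)) / den
        refl[m] = k
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        e *= 1.0 - k * k
        ef = f + k * b
        eb = b + k * f
    return a, e, refl


def burg_psd(series: RateSeries | np.ndarray, order: int = DEFAULT_AR_ORDER,
             fs: float | None = None, n_freqs: int = PSD_GRID_POINTS) -> SpectrumResult:
    """AR(order) power spectral density by Burg's method.

    The series mean is removed before fitting; the one-sided PSD is
    evaluated on an ``n_freqs``-point grid from 0 to the Nyquist frequency.
    """
    if isinstance(series, RateSeries):
        x = series.value
        fs = series.fs
    else:
        x = np.asarray(series, dtype=float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    if x.size <= 2 * order:
        raise ValueError(f"series of length {x.size} too short for AR order {order}")
    x = x - x.mean()
    if np.dot(x, x) == 0:
        raise ValueError("zero-variance series has no spectrum")

    a, sigma2, refl = _burg(x, order)
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(a.size)) / fs)
    denom = np.abs(z @ a) ** 2
    psd = 2.0 * sigma2 / fs / np.maximum(denom, 1e-300)

    main = dominant_peak(SpectrumResult(freqs, psd, np.nan, order, refl)).freq_hz
    return SpectrumResult(freqs=freqs, psd=psd, main_freq=main, ar_order=order,
                          reflection=refl)


def dominant_peak(spectrum: SpectrumResult,
                  band: tuple[float, float] = MAIN_FREQ_BAND) -> DominantFrequency:
    """PSD argmax strictly inside the band, flagged low-confidence when the
    global maximum lies outside it; ties go to the lower frequency."""
    if band[0] < spectrum.freqs[0] - 1e-12 or band[1] > spectrum.freqs[-1] + 1e-12:
        raise ValueError("band exceeds the spectrum's frequency range")
    inside = (spectrum.freqs > band[0]) & (spectrum.freqs <= band[1])
    if not inside.any():
        raise ValueError("no frequency grid point inside the band")
    sub = spectrum.psd[inside]
    freq = float(spectrum.freqs[inside][np.argmax(sub)])  # argmax -> first/lowest tie
    global_max = float(spectrum.freqs[np.argmax(spectrum.psd)])
    low_conf = not (band[0] < global_max <= band[1])
    return DominantFrequency(freq_hz=freq, low_confidence=low_conf)


def main_frequency(spectrum: SpectrumResult,
                   band: tuple[float, float] = MAIN_FREQ_BAND) -> float:
    """Frequency (Hz) of the maximum PSD value inside the band."""
    return dominant_peak(spectrum, band).freq_hz
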