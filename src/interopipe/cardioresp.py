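"""Lagged cardiorespiratory correlation.

The coupling statistic is the Spearman cross-correlation between the
breathing signal and the 2-s-smoothed heart-rate series over lags
-30..+30 s; the signed coefficient of maximum absolute value and its lag
summarize the profile.  Positive lag means heart-rate changes follow
breathing changes (respiratory sinus arrhythmia's causal direction), so a
breathing-to-heart-rate delay of 10 s appears as lag = +10 s.

A seeded circular-shift surrogate threshold supports interpreting observed
coupling against a no-coupling null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fnirs import _max_abs_rho, lagged_spearman
from .rates import RateSeries

__all__ = ["CardiorespCorr", "cardioresp_correlation", "coupling_null_threshold",
           "resample_to_grid"]

DEFAULT_LAG_RANGE_S = (-30.0, 30.0)
MIN_OVERLAP_S = 30.0
RECOMMENDED_OVERLAP_S = 60.0


@dataclass
class CardiorespCorr:
    lags: np.ndarray  # s
    rho: np.ndarray  # Spearman coefficient per lag
    rho_max: float  # signed value at max |rho|
    lag_at_max: float  # s


def resample_to_grid(x: np.ndarray, fs_in: float, t_grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of a sampled series onto another time grid."""
    t_in = np.arange(x.size) / fs_in
    return np.interp(t_grid, t_in, x)


def cardioresp_correlation(
    breathing: np.ndarray,
    hr: RateSeries,
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S,
    breathing_fs: float | None = None,
) -> CardiorespCorr:
    """Spearman cross-correlation profile of heart rate against breathing.

    ``breathing`` is either already on the heart-rate grid or a raw series
    with ``breathing_fs`` given, in which case it is resampled.  Each lag
    uses the overlapping segment only; the overlap remaining at the extreme
    lag must be at least 30 s (60 s recommended; a warning is issued below
    that).
    """
    if breathing_fs is not None:
        breathing = resample_to_grid(breathing, breathing_fs, hr.t)
    breathing = np.asarray(breathing, dtype=float)
    if breathing.size != hr.value.size:
        raise ValueError("breathing and heart-rate series must share a grid")
    fs = hr.fs
    n = breathing.size
    max_lag = max(abs(lag_range_s[0]), abs(lag_range_s[1]))
    overlap_s = n / fs - max_lag
    if overlap_s < MIN_OVERLAP_S:
        raise ValueError(
            f"only {overlap_s:.1f} s of overlap at the extreme lag; need >= {MIN_OVERLAP_S} s"
        )
    if overlap_s < RECOMMENDED_OVERLAP_S:
        warnings.warn(f"overlap at extreme lag is {overlap_s:.1f} s (< 60 s recommended)")
    if breathing.std() < 1e-12 or hr.value.std() < 1e-12:
        raise ValueError("correlation undefined for constant input")

    lags_s, rho = lagged_spearman(breathing, hr.value, fs, lag_range_s,
                                  lag_step_s=1.0 / fs)
    rho_max, lag_at_max = _max_abs_rho(lags_s, rho)
    return CardiorespCorr(lags=lags_s, rho=rho, rho_max=rho_max, lag_at_max=lag_at_max)


def coupling_null_threshold(
    breathing: np.ndarray,
    hr: RateSeries,
    n_surrogates: int,
    seed: int,
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S,
    breathing_fs: float | None = None,
) -> float:
    """95th percentile of |rho_max| over circular-shift surrogates.

    Each surrogate circularly shifts the breathing series by a uniform
    random offset of at least 30 s, destroying breathing/heart-rate
    alignment while preserving both marginals and autocorrelations.
    """
    if n_surrogates <= 0:
        raise ValueError("need at least one surrogate")
    if breathing_fs is not None:
        breathing = resample_to_grid(breathing, breathing_fs, hr.t)
    breathing = np.asarray(breathing, dtype=float)
    fs = hr.fs
    n = breathing.size
    min_shift = int(round(30.0 * fs))
    if n <= 2 * min_shift:
        raise ValueError("record too short for >= 30 s circular shifts")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    maxima = np.empty(n_surrogates)
    for i, s in enumerate(shifts):
        surr = np.roll(breathing, int(s))
        cc = cardioresp_correlation(surr, hr, lag_range_s)
        maxima[i] = abs(cc.rho_max)
    return float(np.quantile(maxima, 0.95))
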