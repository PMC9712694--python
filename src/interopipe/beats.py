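"""ECG and breathing preprocessing: filtering, peak detection by template
matching, ectopic-interval detection and interpolation correction.

R-peak detection follows a two-pass template-matching scheme: a provisional
pass picks adaptive-threshold local maxima under a physiological refractory
period, a median beat template is built from the provisional peaks, and the
final peaks are re-picked where the normalized correlation between template
and signal exceeds threshold.  Inhalation peaks use the same scheme on a
2-s moving-mean smoothed belt signal with a longer refractory period.

All filtering here is zero-phase (forward-backward): downstream lag
analyses (cardiorespiratory lag, response latencies) would be biased by a
causal filter's group delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "BeatAnnotations",
    "SignalUnusableError",
    "filter_ecg",
    "detect_r_peaks",
    "detect_ectopic",
    "correct_ectopic",
    "detect_breath_peaks",
]

#: Template-matching settings: normalized-correlation threshold and the
#: refractory periods bounding physiological rates (HR < 240 bpm, paced
#: breathing <= 0.4 Hz, spontaneous < 0.67 Hz).
TEMPLATE_CORR_THRESHOLD = 0.6
ECG_REFRACTORY_S = 0.25
BREATH_REFRACTORY_S = 1.5
ECG_TEMPLATE_HALF_S = 0.10
BREATH_TEMPLATE_HALF_S = 1.5

#: Robust amplitude criterion for ectopic intervals: |dIBI| local maxima
#: exceeding median + 4*MAD (a bare local-maximum rule would flag half of
#: all intervals).
ECTOPIC_MAD_FACTOR = 4.0


class SignalUnusableError(ValueError):
    """Raised when a signal contains no detectable periodic events."""


@dataclass
class BeatAnnotations:
    """Detected event times with per-interval ectopic/corrected flags.

    ``ibi[k] = event_times[k+1] - event_times[k]``; flag arrays have one
    entry per interval.
    """

    event_times: np.ndarray
    ectopic_flags: np.ndarray = None  # type: ignore[assignment]
    corrected: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size >= 2 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        n = max(self.event_times.size - 1, 0)
        if self.ectopic_flags is None:
            self.ectopic_flags = np.zeros(n, dtype=bool)
        if self.corrected is None:
            self.corrected = np.zeros(n, dtype=bool)
        if len(self.ectopic_flags) != n or len(self.corrected) != n:
            raise ValueError("flag arrays must have one entry per interval")

    @property
    def ibi(self) -> np.ndarray:
        return np.diff(self.event_times)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_ecg(ecg: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 45.0),
               order: int = 4) -> np.ndarray:
    """Band-pass the raw ECG (default Butterworth order 4, 0.5–45 Hz),
    zero-phase."""
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} Hz too low for the {band[1]} Hz band edge")
    sos = sps.butter(order, band, btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ecg, dtype=float))


def moving_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving mean with edge-truncated windows."""
    if window_samples <= 1:
        return np.asarray(x, dtype=float).copy()
    kernel = np.ones(window_samples)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


# ---------------------------------------------------------------------------
# Two-pass template matching
# ---------------------------------------------------------------------------

def _provisional_peaks(x: np.ndarray, fs: float, refractory_s: float) -> np.ndarray:
    distance = max(1, int(round(refractory_s * fs)))
    peaks, props = sps.find_peaks(x, distance=distance)
    if peaks.size == 0:
        return peaks
    heights = x[peaks]
    # adaptive threshold: half of a robust (90th percentile) peak amplitude
    thr = 0.5 * np.quantile(heights, 0.9)
    return peaks[heights >= thr]


def _median_template(x: np.ndarray, peaks: np.ndarray, half: int) -> np.ndarray | None:
    segs = [x[p - half : p + half + 1] for p in peaks if p - half >= 0 and p + half + 1 <= x.size]
    if len(segs) < 3:
        return None
    return np.median(np.vstack(segs), axis=0)


def _normalized_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding normalized cross-correlation (cosine similarity of the
    mean-removed template against each window), aligned to window centers."""
    tpl = template - template.mean()
    tn = np.linalg.norm(tpl)
    if tn == 0:
        return np.zeros_like(x)
    w = tpl.size
    num = sps.fftconvolve(x, tpl[::-1], mode="same")
    # local energy of the mean-removed window
    ones = np.ones(w)
    s1 = sps.fftconvolve(x, ones, mode="same")
    s2 = sps.fftconvolve(x * x, ones, mode="same")
    cnt = sps.fftconvolve(np.ones_like(x), ones, mode="same")
    var = np.maximum(s2 - s1 * s1 / cnt, 0.0)
    local = np.sqrt(var)
    # num includes the window-mean term only through tpl being zero-mean
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = num / (tn * np.where(local > 0, local, np.inf))
    return np.clip(np.nan_to_num(ncc), -1.0, 1.0)


def _template_pass(
    x: np.ndarray,
    fs: float,
    refractory_s: float,
    half_s: float,
    corr_threshold: float = TEMPLATE_CORR_THRESHOLD,
) -> np.ndarray:
    prov = _provisional_peaks(x, fs, refractory_s)
    if prov.size < 3:
        raise SignalUnusableError("fewer than 3 provisional events detected")
    half = int(round(half_s * fs))
    template = _median_template(x, prov, half)
    if template is None:
        raise SignalUnusableError("too few complete template windows")

    ncc = _normalized_correlation(x, template)
    distance = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(ncc, height=corr_threshold, distance=distance)
    if cand.size < 3:
        raise SignalUnusableError("template matching confirmed fewer than 3 events")

    # refine each match to the local signal maximum (template center offset)
    tpl_off = int(np.argmax(template)) - half
    refine = max(1, int(round(0.1 * refractory_s * fs)))
    final = []
    for c in cand:
        c = c + tpl_off
        a, b = max(c - refine, 0), min(c + refine + 1, x.size)
        if a >= b:
            continue
        final.append(a + int(np.argmax(x[a:b])))
    final = np.unique(final)

    # amplitude screen: secondary deflections (e.g. T-waves) can correlate
    # with the template but sit far below the true event amplitude
    amps = x[final]
    final = final[amps >= 0.5 * np.median(amps)]
    if final.size < 3:
        raise SignalUnusableError("template matching confirmed fewer than 3 events")

    # plausibility: genuine cardiac/respiratory event trains are quasi-
    # periodic, incoherent noise detections are not
    ibi = np.diff(final) / fs
    med = np.median(ibi)
    if med <= 0 or np.median(np.abs(ibi - med)) / med > 0.5:
        raise SignalUnusableError("detected event train is not quasi-periodic")
    return final


def detect_r_peaks(ecg_filtered: np.ndarray, fs: float) -> BeatAnnotations:
    """Two-pass template-matching R-peak detection.

    Raises :class:`SignalUnusableError` on signals without a coherent beat
    morphology (e.g. pure noise).  Requires at least 10 s of signal.
    """
    x = np.asarray(ecg_filtered, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    peaks = _template_pass(x, fs, ECG_REFRACTORY_S, ECG_TEMPLATE_HALF_S)
    return BeatAnnotations(event_times=peaks / fs)


def detect_breath_peaks(breathing: np.ndarray, fs: float) -> BeatAnnotations:
    """Inhalation-peak detection: 2-s moving-mean smoothing, then the same
    two-pass template scheme with a 1.5 s refractory period."""
    x = np.asarray(breathing, dtype=float)
    if x.size < 20 * fs:
        raise ValueError("need at least 20 s of breathing signal")
    if x.std() < 1e-12:
        raise SignalUnusableError("flat breathing signal")
    sm = moving_mean(x, int(round(2.0 * fs)))
    peaks = _template_pass(sm, fs, BREATH_REFRACTORY_S, BREATH_TEMPLATE_HALF_S)
    return BeatAnnotations(event_times=peaks / fs)


# ---------------------------------------------------------------------------
# Ectopic intervals
# ---------------------------------------------------------------------------

def detect_ectopic(annotations: BeatAnnotations) -> np.ndarray:
    """Indices of ectopic intervals.

    A candidate is a local maximum of |dIBI| (the derivative of the
    interval series) whose magnitude exceeds median + 4*MAD of |dIBI|; of
    the two intervals adjoining the jump, the one deviating more from the
    median interval is flagged.
    """
    ibi = annotations.ibi
    if ibi.size < 4:
        raise ValueError("need at least 4 intervals")
    d = np.diff(ibi)  # d[j] = ibi[j+1] - ibi[j]
    ad = np.abs(d)
    med = np.median(ad)
    mad = np.median(np.abs(ad - med))
    # 1 ns floor guards against float dust on otherwise constant trains
    thr = med + ECTOPIC_MAD_FACTOR * mad + 1e-9
    ibi_med = np.median(ibi)
    flagged: set[int] = set()
    for j in range(ad.size):
        left = ad[j - 1] if j > 0 else -np.inf
        right = ad[j + 1] if j + 1 < ad.size else -np.inf
        if ad[j] > thr and ad[j] >= left and ad[j] >= right:
            a, b = j, j + 1  # intervals adjoining the jump
            pick = a if abs(ibi[a] - ibi_med) >= abs(ibi[b] - ibi_med) else b
            flagged.add(pick)
    return np.array(sorted(flagged), dtype=int)


def correct_ectopic(annotations: BeatAnnotations, indices: np.ndarray) -> BeatAnnotations:
    """Replace flagged IBIs by cubic interpolation over unflagged neighbors
    and rebuild the event times cumulatively from the first event.

    Deterministic replacement for the manual interpolation step of an
    interactive review; unflagged intervals are never altered.
    """
    ibi = annotations.ibi.copy()
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        return BeatAnnotations(
            event_times=annotations.event_times.copy(),
            ectopic_flags=annotations.ectopic_flags.copy(),
            corrected=annotations.corrected.copy(),
        )
    if np.any(indices < 0) or np.any(indices >= ibi.size):
        raise IndexError("ectopic index out of range")
    good = np.setdiff1d(np.arange(ibi.size), indices)
    if good.size == 0:
        raise ValueError("all intervals flagged: uncorrectable record")
    if good.size >= 4:
        interp = CubicSpline(good, ibi[good])
    else:
        interp = interp1d(good, ibi[good], kind="linear", fill_value="extrapolate")
    ibi[indices] = np.maximum(interp(indices), 1e-6)
    times = annotations.event_times[0] + np.concatenate([[0.0], np.cumsum(ibi)])
    ectopic = annotations.ectopic_flags.copy()
    ectopic[indices] = True
    corrected = annotations.corrected.copy()
    corrected[indices] = True
    return BeatAnnotations(event_times=times, ectopic_flags=ectopic, corrected=corrected)
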