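"""fNIRS processing: Beer–Lambert conversion, filtering, connectivity and
breathing-response extraction.

Dual-wavelength (760/840 nm) light intensities are converted to optical
densities, then to oxygenated-hemoglobin concentration changes (dHbO, uM)
with the modified Beer–Lambert law (MBLL).  Channels are band-pass filtered
at 0.05–0.6 Hz (Butterworth order 3, zero-phase) to remove cardiac pulse
and very slow drifts.  Functional connectivity is the channel-by-channel
Spearman matrix summarized per channel by the median over its off-diagonal
row.  The breathing-locked component of the hemodynamics is extracted by
PCA over the z-scored 23 HbO channels plus the breathing signal: principal
components whose maximum-|rho| lagged Spearman correlation with breathing
(lags -30..30 s) exceeds 0.6 are back-projected onto the channels and
summed into a per-channel breathing response, whose lag against the
chest-belt breathing is then measured the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import rankdata

__all__ = [
    "EXTINCTION",
    "HBR_TO_HBO_RATIO",
    "OpticalDensitySeries",
    "HbOSeries",
    "ConnectivityResult",
    "BreathingResponse",
    "intensities_to_od",
    "od_to_hbo",
    "mbll_forward",
    "filter_fnirs",
    "channel_connectivity",
    "extract_breathing_response",
    "breathing_response_lag",
    "lagged_spearman",
]

#: Molar extinction coefficients (cm^-1 M^-1) for HbO2 / HHb at the two
#: instrument wavelengths; standard compiled hemoglobin spectra
#: (Gratzer/Prahl tabulation).
EXTINCTION = {
    760.0: (586.0, 1548.5),  # (HbO2, HHb)
    840.0: (1058.0, 693.0),
}
WAVELENGTHS_NM = (760.0, 840.0)

#: Fixed dHbR/dHbO ratio used by the synthetic forward model; analysis keeps
#: dHbR internal and reports HbO only.
HBR_TO_HBO_RATIO = -0.3

DEFAULT_DPF = 6.0
DEFAULT_DISTANCE_CM = 3.5
COMPONENT_RHO_THRESHOLD = 0.6
DEFAULT_LAG_RANGE_S = (-30.0, 30.0)


def _extinction_matrix() -> np.ndarray:
    return np.array([EXTINCTION[w] for w in WAVELENGTHS_NM])  # (2 wl, 2 species)


@dataclass
class OpticalDensitySeries:
    """Unitless optical densities per channel and wavelength at 50 Hz."""

    od: np.ndarray  # (n_channels, 2, n) at 760/840 nm
    fs: float = 50.0
    distance_cm: float = DEFAULT_DISTANCE_CM


@dataclass
class HbOSeries:
    hbo: np.ndarray  # (n_channels, n), uM
    fs: float = 50.0
    dpf: float = DEFAULT_DPF


@dataclass
class ConnectivityResult:
    matrix: np.ndarray  # (n_channels, n_channels) Spearman
    per_channel_median: np.ndarray  # median over off-diagonal row entries


@dataclass
class BreathingResponse:
    response: np.ndarray  # (n_channels, n); zeros when empty
    selected_components: list[tuple[int, float, float]]  # (index, rho, lag_s)
    lag_per_channel: np.ndarray | None = None
    empty: bool = False
    fs: float = 50.0


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def intensities_to_od(intensity: np.ndarray, fs: float = 50.0,
                      distance_cm: float = DEFAULT_DISTANCE_CM) -> OpticalDensitySeries:
    """OD(t) = -log10(I(t) / mean(I)) per channel and wavelength."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("light intensities must be strictly positive")
    mean = intensity.mean(axis=-1, keepdims=True)
    od = -np.log10(intensity / mean)
    return OpticalDensitySeries(od=od, fs=fs, distance_cm=distance_cm)


def mbll_forward(hbo_um: np.ndarray, hbr_um: np.ndarray,
                 dpf: float = DEFAULT_DPF,
                 distance_cm: float = DEFAULT_DISTANCE_CM) -> np.ndarray:
    """Forward Beer–Lambert map: concentration changes (uM) -> OD changes.

    Used by the synthetic generator so that the inversion in
    :func:`od_to_hbo` is exercised on consistent coefficients.
    """
    E = _extinction_matrix()  # (2 wl, 2 species)
    conc = np.stack([hbo_um, hbr_um], axis=-2) * 1e-6  # (..., 2 species, n), M
    return np.einsum("ws,...sn->...wn", E, conc) * distance_cm * dpf


def od_to_hbo(od: OpticalDensitySeries, dpf: float = DEFAULT_DPF,
              distance_cm: float | None = None) -> HbOSeries:
    """Invert the 2x2 MBLL system per sample; returns dHbO in uM.

    dHbR is solved alongside but not analyzed further.
    """
    if distance_cm is None:
        distance_cm = od.distance_cm
    E = _extinction_matrix() * distance_cm * dpf
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("singular extinction matrix: bad wavelength pair")
    Einv = np.linalg.inv(E)
    conc = np.einsum("sw,cwn->csn", Einv, od.od) * 1e6  # uM
    return HbOSeries(hbo=conc[:, 0, :], fs=od.fs, dpf=dpf)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_fnirs(hbo: HbOSeries, band: tuple[float, float] = (0.05, 0.6),
                 order: int = 3) -> HbOSeries:
    """Zero-phase Butterworth band-pass (default order 3, 0.05–0.6 Hz):
    removes cardiac pulse (~1.2 Hz) and very slow systemic drifts."""
    if hbo.fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the upper band edge")
    sos = sps.butter(order, band, btype="band", fs=hbo.fs, output="sos")
    return HbOSeries(hbo=sps.sosfiltfilt(sos, hbo.hbo, axis=-1), fs=hbo.fs, dpf=hbo.dpf)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def channel_connectivity(hbo: HbOSeries) -> ConnectivityResult:
    """Pairwise Spearman correlation over the segment for all channel pairs.

    Per-channel summary is the median over the off-diagonal entries of the
    channel's row.  Requires at least 30 s of signal.
    """
    x = hbo.hbo
    if x.shape[-1] < 30 * hbo.fs:
        raise ValueError("connectivity needs a segment of at least 30 s")
    ranks = np.apply_along_axis(rankdata, -1, x)
    ranks = ranks - ranks.mean(axis=-1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=-1))
    matrix = (ranks @ ranks.T) / np.outer(norm, norm)
    matrix = np.clip(matrix, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    nc = matrix.shape[0]
    off = matrix[~np.eye(nc, dtype=bool)].reshape(nc, nc - 1)
    return ConnectivityResult(matrix=matrix, per_channel_median=np.median(off, axis=1))


# ---------------------------------------------------------------------------
# Lagged Spearman utilities
# ---------------------------------------------------------------------------

def _spearman(u: np.ndarray, v: np.ndarray) -> float:
    ru = rankdata(u)
    rv = rankdata(v)
    ru -= ru.mean()
    rv -= rv.mean()
    den = np.sqrt((ru @ ru) * (rv @ rv))
    if den == 0:
        return np.nan
    return float((ru @ rv) / den)


def lagged_spearman(
    reference: np.ndarray,
    signal_: np.ndarray,
    fs: float,
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S,
    lag_step_s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlation of ``signal_(t + lag)`` against ``reference(t)``
    over a lag grid; positive lag means the signal follows the reference.

    ``signal_`` may be 2-D (one row per signal); the reference-segment ranks
    are then shared across rows.  Correlations use the overlapping segment
    only (no padding).
    """
    was_1d = np.asarray(signal_).ndim == 1
    signal_ = np.atleast_2d(np.asarray(signal_, float))
    n = min(reference.size, signal_.shape[-1])
    reference = np.asarray(reference, float)[:n]
    signal_ = signal_[:, :n]
    step = max(1, int(round(lag_step_s * fs)))
    k_min = int(np.ceil(lag_range_s[0] * fs / step))
    k_max = int(np.floor(lag_range_s[1] * fs / step))
    lags = np.arange(k_min, k_max + 1) * step
    m = signal_.shape[0]
    rho = np.full((m, lags.size), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            u, v = reference[: n - k], signal_[:, k:]
        else:
            u, v = reference[-k:], signal_[:, : n + k]
        if u.size < 4:
            continue
        ru = rankdata(u)
        ru = ru - ru.mean()
        nu = np.sqrt(ru @ ru)
        if nu == 0:
            continue
        rv = np.apply_along_axis(rankdata, -1, v)
        rv = rv - rv.mean(axis=-1, keepdims=True)
        nv = np.sqrt((rv**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[:, i] = (rv @ ru) / (nv * nu)
    lags_s = lags / fs
    return (lags_s, rho[0]) if was_1d else (lags_s, rho)


def _max_abs_rho(lags_s: np.ndarray, rho: np.ndarray) -> tuple[float, float]:
    finite = np.isfinite(rho)
    if not finite.any():
        raise ValueError("correlation undefined at every lag (constant input?)")
    idx = np.nanargmax(np.abs(np.where(finite, rho, 0.0)))
    return float(rho[idx]), float(lags_s[idx])


# ---------------------------------------------------------------------------
# Breathing response (PCA)
# ---------------------------------------------------------------------------

def extract_breathing_response(
    hbo: HbOSeries,
    breathing: np.ndarray,
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S,
    rho_threshold: float = COMPONENT_RHO_THRESHOLD,
    lag_step_s: float = 0.25,
    include_breathing_column: bool = True,
) -> BreathingResponse:
    """PCA separation of the breathing-locked hemodynamic component.

    The z-scored channel matrix (plus, by default, the z-scored breathing
    signal as a 24th column) is decomposed by SVD; each component score is
    lag-correlated (Spearman, lags -30..30 s) against breathing, and
    components whose maximum |rho| exceeds the 0.6 threshold are
    back-projected onto the 23 channel columns only (reconstructing the
    breathing column itself would be circular) and summed.  The response is
    returned in channel units (per-channel sd restored, mean excluded).

    When no component passes the threshold the result is all-zero and
    flagged ``empty`` rather than raising.
    """
    x = hbo.hbo
    nc, n = x.shape
    if n < 100 * hbo.fs / 50.0 and n < 100:
        raise ValueError("segment too short for component extraction")
    breathing = np.asarray(breathing, dtype=float)[:n]
    if breathing.size != n:
        raise ValueError("breathing must cover the HbO segment at the same rate")

    def zscore(a):
        sd = a.std(axis=-1, keepdims=True)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return (a - a.mean(axis=-1, keepdims=True)) / sd

    xz = zscore(x)
    cols = np.vstack([xz, zscore(breathing[None, :])]) if include_breathing_column else xz

    # correlation-matrix PCA via SVD of the (n, p) z-scored matrix
    u, s, vt = np.linalg.svd(cols.T, full_matrices=False)
    scores = u * s  # (n, p) component time courses

    live = np.nonzero(s > 1e-10)[0]
    lags_s, rho_all = lagged_spearman(breathing, scores[:, live].T, hbo.fs,
                                      lag_range_s, lag_step_s)
    selected: list[tuple[int, float, float]] = []
    for row, k in enumerate(live):
        rho = rho_all[row]
        if not np.isfinite(rho).any():
            continue
        if include_breathing_column and vt[k, -1] ** 2 > 0.5:
            # component dominated by the breathing column itself: it is the
            # reference, not shared hemodynamics, and selecting it would be
            # circular
            continue
        r, lag = _max_abs_rho(lags_s, rho)
        if abs(r) > rho_threshold:
            selected.append((int(k), r, lag))

    if not selected:
        return BreathingResponse(
            response=np.zeros_like(x),
            selected_components=[],
            empty=True,
            fs=hbo.fs,
        )

    idx = [k for k, _, _ in selected]
    recon_z = scores[:, idx] @ vt[idx, :nc]  # (n, nc) in z-units
    sd = x.std(axis=-1, keepdims=True)
    response = recon_z.T * sd
    return BreathingResponse(
        response=response,
        selected_components=selected,
        empty=False,
        fs=hbo.fs,
    )


def breathing_response_lag(
    response: BreathingResponse,
    breathing: np.ndarray,
    lag_range_s: tuple[float, float] = DEFAULT_LAG_RANGE_S,
    lag_step_s: float = 0.25,
) -> np.ndarray:
    """Per-channel lag (s) of the maximum-|rho| Spearman correlation of the
    reconstructed breathing response against the chest-belt breathing."""
    if response.empty:
        raise ValueError("cannot compute lags of an empty breathing response")
    breathing = np.asarray(breathing, dtype=float)
    lags_s, rho_all = lagged_spearman(breathing, response.response, response.fs,
                                      lag_range_s, lag_step_s)
    lags = np.empty(response.response.shape[0])
    for c in range(lags.size):
        _, lags[c] = _max_abs_rho(lags_s, rho_all[c])
    return lags
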