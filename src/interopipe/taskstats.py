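"""Task-level markers and the statistical layer.

Heartbeat-counting accuracy is the printed percentage-error form

    accuracy = 1 - (beats_ecg - beats_counted) / beats_ecg

(no absolute value, so over-counting scores above 1; an absolute variant is
available behind a flag), averaged over the six counting trials per
subject.  Transition analyses align a marker series on task transitions,
z-score each subject's trial average over the full window, and aggregate
across subjects by median and (unscaled) median absolute deviation.

Group inference uses the Wilcoxon signed-rank test in its tie-corrected
normal approximation with a signed z, corrected by a Monte-Carlo sign-flip
permutation test (10,000 permutations; p_mc = (1 + #{p_perm <= p_obs}) /
(n_perm + 1)), the Friedman test across paced-rate conditions, Spearman
correlations with Student-t p-values, and Bonferroni correction over the
23 fNIRS channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from scipy.stats import rankdata

from .beats import moving_mean
from .rates import RateSeries

__all__ = [
    "TrialEpochSet",
    "StatOutcome",
    "counting_accuracy",
    "align_transitions",
    "group_median_mad",
    "wilcoxon_signed_rank",
    "monte_carlo_correct",
    "friedman_test",
    "spearman_p",
    "spearman_p_from_rho",
    "bonferroni_channels",
]

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05
N_FNIRS_CHANNELS = 23
ZERO_VARIANCE_SD = 1e-12


@dataclass
class TrialEpochSet:
    """One subject's transition-aligned epochs.

    ``aligned`` holds one row per trial on the relative grid ``rel_t``;
    ``average`` is the trial mean, z-scored over the full window when
    ``normalized`` (zero-variance averages are emitted as zeros and
    flagged, not NaN).
    """

    aligned: np.ndarray  # (n_trials, n_samples)
    rel_t: np.ndarray  # s, relative to the transition
    window: tuple[float, float]
    average: np.ndarray
    normalized: bool
    zero_variance: bool = False
    n_dropped: int = 0

    def pre_post_means(self) -> tuple[float, float]:
        """Mean of the (z-scored) subject average before and after the
        transition; with a symmetric window these are exact negatives."""
        pre = self.average[self.rel_t < 0]
        post = self.average[self.rel_t > 0]
        return float(pre.mean()), float(post.mean())


def counting_accuracy(counted: int | np.ndarray, ecg_beats: int | np.ndarray,
                      absolute_error: bool = False) -> float | np.ndarray:
    """Heartbeat-counting accuracy from the percentage counting error."""
    counted = np.asarray(counted, dtype=float)
    ecg_beats = np.asarray(ecg_beats, dtype=float)
    if np.any(ecg_beats <= 0):
        raise ValueError("ecg_beats must be positive")
    if np.any(counted < 0):
        raise ValueError("counted heartbeats cannot be negative")
    err = (ecg_beats - counted) / ecg_beats
    if absolute_error:
        err = np.abs(err)
    out = 1.0 - err
    return float(out) if out.ndim == 0 else out


def align_transitions(
    marker: RateSeries,
    transition_times: np.ndarray,
    window: tuple[float, float],
    normalize: bool = True,
    smooth_s: float | None = None,
) -> TrialEpochSet:
    """Extract per-trial epochs of ``marker`` around each transition and
    average them into one subject-level curve.

    Transitions without full window coverage are dropped with a warning.
    z-scoring (mean 0, sd 1 over the full window) is applied to the trial
    average; an optional moving-mean smoothing (e.g. 10 s for display) is
    applied before normalization.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must be an increasing interval")
    fs = marker.fs
    # bin-center convention: no sample sits exactly on the transition, so a
    # symmetric window has equal pre- and post-halves
    rel_t = (np.arange(round(t0 * fs), round(t1 * fs)) + 0.5) / fs
    epochs = []
    dropped = 0
    for tr in np.atleast_1d(np.asarray(transition_times, dtype=float)):
        tt = tr + rel_t
        if tt[0] < marker.t[0] - 1e-9 or tt[-1] > marker.t[-1] + 1e-9:
            dropped += 1
            warnings.warn(f"transition at {tr:.1f} s lacks full window coverage; dropped")
            continue
        epochs.append(np.interp(tt, marker.t, marker.value))
    if not epochs:
        raise ValueError("no transition had full window coverage")
    aligned = np.vstack(epochs)
    average = aligned.mean(axis=0)
    if smooth_s is not None:
        average = moving_mean(average, max(1, int(round(smooth_s * fs))))
    zero_var = False
    if normalize:
        sd = average.std()
        if sd < ZERO_VARIANCE_SD:
            average = np.zeros_like(average)
            zero_var = True
        else:
            average = (average - average.mean()) / sd
    return TrialEpochSet(
        aligned=aligned,
        rel_t=rel_t,
        window=window,
        average=average,
        normalized=normalize,
        zero_variance=zero_var,
        n_dropped=dropped,
    )


def group_median_mad(values: np.ndarray) -> tuple[float, float]:
    """Group median and unscaled median absolute deviation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

@dataclass
class StatOutcome:
    statistic: float
    z: float | None
    p: float
    p_mc: float | None = None
    significant: bool = False
    correction: str = "none"  # {"none", "monte_carlo", "bonferroni_23"}


def _signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Tie-corrected signed-rank machinery shared by the test and its
    permutation correction.

    Returns (W_plus, mu, sigma, ranks_of_abs_diffs) after dropping zero
    differences.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(r, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    signed_r = np.where(d > 0, r, 0.0)
    return w_plus, mu, np.sqrt(var), r * np.sign(d)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> StatOutcome:
    """Paired Wilcoxon signed-rank test, normal approximation.

    z is signed (positive when x tends to exceed y) with tie-corrected
    variance; p is two-sided.  Zero differences are dropped; at least five
    non-zero pairs are required.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.count_nonzero(d) < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    w_plus, mu, sigma, _ = _signed_rank(x, y)
    z = (w_plus - mu) / sigma
    p = 2.0 * spstats.norm.sf(abs(z))
    return StatOutcome(statistic=w_plus, z=float(z), p=float(min(p, 1.0)),
                       significant=p <= DEFAULT_ALPHA)


def monte_carlo_correct(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = 0,
) -> StatOutcome:
    """Monte-Carlo permutation correction of the paired Wilcoxon p.

    The exchangeability structure of a paired design is the sign of each
    difference, so each permutation randomly flips the signs of the paired
    differences and recomputes the normal-approximation p.  The corrected
    p uses the add-one estimator p_mc = (1 + #{p_perm <= p_obs}) /
    (n_perm + 1), which cannot be zero.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    obs = wilcoxon_signed_rank(x, y)
    _, mu, sigma, signed_r = _signed_rank(x, y)
    r_abs = np.abs(signed_r)
    rng = np.random.default_rng(seed)
    flips = rng.random((n_perm, r_abs.size)) < 0.5
    # W+ under sign flips is linear in the flip pattern; |z| orders exactly
    # like the two-sided normal-approximation p
    w_perm = flips @ r_abs
    z_perm = (w_perm - mu) / sigma
    p_perm = 2.0 * spstats.norm.sf(np.abs(z_perm))
    p_mc = (1.0 + np.count_nonzero(p_perm <= obs.p + 1e-12)) / (n_perm + 1.0)
    return StatOutcome(statistic=obs.statistic, z=obs.z, p=obs.p, p_mc=float(p_mc),
                       significant=p_mc <= alpha, correction="monte_carlo")


def friedman_test(data: np.ndarray) -> StatOutcome:
    """Friedman chi-square across conditions (columns) for paired subjects
    (rows), with tie correction; p from the chi-square distribution."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a (subjects x conditions) matrix, both >= 2")
    if np.isnan(data).any():
        raise ValueError("complete cases required")
    if np.all(data == data[:, [0]]):
        # identical conditions: statistic 0, p 1 (scipy raises here)
        return StatOutcome(statistic=0.0, z=None, p=1.0)
    stat, p = spstats.friedmanchisquare(*data.T)
    return StatOutcome(statistic=float(stat), z=None, p=float(p),
                       significant=p <= DEFAULT_ALPHA)


def spearman_p(x: np.ndarray, y: np.ndarray) -> StatOutcome:
    """Spearman correlation with the Student-t approximation for its p-value:
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need paired samples with n >= 4")
    rx = rankdata(x) - (n + 1) / 2.0
    ry = rankdata(y) - (n + 1) / 2.0
    den = np.sqrt((rx @ rx) * (ry @ ry))
    if den == 0:
        raise ValueError("correlation undefined for constant input")
    rho = float(np.clip((rx @ ry) / den, -1.0, 1.0))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * spstats.t.sf(abs(t), df=n - 2))
    return StatOutcome(statistic=rho, z=None, p=p, significant=p <= DEFAULT_ALPHA)


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided Student-t p-value for a given Spearman coefficient at
    sample size n (t = rho*sqrt((n-2)/(1-rho^2)), n-2 df)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * spstats.t.sf(abs(t), df=n - 2))


def bonferroni_channels(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA,
                        n_channels: int = N_FNIRS_CHANNELS) -> np.ndarray:
    """Per-channel significance flags at the Bonferroni-corrected level
    alpha / n_channels."""
    p_values = np.asarray(p_values, dtype=float)
    return p_values <= alpha / n_channels
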