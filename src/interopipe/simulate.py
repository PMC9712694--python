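"""Protocol-structured synthetic multimodal recordings with known ground truth.

Generates the signals an interoception study session produces — ECG and
breathing-belt traces at 250 Hz plus 23-channel dual-wavelength fNIRS at
50 Hz — following a fixed session structure: an initial rest, six
heartbeat-counting blocks of random 30–60 s duration each followed by a
report phase, and a paced-breathing task of four 5-step blocks
(0.1–0.2–0.4–0.2–0.1 Hz twice, then 0.15–0.3–0.4–0.3–0.15 Hz twice,
50 s per step) so that every paced rate occurs exactly four times.

Heartbeats come from an integral pulse frequency modulation (IPFM) model:
an instantaneous cardiac rate

    m(t) = mean_hr * (1 + rsa_gain * b(t - rsa_lag_s) + lf_gain * sin(2*pi*0.1*t))

is integrated and a beat is emitted at every integer crossing of the
integral.  ``b`` is the unit-normalized breathing waveform, so ``rsa_gain``
sets the depth of respiratory sinus arrhythmia and ``lf_gain`` a 0.1 Hz
Mayer-wave component.  ECG is a QRS-like template train placed at the beat
times; fNIRS channels mix a shared band-limited neural slow wave, a lagged
breathing component, a cardiac pulse train, and white noise, and are also
exported as forward-modelled optical densities at 760/840 nm so the
analysis-side Beer–Lambert inversion has real work to do.

Ground truth (beat times, breath-peak times, injected per-channel breathing
components) travels in a separate :class:`SimTruth` object that analysis
stages never receive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .fnirs import HBR_TO_HBO_RATIO, mbll_forward

__all__ = [
    "SimConfig",
    "ProtocolEvent",
    "ProtocolSchedule",
    "SimTruth",
    "MultiModalRecording",
    "generate_protocol",
    "simulate_breathing",
    "simulate_heartbeats",
    "synthesize_ecg",
    "simulate_fnirs",
    "simulate_recording",
]

#: Paced-breathing step sequences (Hz), 50 s per step.
PACED_BLOCK_A = (0.1, 0.2, 0.4, 0.2, 0.1)
PACED_BLOCK_B = (0.15, 0.3, 0.4, 0.3, 0.15)
PACED_STEP_S = 50.0

#: Fixed protocol timing (seconds).
INITIAL_REST_S = 180.0
POST_COUNTING_REST_S = 60.0
INTER_PACED_REST_S = 30.0
INTER_PAIR_REST_S = 60.0
FINAL_REST_S = 60.0
REPORT_GAP_S = 15.0
COUNTING_BLOCK_RANGE_S = (30.0, 60.0)
N_COUNTING_BLOCKS = 6


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    All gains are non-negative and ``rsa_gain + lf_gain < 1`` so the
    instantaneous cardiac rate stays positive.
    """

    duration_s: float | None = None  # None: derive from the schedule
    mean_hr: float = 1.2  # Hz, resting heart rate
    rsa_gain: float = 0.15  # fraction of rate modulation by breathing
    rsa_lag_s: float = 0.5  # breathing -> heart-rate delay, s
    lf_gain: float = 0.05  # 0.1 Hz Mayer-wave modulation depth
    breathing_mode: str = "paced"  # {"free", "paced"}
    free_breathing_rate: float = 0.24  # Hz
    breathing_jitter: float = 0.05  # relative sd of slow free-rate wander
    ecg_noise_sd: float = 0.05  # signal units (R amplitude = 1)
    hr_counting_drop_hz: float = 0.0  # HR decrease while counting heartbeats
    br_counting_drop_hz: float = 0.0  # breathing-rate decrease while counting
    fnirs_breathing_gain: np.ndarray | float = 0.5  # uM per channel
    fnirs_breathing_lag_s: np.ndarray | float = 5.0  # s per channel
    fnirs_neural_gain: float = 0.5  # uM, shared slow-wave amplitude
    fnirs_pulse_gain: float = 0.1  # uM
    fnirs_noise_sd: float = 0.1  # uM
    n_channels: int = 23
    fs_ecg: float = 250.0  # Hz (also breathing-belt rate)
    fs_fnirs: float = 50.0  # Hz
    dpf: float = 6.0
    sd_distance_cm: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if self.rsa_gain < 0 or self.lf_gain < 0:
            raise ValueError("modulation gains must be non-negative")
        if self.rsa_gain + self.lf_gain >= 1:
            raise ValueError("rsa_gain + lf_gain must stay below 1")
        if self.fs_ecg <= 2 * 45 or self.fs_fnirs <= 2 * self.mean_hr:
            raise ValueError("sampling rates violate the Nyquist margin")

    def channel_vector(self, value: np.ndarray | float) -> np.ndarray:
        v = np.broadcast_to(np.asarray(value, dtype=float), (self.n_channels,))
        return np.array(v, dtype=float)


@dataclass(frozen=True)
class ProtocolEvent:
    label: str  # {"rest", "counting", "report", "paced_step"}
    start_s: float
    end_s: float
    target_breathing_rate: float | None = None  # Hz, paced steps only
    counted_heartbeats: int | None = None  # counting blocks only
    confidence: int | None = None  # 1..9, counting blocks only

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolSchedule:
    events: tuple[ProtocolEvent, ...]

    @property
    def duration_s(self) -> float:
        return self.events[-1].end_s if self.events else 0.0

    def by_label(self, label: str) -> list[ProtocolEvent]:
        return [e for e in self.events if e.label == label]

    def paced_steps(self, rate: float | None = None) -> list[ProtocolEvent]:
        steps = self.by_label("paced_step")
        if rate is None:
            return steps
        return [e for e in steps if np.isclose(e.target_breathing_rate, rate)]

    def validate(self) -> None:
        t = 0.0
        for e in self.events:
            if e.start_s < t - 1e-9 or e.end_s <= e.start_s:
                raise ValueError("events must be non-overlapping and time-ordered")
            t = e.end_s


@dataclass
class SimTruth:
    """Ground truth carried alongside signals; never consumed by analysis."""

    beat_times: np.ndarray
    breath_peak_times: np.ndarray
    fnirs_breathing_components: np.ndarray | None = None  # (n_channels, n) uM
    fnirs_breathing_lag_s: np.ndarray | None = None
    rsa_gain: float | None = None
    rsa_lag_s: float | None = None


@dataclass
class MultiModalRecording:
    """Synchronized session signals; all series share time origin 0."""

    ecg: np.ndarray
    breathing: np.ndarray
    fs_ecg: float
    schedule: ProtocolSchedule
    fnirs_od: np.ndarray | None = None  # (n_channels, 2, n) at 760/840 nm
    fnirs_hbo: np.ndarray | None = None  # (n_channels, n) uM
    fs_fnirs: float | None = None
    truth: SimTruth | None = None


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

def generate_protocol(
    seed: int,
    mean_hr: float = 1.2,
    interoceptive_accuracy: float | None = None,
) -> ProtocolSchedule:
    """Build the session event schedule.

    Counting-block durations are drawn uniformly from 30–60 s; each block is
    followed by a fixed 15 s report gap in which the subject states the
    number of heartbeats counted and a 1–9 confidence rating.  Reported
    counts emulate a subject of the given interoceptive accuracy (drawn
    uniformly from 0.4–1.0 when not supplied), with confidence noisily
    tracking accuracy so cohort-level accuracy/confidence correlations are
    positive, as real cohorts show.
    """
    rng = np.random.default_rng(seed)
    if interoceptive_accuracy is None:
        interoceptive_accuracy = float(rng.uniform(0.4, 1.0))

    events: list[ProtocolEvent] = []
    t = 0.0

    def add(label, dur, **kw):
        nonlocal t
        events.append(ProtocolEvent(label, t, t + dur, **kw))
        t += dur

    add("rest", INITIAL_REST_S)
    for _ in range(N_COUNTING_BLOCKS):
        dur = float(rng.uniform(*COUNTING_BLOCK_RANGE_S))
        trial_acc = max(0.0, interoceptive_accuracy + float(rng.normal(0, 0.05)))
        counted = int(round(dur * mean_hr * trial_acc))
        conf = int(np.clip(round(9 * (interoceptive_accuracy + rng.normal(0, 0.1))), 1, 9))
        add("counting", dur, counted_heartbeats=counted, confidence=conf)
        add("report", REPORT_GAP_S)
    add("rest", POST_COUNTING_REST_S)

    def paced_block(rates):
        for r in rates:
            add("paced_step", PACED_STEP_S, target_breathing_rate=r)

    paced_block(PACED_BLOCK_A)
    add("rest", INTER_PACED_REST_S)
    paced_block(PACED_BLOCK_A)
    add("rest", INTER_PAIR_REST_S)
    paced_block(PACED_BLOCK_B)
    add("rest", INTER_PACED_REST_S)
    paced_block(PACED_BLOCK_B)
    add("rest", FINAL_REST_S)

    sched = ProtocolSchedule(tuple(events))
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# Breathing
# ---------------------------------------------------------------------------

def _breathing_phase(schedule: ProtocolSchedule, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous breathing frequency integrated to a cycle phase.

    Returns (time grid, phase in cycles).  Paced steps pin the frequency to
    the target rate; elsewhere the rate wanders slowly around
    ``free_breathing_rate`` (seeded, low-pass filtered jitter).  The phase
    accumulates continuously, so step transitions carry no waveform jump.
    """
    duration = config.duration_s if config.duration_s is not None else schedule.duration_s
    n = int(round(duration * config.fs_ecg))
    t = np.arange(n) / config.fs_ecg
    if n == 0:
        return t, np.empty(0)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    freq = np.full(n, config.free_breathing_rate)
    if config.breathing_jitter > 0:
        wander = rng.standard_normal(n)
        # ~0.02 Hz low-pass: slow drift of the spontaneous rate
        sos = sps.butter(2, 0.02, btype="low", fs=config.fs_ecg, output="sos")
        wander = sps.sosfiltfilt(sos, wander)
        sd = wander.std()
        if sd > 0:
            wander = wander / sd
        freq *= 1.0 + config.breathing_jitter * wander

    if config.br_counting_drop_hz:
        for e in schedule.by_label("counting"):
            i0, i1 = int(e.start_s * config.fs_ecg), int(e.end_s * config.fs_ecg)
            freq[i0:i1] = np.maximum(freq[i0:i1] - config.br_counting_drop_hz, 0.05)

    if config.breathing_mode == "paced":
        for e in schedule.by_label("paced_step"):
            i0, i1 = int(e.start_s * config.fs_ecg), int(e.end_s * config.fs_ecg)
            freq[i0:i1] = e.target_breathing_rate

    phase = np.cumsum(freq) / config.fs_ecg
    return t, phase


def simulate_breathing(schedule: ProtocolSchedule, config: SimConfig) -> np.ndarray:
    """Breathing-belt waveform on the ECG time grid, amplitude-normalized to 1.

    Each cycle is a raised cosine (smooth, plethysmography-like):
    ``w = 0.5 - 0.5*cos(2*pi*phase)`` with an inhalation peak per cycle.
    """
    _, phase = _breathing_phase(schedule, config)
    if phase.size == 0:
        return phase
    return 0.5 - 0.5 * np.cos(2 * np.pi * phase)


def _breath_peak_times(schedule: ProtocolSchedule, config: SimConfig) -> np.ndarray:
    """Ground-truth inhalation-peak times: phase crossings of k + 1/2 cycles."""
    t, phase = _breathing_phase(schedule, config)
    if phase.size == 0:
        return phase
    shifted = phase - 0.5
    k = np.floor(shifted)
    cross = np.nonzero(np.diff(k) >= 1)[0]
    # linear interpolation of the crossing instant
    target = k[cross] + 1
    frac = (target - shifted[cross]) / (shifted[cross + 1] - shifted[cross])
    return t[cross] + frac / config.fs_ecg


# ---------------------------------------------------------------------------
# Heartbeats (IPFM)
# ---------------------------------------------------------------------------

def simulate_heartbeats(
    breathing: np.ndarray,
    config: SimConfig,
    rate_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Beat times from the IPFM model.

    The instantaneous rate is integrated on the breathing grid (4 ms at the
    default 250 Hz) and a beat is emitted wherever the integral crosses a
    successive integer, with linear interpolation of the crossing time.
    ``rate_offset`` (Hz, same grid) lets callers superpose slow task-related
    rate shifts on top of the respiratory and Mayer-wave modulation.
    """
    if config.mean_hr <= 0:
        raise ValueError("mean_hr must be positive")
    b = np.asarray(breathing, dtype=float)
    n = b.size
    if n == 0:
        return np.empty(0)
    fs = config.fs_ecg
    t = np.arange(n) / fs

    bn = b - b.mean()
    amax = np.max(np.abs(bn)) if n else 0.0
    if amax > 0:
        bn = bn / amax
    lag_samples = int(round(config.rsa_lag_s * fs))
    if lag_samples > 0:
        bn = np.concatenate([np.zeros(lag_samples), bn[: n - lag_samples]])
    elif lag_samples < 0:
        bn = np.concatenate([bn[-lag_samples:], np.zeros(-lag_samples)])

    m = config.mean_hr * (1.0 + config.rsa_gain * bn + config.lf_gain * np.sin(2 * np.pi * 0.1 * t))
    if rate_offset is not None:
        m = m + np.asarray(rate_offset, dtype=float)
    m = np.maximum(m, 1e-6)

    integral = np.concatenate([[0.0], np.cumsum(m) / fs])
    k = np.floor(integral)
    cross = np.nonzero(np.diff(k) >= 1)[0]
    target = k[cross] + 1
    frac = (target - integral[cross]) / (integral[cross + 1] - integral[cross])
    return (cross + frac) / fs


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _qrs_template(fs: float) -> np.ndarray:
    """QRS-like complex, ~80 ms wide, unit R amplitude, with Q/S dips and a
    small T-wave so template matching faces realistic morphology."""
    tt = np.arange(-0.1, 0.35, 1.0 / fs)
    r = np.exp(-0.5 * (tt / 0.010) ** 2)
    q = -0.12 * np.exp(-0.5 * ((tt + 0.028) / 0.008) ** 2)
    s = -0.18 * np.exp(-0.5 * ((tt - 0.028) / 0.008) ** 2)
    t_wave = 0.12 * np.exp(-0.5 * ((tt - 0.22) / 0.04) ** 2)
    return r + q + s + t_wave


def synthesize_ecg(
    beat_times: np.ndarray,
    config: SimConfig,
    duration_s: float | None = None,
) -> np.ndarray:
    """Place a fixed QRS-like template at each beat time on the 250 Hz grid
    and add white noise of sd ``ecg_noise_sd`` (R amplitude is 1)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    fs = config.fs_ecg
    if duration_s is None:
        duration_s = config.duration_s
        if duration_s is None:
            duration_s = float(beat_times[-1]) + 1.0 if beat_times.size else 1.0
    n = int(round(duration_s * fs))
    ecg = np.zeros(n)
    tpl = _qrs_template(fs)
    tpl_peak = int(np.argmax(tpl))
    for bt in beat_times:
        i0 = int(round(bt * fs)) - tpl_peak
        a, b = max(i0, 0), min(i0 + tpl.size, n)
        if a < b:
            ecg[a:b] += tpl[a - i0 : b - i0]
    if config.ecg_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
        ecg = ecg + rng.normal(0, config.ecg_noise_sd, n)
    return ecg


# ---------------------------------------------------------------------------
# fNIRS forward model
# ---------------------------------------------------------------------------

def simulate_fnirs(
    breathing: np.ndarray,
    beat_times: np.ndarray,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel dHbO (uM) plus forward-modelled optical densities.

    Channel ``c`` mixes (i) a shared neural slow wave — three seeded
    band-limited 0.05–0.15 Hz latent processes mixed group-wise across the
    probe, (ii) the breathing waveform delayed by
    ``fnirs_breathing_lag_s[c]`` and scaled by ``fnirs_breathing_gain[c]``,
    (iii) a cardiac pulse bump train at the beat times, and (iv) white
    noise.  dHbR is fixed at ``HBR_TO_HBO_RATIO`` times dHbO and the pair is
    pushed through the same Beer–Lambert forward map the analysis side
    inverts.

    Returns ``(hbo, od, breathing_components)`` with shapes
    ``(n_channels, n)``, ``(n_channels, 2, n)``, ``(n_channels, n)``.
    """
    fs = config.fs_fnirs
    step = int(round(config.fs_ecg / fs))
    b = np.asarray(breathing, dtype=float)[::step]
    n = b.size
    nc = config.n_channels
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 43]))

    # unit-sd normalization: channel gains are the injected component's
    # amplitude in uM (standard deviation)
    bn = b - b.mean() if n else b
    sd = bn.std() if n else 0.0
    if sd > 0:
        bn = bn / sd

    gains = config.channel_vector(config.fnirs_breathing_gain)
    lags = config.channel_vector(config.fnirs_breathing_lag_s)

    # shared neural slow waves, group-wise mixing over three probe regions
    neural = np.zeros((nc, n))
    if config.fnirs_neural_gain > 0 and n > 50:
        sos = sps.butter(2, [0.05, 0.15], btype="band", fs=fs, output="sos")
        latents = sps.sosfiltfilt(sos, rng.standard_normal((3, n)), axis=-1)
        sd = latents.std(axis=-1, keepdims=True)
        latents = np.divide(latents, sd, out=np.zeros_like(latents), where=sd > 0)
        groups = np.minimum(np.arange(nc) * 3 // nc, 2)
        mix = 0.2 + 0.6 * np.eye(3)[groups]  # own region 0.8, others 0.2
        mix += 0.05 * rng.standard_normal((nc, 3))
        neural = config.fnirs_neural_gain * (mix @ latents)

    breathing_components = np.zeros((nc, n))
    for c in range(nc):
        k = int(round(lags[c] * fs))
        if k >= 0:
            shifted = np.concatenate([np.zeros(k), bn[: n - k]]) if k < n else np.zeros(n)
        else:
            shifted = np.concatenate([bn[-k:], np.zeros(min(-k, n))])[:n]
        breathing_components[c] = gains[c] * shifted

    pulse = np.zeros(n)
    if config.fnirs_pulse_gain > 0 and n:
        bump = np.exp(-0.5 * ((np.arange(-0.15, 0.15, 1 / fs)) / 0.05) ** 2)
        half = bump.size // 2
        for bt in np.asarray(beat_times, dtype=float):
            i0 = int(round(bt * fs)) - half
            a_, b_ = max(i0, 0), min(i0 + bump.size, n)
            if a_ < b_:
                pulse[a_:b_] += bump[a_ - i0 : b_ - i0]
        pulse *= config.fnirs_pulse_gain

    noise = rng.normal(0, config.fnirs_noise_sd, (nc, n)) if config.fnirs_noise_sd > 0 else 0.0
    hbo = neural + breathing_components + pulse[None, :] + noise

    hbr = HBR_TO_HBO_RATIO * hbo
    od = mbll_forward(hbo, hbr, dpf=config.dpf, distance_cm=config.sd_distance_cm)
    return hbo, od, breathing_components


# ---------------------------------------------------------------------------
# Full recording
# ---------------------------------------------------------------------------

def simulate_recording(
    config: SimConfig,
    schedule: ProtocolSchedule | None = None,
    with_fnirs: bool = True,
) -> MultiModalRecording:
    """Generate a complete session: schedule, breathing, IPFM beats, ECG and
    (optionally) fNIRS, with ground truth attached."""
    if schedule is None:
        schedule = generate_protocol(config.seed, mean_hr=config.mean_hr)
    breathing = simulate_breathing(schedule, config)

    rate_offset = None
    if config.hr_counting_drop_hz:
        n = breathing.size
        rate_offset = np.zeros(n)
        for e in schedule.by_label("counting"):
            i0, i1 = int(e.start_s * config.fs_ecg), int(e.end_s * config.fs_ecg)
            rate_offset[i0:i1] = -config.hr_counting_drop_hz

    beat_times = simulate_heartbeats(breathing, config, rate_offset=rate_offset)
    duration = config.duration_s if config.duration_s is not None else schedule.duration_s
    ecg = synthesize_ecg(beat_times, config, duration_s=duration)
    truth = SimTruth(
        beat_times=beat_times,
        breath_peak_times=_breath_peak_times(schedule, config),
        rsa_gain=config.rsa_gain,
        rsa_lag_s=config.rsa_lag_s,
    )
    rec = MultiModalRecording(
        ecg=ecg,
        breathing=breathing,
        fs_ecg=config.fs_ecg,
        schedule=schedule,
        truth=truth,
    )
    if with_fnirs:
        hbo, od, comp = simulate_fnirs(breathing, beat_times, config)
        rec.fnirs_hbo = hbo
        rec.fnirs_od = od
        rec.fs_fnirs = config.fs_fnirs
        truth.fnirs_breathing_components = comp
        truth.fnirs_breathing_lag_s = config.channel_vector(config.fnirs_breathing_lag_s)
    return rec
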