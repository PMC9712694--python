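# Methods

This note records the models implemented in `interopipe`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Generative model

### Protocol

A session is a fixed event schedule: 180 s rest; six heartbeat-counting
blocks with durations drawn uniformly from 30–60 s, each followed by a 15 s
report phase (the protocol specifies the counting durations but not the
report length; 15 s keeps every "not counting" window at least 30 s long
when combined with adjacent rest, which the transition contrasts need);
60 s rest; then the paced-breathing task as four five-step blocks —
0.1–0.2–0.4–0.2–0.1 Hz twice (separated by 30 s rest), then, after 60 s
rest, 0.15–0.3–0.4–0.3–0.15 Hz twice — each step 50 s, so every paced rate
occurs exactly four times and every transition twice. A final 60 s rest
guarantees window coverage for the last transitions. Reported heartbeat
counts and 1–9 confidence ratings are generated from a per-subject
interoceptive-accuracy parameter with trial-level noise, so cohort-level
accuracy/confidence correlations are positive as in real cohorts.

### Breathing

The belt signal is a raised cosine per respiratory cycle,
`w = 0.5 − 0.5·cos(2πφ(t))`, where the phase φ integrates an instantaneous
breathing frequency: the target rate inside paced steps, elsewhere a free
rate (default 0.24 Hz) modulated by a slow (< 0.02 Hz) random wander of
10% relative sd. Spontaneous breathing-rate variability of 10–20% is
typical for seated adults; 10% was fixed once as the generator's default.
Because the phase accumulates continuously, paced-step transitions carry no
waveform discontinuity. Inhalation-peak ground truth is the set of φ =
k + ½ crossings.

### Heartbeats (IPFM)

Beats are emitted where the running integral of the instantaneous cardiac
rate

    m(t) = mean_hr · (1 + rsa_gain · b(t − rsa_lag_s) + lf_gain · sin(2π·0.1·t))

crosses successive integers (`b` is the unit-normalized breathing
waveform). Integration runs on the 4 ms ECG grid with linear interpolation
of each crossing, accurate to well under 1 ms. `rsa_gain + lf_gain < 1`
keeps the rate positive. Defaults: mean_hr 1.2 Hz, rsa_gain 0.15, lf_gain
0.05, rsa_lag_s 0.5 s (the cohort pipeline draws per-subject lags around
10 s, the group-level latency scale of breathing-to-heart influence during
attention tasks). Optional task effects — a heart-rate drop and a
breathing-rate drop during counting blocks — are zero in `SimConfig` by
default (pure physiology); the cohort pipeline injects 0.05 Hz and 0.02 Hz
drops so transition contrasts have a realistic direction and magnitude.

### ECG and fNIRS forward models

ECG is a fixed QRS-like template (R width ≈ 20 ms with Q/S dips, a small
T-wave at +220 ms, unit R amplitude) placed at each beat time on the
250 Hz grid plus white noise (default sd 0.05). The T-wave is deliberately
included so template matching must reject secondary deflections.

Each fNIRS channel mixes (i) a shared "neural" slow wave — three seeded
band-limited 0.05–0.15 Hz latent processes mixed over three probe regions
(own-region weight 0.8, others 0.2), default amplitude 0.5 µM, (ii) the
breathing waveform delayed per channel and scaled to a configured µM sd
(channel gains are amplitudes of the injected component), (iii) a Gaussian
pulse bump at each beat time (0.1 µM), and (iv) white noise (0.1 µM).
ΔHbR is fixed at −0.3·ΔHbO — it exists only to make the two-wavelength
inversion non-trivial, since the analysis uses HbO exclusively — and the
pair is pushed through the Beer–Lambert forward map (extinction
coefficients below) to produce the optical densities the analysis inverts.

What the generator does **not** emulate: motion artifacts, electrode/optode
drift, scalp-coupling variation, stroke-volume effects, multi-lead ECG
morphology, arrhythmias beyond isolated ectopic-like interval outliers, or
any attention-dependent change in coupling strength. Tests passing on this
generator therefore demonstrate correctness of the analysis chain and
recoverability of known ground truth — not robustness to every artifact
class of real recordings.

## Analysis chain

### Filtering and detection

All filters are zero-phase (forward–backward `sosfiltfilt`); a causal
filter's group delay would bias every lag estimate downstream (the 10-s
coupling lag, fNIRS response latencies). The effective order doubling is
accepted. ECG: Butterworth order 4, 0.5–45 Hz. fNIRS: order 3,
0.05–0.6 Hz, which attenuates the ~1.2 Hz cardiac pulse by well over 10×.

R-peak detection is two-pass template matching: provisional peaks are
local maxima above half of a robust (90th-percentile) peak amplitude under
a 250 ms refractory period; the median beat template (±100 ms) is then
correlated against the signal (normalized sliding correlation) and peaks
re-picked where correlation exceeds 0.6, refined to the local signal
maximum. Two plausibility guards reject unusable signals: candidate
amplitudes must not fall below half the median candidate amplitude
(suppresses T-wave matches), and the detected train must be quasi-periodic
(MAD/median of intervals ≤ 0.5) — incoherent noise fails this. Breathing
uses the same scheme on a 2-s moving-mean smoothed signal with a 1.5 s
refractory and ±1.5 s template window. Thresholds come from physiological
bounds (HR < 240 bpm; breathing ≤ 0.4 Hz paced, < 0.67 Hz spontaneous).

Ectopic intervals: candidates are local maxima of |ΔIBI| exceeding
median + 4·MAD (+1 ns numerical floor); of the two intervals adjoining a
jump, the one farther from the median interval is flagged. A bare
local-maximum rule would flag every other interval, hence the robust
amplitude criterion. Flagged intervals are replaced by cubic interpolation
over unflagged neighbors and the event times rebuilt cumulatively —
a deterministic, reproducible stand-in for interactive manual correction.

### Rates and spectra

Instantaneous rate 1/IBI is assigned at each event time and cubically
resampled to a uniform 4 Hz grid (Nyquist comfortably above the 0.5 Hz
band of interest). Assigning the interval-average rate at the interval's
right endpoint delays the rate series by about half a mean IBI (~0.4 s at
1.2 Hz); this is the conventional construction and the bias is below the
0.5 s tolerance of the lag analyses, but it is the reason recovered
coupling lags sit at the upper edge of that tolerance.

HRV spectra use the uniformly resampled IBI series (interval, not rate —
the conventional HRV choice; at these modulation depths the two differ
negligibly), mean-removed, fitted by Burg's recursion at order 16. The
implementation returns the reflection coefficients (all in (−1,1) for a
valid model) and is cross-checked in tests against
`statsmodels.regression.linear_model.burg` and an FFT periodogram. The
one-sided PSD is evaluated on a 1024-point grid from 0 to Nyquist
(bin ≈ 0.002 Hz at 4 Hz), and the dominant frequency is the PSD maximum
strictly inside 0–0.5 Hz, ties toward the lower frequency; when the global
maximum lies outside the band the result carries a low-confidence flag.

### Coupling

The cardiorespiratory statistic is Spearman correlation between breathing
and the 2-s-smoothed heart-rate series at every lag on the resampling grid
(0.25 s) in −30…+30 s, computed on the overlapping segment only. Sign
convention: positive lag means heart-rate changes follow breathing
changes, so a breathing→heart delay of 10 s reports +10 s. The smoothing
window is mean-preserving (exact re-centering after edge-truncated moving
average). The surrogate threshold is the 95th percentile of |ρ_max| over
circular shifts of breathing by ≥ 30 s: shifts preserve marginals and
autocorrelation while destroying alignment. For strongly periodic
breathing with little rate variability the surrogate distribution is
itself high — lag-resolved coupling against a periodic reference is only
identifiable up to cycle ambiguity, which is also why per-channel fNIRS
lags are only interpretable when the lag spread is within one respiratory
cycle.

### fNIRS conversion and breathing response

The Beer–Lambert inversion solves the 2×2 system per sample with molar
extinction coefficients from the standard compiled hemoglobin spectra
(Gratzer/Prahl): ε(HbO₂, HHb) = (586, 1548.5) cm⁻¹M⁻¹ at 760 nm and
(1058, 693) cm⁻¹M⁻¹ at 840 nm, source–detector distance 3.5 cm, DPF 6.0.
Any consistent coefficient choice only rescales ΔHbO and cannot change the
rank-based (Spearman) results downstream.

The breathing response uses correlation-matrix PCA (z-scored columns —
channels and breathing are in incommensurable units): SVD of the 24-column
matrix of 23 HbO channels plus breathing. Each component score is
lag-correlated (Spearman, −30…30 s) against breathing; components with
max |ρ| > 0.6 are kept and back-projected onto the 23 channel columns only
(per-channel sd restored). Two design points: (1) components whose squared
loading on the breathing column exceeds 0.5 are excluded — such a
component *is* the reference and selecting it would be circular; this also
makes the null case (no injected breathing in the channels) come out empty
rather than always selecting the breathing column's own component.
(2) When nothing passes the threshold the result is an all-zero response
flagged `empty`, not an error. The breathing column is included in the PCA
by default (`include_breathing_column=False` gives the channels-only
variant).

### Statistics

* Group dispersion is the **unscaled** MAD (no 1.4826 normal-consistency
  factor) — a descriptive spread, matching the small dispersions that
  median ± MAD summaries of rate data produce.
* Wilcoxon signed-rank uses the tie-corrected normal approximation with a
  **signed** z (positive when the first sample tends to exceed the
  second); zero differences are dropped and at least five non-zero pairs
  are required. The normal approximation tracks the exact sign-flip
  distribution to ≤ 0.02 in the decision-relevant tail; at n = 6 its
  mid-range p-values deviate from exact enumeration by up to ~0.1, an
  intrinsic property of the approximation.
* Monte-Carlo correction randomly flips the signs of the paired
  differences (the exchangeability structure of a paired design),
  recomputes the approximation p per permutation, and reports
  p_mc = (1 + #{p_perm ≤ p_obs})/(n_perm + 1) — the add-one estimator
  cannot return zero. Because W⁺ is linear in the sign pattern, the 10,000
  permutations are a single matrix product; 1000-cohort calibration runs
  in seconds and the realized type-I error sits inside [0.03, 0.07] at
  α = 0.05.
* Transition epochs use a bin-center grid (no sample on the transition
  itself), so a symmetric window has exactly equal halves and the
  z-scored subject average satisfies pre-mean = −post-mean identically.
  Zero-variance epochs are emitted as zeros with a flag, never NaN.
* Counting accuracy is the signed percentage-error form (over-counting
  scores above 1); an absolute-value variant exists behind
  `absolute_error=True` but is not the default. Per-subject scores average
  the six trials; repeated transitions are averaged per subject before any
  group test, never pooled as independent samples.
* Friedman's test (scipy, tie-corrected) compares rest against the five
  paced rates; Spearman p-values use the Student-t approximation
  t = ρ√((n−2)/(1−ρ²)); channel-wise tests are Bonferroni-corrected at
  α = 0.05/23.

## Problem sizes

Validation runs use sizes chosen to make the checks statistically
meaningful while staying desk-scale: 19-subject cohorts (12 with fNIRS)
for group analyses, 300 s records for coupling and component recovery,
100 seeded 60 s records for detector sensitivity/PPV, 1000 null cohorts ×
10,000 permutations for calibration, and exact enumeration at n ≤ 10
pairs (2⁸ patterns for the Monte-Carlo cross-check).

## Known limitations

* Coupling lags (and fNIRS response lags) are identifiable only modulo the
  respiratory cycle when breathing is nearly periodic; the surrogate
  threshold quantifies, but cannot remove, this ambiguity.
* The rate series inherits a ~half-IBI assignment delay (above).
* The PCA separator assumes the breathing-locked subspace is
  low-dimensional; channels with widely spread lags under fast breathing
  mix across components and per-channel recovery degrades.
* The smoothed-noise rejection guard in breath-peak detection accepts any
  quasi-periodic slow signal — a 2-s-smoothed noise process is
  indistinguishable in principle from irregular breathing.
* Group tables from the synthetic cohort reproduce the *structure* of a
  real study's results (directions, frequency locking, antisymmetric
  transition contrasts); absolute coupling levels depend on the generator's
  RSA gain and noise settings and are not calibrated to any particular
  population.
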