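"""End-to-end study orchestration on a synthetic cohort.

``run_study`` simulates (or loads) a cohort of protocol-structured
recordings, runs every analysis stage — beat and breath detection, rate
series, Burg spectra, cardiorespiratory coupling, fNIRS connectivity and
breathing response, task statistics — and emits the group-level result
tables: condition medians of heart/breathing rate and their ratio,
transition z-score contrasts, paced-breathing dominant frequencies, and
cardiorespiratory correlation per condition, each with paired Wilcoxon
tests under Monte-Carlo permutation correction.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beats import correct_ectopic, detect_breath_peaks, detect_ectopic, detect_r_peaks, filter_ecg
from .cardioresp import cardioresp_correlation, resample_to_grid
from .fnirs import (
    HbOSeries,
    breathing_response_lag,
    channel_connectivity,
    extract_breathing_response,
    filter_fnirs,
    od_to_hbo,
    OpticalDensitySeries,
)
from .io import PipelineConfig, write_recording
from .rates import RateSeries, burg_psd, ibi_series, ibi_to_rate, main_frequency, rate_ratio, smooth_rate
from .simulate import MultiModalRecording, SimConfig, simulate_recording
from .taskstats import (
    align_transitions,
    counting_accuracy,
    group_median_mad,
    monte_carlo_correct,
    spearman_p,
)

__all__ = ["StudyResults", "subject_sim_config", "analyze_subject", "run_study"]

#: Transition pairs analyzed in the paced task: (from_rate, to_rate).
SLOWER_TO_FASTER = ((0.1, 0.2), (0.15, 0.3), (0.2, 0.4), (0.3, 0.4))
FASTER_TO_SLOWER = ((0.2, 0.1), (0.3, 0.15), (0.4, 0.2), (0.4, 0.3))
PACED_RATES = (0.1, 0.15, 0.2, 0.3, 0.4)


@dataclass
class StudyResults:
    subjects: pd.DataFrame  # tidy per-subject metrics
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False, float_format="%.6g")
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        return outdir


def subject_sim_config(config: PipelineConfig, subject: int,
                       with_fnirs: bool) -> SimConfig:
    """Draw one subject's physiology around the cohort-level settings."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, subject]))
    nc = config.n_channels
    return SimConfig(
        mean_hr=float(np.clip(rng.normal(config.mean_hr, 0.10), 0.8, 1.8)),
        free_breathing_rate=float(np.clip(rng.normal(config.free_breathing_rate, 0.03), 0.15, 0.4)),
        rsa_gain=float(np.clip(rng.normal(config.rsa_gain, 0.03), 0.05, 0.4)),
        rsa_lag_s=float(np.clip(rng.normal(config.rsa_lag_s, 1.5), 2.0, 20.0)),
        lf_gain=config.lf_gain,
        ecg_noise_sd=config.ecg_noise_sd,
        hr_counting_drop_hz=config.hr_counting_drop_hz,
        br_counting_drop_hz=config.br_counting_drop_hz,
        fnirs_breathing_gain=rng.uniform(0.3, 0.8, nc) if with_fnirs else 0.0,
        fnirs_breathing_lag_s=rng.uniform(2.0, 12.0, nc) if with_fnirs else 0.0,
        n_channels=nc,
        fs_ecg=config.fs_ecg,
        fs_fnirs=config.fs_fnirs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Per-subject analysis
# ---------------------------------------------------------------------------

def _segment_mean(series: RateSeries, intervals: list[tuple[float, float]]) -> float:
    mask = np.zeros(series.t.size, dtype=bool)
    for a, b in intervals:
        mask |= (series.t >= a) & (series.t < b)
    return float(series.value[mask].mean()) if mask.any() else np.nan

def _segment_slice(series: RateSeries, a: float, b: float) -> RateSeries:
    mask = (series.t >= a) & (series.t < b)
    return RateSeries(t=series.t[mask], value=series.value[mask], source=series.source)


def _paced_transition_times(schedule) -> dict[tuple[float, float], list[float]]:
    """Within-block step transitions keyed by (from_rate, to_rate)."""
    out: dict[tuple[float, float], list[float]] = {}
    steps = schedule.by_label("paced_step")
    for prev, nxt in zip(steps[:-1], steps[1:]):
        if abs(prev.end_s - nxt.start_s) > 1e-9:
            continue  # different paced blocks
        key = (prev.target_breathing_rate, nxt.target_breathing_rate)
        out.setdefault(key, []).append(nxt.start_s)
    return out


def analyze_subject(rec: MultiModalRecording, config: PipelineConfig,
                    subject: int = 0) -> dict:
    """Run the full analysis chain on one recording; returns a flat metric
    dict (one row of the per-subject table)."""
    sched = rec.schedule
    fs = rec.fs_ecg

    ecg_f = filter_ecg(rec.ecg, fs, band=config.ecg_band, order=config.ecg_filter_order)
    ann = detect_r_peaks(ecg_f, fs)
    ann = correct_ectopic(ann, detect_ectopic(ann))
    hr = ibi_to_rate(ann, config.grid_fs, source="heart")
    hr_s = smooth_rate(hr, config.smooth_window_s)

    br_ann = detect_breath_peaks(rec.breathing, fs)
    br = ibi_to_rate(br_ann, config.grid_fs, source="breathing")
    br_on_hr = RateSeries(t=hr.t, value=np.interp(hr.t, br.t, br.value), source="breathing")
    ratio = rate_ratio(hr, br_on_hr)

    row: dict = {"subject": subject}

    rest0 = sched.by_label("rest")[0]
    counting = sched.by_label("counting")
    rest_iv = [(rest0.start_s, rest0.end_s)]
    count_iv = [(e.start_s, e.end_s) for e in counting]
    row["hr_rest"] = _segment_mean(hr, rest_iv)
    row["hr_counting"] = _segment_mean(hr, count_iv)
    row["br_rest"] = _segment_mean(br, rest_iv)
    row["br_counting"] = _segment_mean(br, count_iv)
    row["ratio_rest"] = _segment_mean(ratio, rest_iv)
    row["ratio_counting"] = _segment_mean(ratio, count_iv)
    for r in PACED_RATES:
        iv = [(e.start_s, e.end_s) for e in sched.paced_steps(r)]
        row[f"hr_paced_{r}"] = _segment_mean(hr, iv)
        row[f"br_paced_{r}"] = _segment_mean(br, iv)
        row[f"ratio_paced_{r}"] = _segment_mean(ratio, iv)

    # counting accuracy (signed percentage-error form) and confidence
    accs, confs = [], []
    for e in counting:
        beats_in = int(np.count_nonzero(
            (ann.event_times >= e.start_s) & (ann.event_times < e.end_s)))
        if beats_in > 0 and e.counted_heartbeats is not None:
            accs.append(counting_accuracy(e.counted_heartbeats, beats_in))
            confs.append(e.confidence)
    row["counting_accuracy"] = float(np.mean(accs)) if accs else np.nan
    row["confidence"] = float(np.mean(confs)) if confs else np.nan

    # HRV dominant frequency per paced rate (Burg order 16 on the IBI
    # series within each 50-s step, averaged over the four trials)
    for r in PACED_RATES:
        freqs = []
        for e in sched.paced_steps(r):
            seg_t = ann.event_times[(ann.event_times >= e.start_s) & (ann.event_times < e.end_s)]
            if seg_t.size < 2:
                continue
            from .beats import BeatAnnotations
            seg = ibi_series(BeatAnnotations(event_times=seg_t), config.grid_fs)
            if seg.value.size <= 2 * config.ar_order:
                continue
            spec = burg_psd(seg, order=config.ar_order)
            freqs.append(main_frequency(spec, config.main_freq_band))
        row[f"mainfreq_paced_{r}"] = float(np.median(freqs)) if freqs else np.nan
    rest_t = ann.event_times[(ann.event_times >= rest0.start_s) & (ann.event_times < rest0.end_s)]
    if rest_t.size > 2 * config.ar_order + 2:
        from .beats import BeatAnnotations
        rest_ibi = ibi_series(BeatAnnotations(event_times=rest_t), config.grid_fs)
        row["mainfreq_rest"] = main_frequency(burg_psd(rest_ibi, order=config.ar_order),
                                              config.main_freq_band)
    else:
        row["mainfreq_rest"] = np.nan

    # cardiorespiratory correlation per condition
    breathing_4hz = resample_to_grid(rec.breathing, fs, hr_s.t)

    def coupling(a: float, b: float, prefix: str) -> None:
        seg_hr = _segment_slice(hr_s, a, b)
        if seg_hr.t.size == 0:
            row[f"cr_{prefix}"] = np.nan
            row[f"cr_lag_{prefix}"] = np.nan
            return
        seg_b = breathing_4hz[(hr_s.t >= a) & (hr_s.t < b)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cc = cardioresp_correlation(seg_b, seg_hr, config.lag_range_s)
            row[f"cr_{prefix}"] = abs(cc.rho_max)
            row[f"cr_lag_{prefix}"] = cc.lag_at_max
        except ValueError:
            row[f"cr_{prefix}"] = np.nan
            row[f"cr_lag_{prefix}"] = np.nan

    coupling(rest0.start_s, rest0.end_s, "rest")
    coupling(counting[0].start_s, sched.by_label("report")[-1].end_s, "counting")
    trans = _paced_transition_times(sched)
    for pair in SLOWER_TO_FASTER + FASTER_TO_SLOWER:
        times = trans.get(pair, [])
        if times:
            # span both steps of the first occurrence of the transition
            coupling(times[0] - 50.0, times[0] + 50.0, f"paced_{pair[0]}_{pair[1]}")
        else:
            row[f"cr_paced_{pair[0]}_{pair[1]}"] = np.nan
            row[f"cr_lag_paced_{pair[0]}_{pair[1]}"] = np.nan

    # transition contrasts: counting -> report (cessation of counting)
    stops = [e.end_s for e in counting]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep_hr = align_transitions(hr, np.asarray(stops), (-30.0, 30.0))
            ep_br = align_transitions(br, np.asarray(stops), (-30.0, 30.0))
        row["hr_trans_pre"], row["hr_trans_post"] = ep_hr.pre_post_means()
        row["br_trans_pre"], row["br_trans_post"] = ep_br.pre_post_means()
    except ValueError:
        for k in ("hr_trans_pre", "hr_trans_post", "br_trans_pre", "br_trans_post"):
            row[k] = np.nan

    return row


def _analyze_fnirs_subject(rec: MultiModalRecording, config: PipelineConfig,
                           row: dict) -> None:
    od = OpticalDensitySeries(od=rec.fnirs_od, fs=rec.fs_fnirs)
    hbo = filter_fnirs(od_to_hbo(od), band=config.fnirs_band,
                       order=config.fnirs_filter_order)
    fsf = rec.fs_fnirs
    sched = rec.schedule

    def seg(a: float, b: float) -> HbOSeries:
        i0, i1 = int(a * fsf), int(b * fsf)
        return HbOSeries(hbo=hbo.hbo[:, i0:i1], fs=fsf, dpf=hbo.dpf)

    rest0 = sched.by_label("rest")[0]
    counting = sched.by_label("counting")
    conn_rest = channel_connectivity(seg(rest0.start_s, rest0.end_s))
    conn_cnt = [channel_connectivity(seg(e.start_s, e.end_s)).per_channel_median
                for e in counting]
    row["conn_rest"] = conn_rest.per_channel_median
    row["conn_counting"] = np.mean(conn_cnt, axis=0)

    # breathing response over the first paced block pair (>= 100 s segment)
    steps = sched.by_label("paced_step")
    a, b = steps[0].start_s, steps[0].start_s + 250.0
    step_ds = int(round(rec.fs_ecg / fsf))
    breathing_50 = rec.breathing[::step_ds]
    i0, i1 = int(a * fsf), int(b * fsf)
    resp = extract_breathing_response(
        seg(a, b), breathing_50[i0:i1],
        lag_range_s=config.lag_range_s,
        rho_threshold=config.component_rho_threshold,
        lag_step_s=0.5,
    )
    row["breathing_response_empty"] = resp.empty
    if not resp.empty:
        row["breathing_response_lags"] = breathing_response_lag(
            resp, breathing_50[i0:i1], lag_range_s=config.lag_range_s, lag_step_s=0.5)
    else:
        row["breathing_response_lags"] = np.full(config.n_channels, np.nan)


# ---------------------------------------------------------------------------
# Group tables
# ---------------------------------------------------------------------------

def _mc_row(x: np.ndarray, y: np.ndarray, config: PipelineConfig, seed: int) -> dict:
    out = {"median_a": np.nan, "mad_a": np.nan, "median_b": np.nan, "mad_b": np.nan,
           "z": np.nan, "p": np.nan, "p_mc": np.nan, "significant": False}
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return out
    out["median_a"], out["mad_a"] = group_median_mad(x)
    out["median_b"], out["mad_b"] = group_median_mad(y)
    try:
        res = monte_carlo_correct(x, y, n_perm=config.n_perm, alpha=config.alpha, seed=seed)
        out.update(z=res.z, p=res.p, p_mc=res.p_mc, significant=res.significant)
    except ValueError:
        pass
    return out


def _build_tables(df: pd.DataFrame, fnirs_rows: list[dict],
                  config: PipelineConfig) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    seed0 = config.seed + 101

    # rates per condition vs rest
    rows = []
    conditions = ["counting"] + [f"paced_{r}" for r in PACED_RATES]
    for meas in ("hr", "br", "ratio"):
        rest = df[f"{meas}_rest"].to_numpy()
        med_r, mad_r = group_median_mad(rest[np.isfinite(rest)])
        for cond in conditions:
            col = f"{meas}_{cond}"
            if col not in df:
                continue
            r = _mc_row(df[col].to_numpy(), rest, config, seed0)
            rows.append({"measure": meas, "condition": cond,
                         "median": r["median_a"], "mad": r["mad_a"],
                         "rest_median": med_r, "rest_mad": mad_r,
                         "z": r["z"], "p": r["p"], "p_mc": r["p_mc"],
                         "significant": r["significant"]})
    tables["rates_by_condition"] = pd.DataFrame(rows)

    # counting-transition z-scored contrast
    rows = []
    for meas in ("hr", "br"):
        pre = df[f"{meas}_trans_pre"].to_numpy()
        post = df[f"{meas}_trans_post"].to_numpy()
        r = _mc_row(pre, post, config, seed0 + 1)
        rows.append({"measure": meas,
                     "counting_median": r["median_a"], "counting_mad": r["mad_a"],
                     "not_counting_median": r["median_b"], "not_counting_mad": r["mad_b"],
                     "z": r["z"], "p": r["p"], "p_mc": r["p_mc"],
                     "significant": r["significant"]})
    tables["counting_transitions"] = pd.DataFrame(rows)

    # paced HRV dominant frequencies per transition pair
    rows = []
    for pair in SLOWER_TO_FASTER + FASTER_TO_SLOWER:
        a = df[f"mainfreq_paced_{pair[0]}"].to_numpy()
        b = df[f"mainfreq_paced_{pair[1]}"].to_numpy()
        r = _mc_row(a, b, config, seed0 + 2)
        rows.append({"transition": f"{pair[0]}->{pair[1]}",
                     "from_median": r["median_a"], "from_mad": r["mad_a"],
                     "to_median": r["median_b"], "to_mad": r["mad_b"],
                     "z": r["z"], "p": r["p"], "p_mc": r["p_mc"],
                     "significant": r["significant"]})
    tables["paced_main_freq"] = pd.DataFrame(rows)

    # cardiorespiratory correlation per condition vs rest
    rows = []
    rest = df["cr_rest"].to_numpy()
    conds = ["counting"] + [f"paced_{p[0]}_{p[1]}" for p in SLOWER_TO_FASTER + FASTER_TO_SLOWER]
    for cond in conds:
        r = _mc_row(df[f"cr_{cond}"].to_numpy(), rest, config, seed0 + 3)
        rows.append({"condition": cond, "median": r["median_a"], "mad": r["mad_a"],
                     "rest_median": r["median_b"], "rest_mad": r["mad_b"],
                     "z": r["z"], "p": r["p"], "p_mc": r["p_mc"],
                     "significant": r["significant"]})
    tables["cardioresp_by_condition"] = pd.DataFrame(rows)

    # behavioral control: accuracy vs confidence
    acc = df["counting_accuracy"].to_numpy()
    conf = df["confidence"].to_numpy()
    ok = np.isfinite(acc) & np.isfinite(conf)
    if ok.sum() >= 4:
        sp = spearman_p(acc[ok], conf[ok])
        tables["behavior"] = pd.DataFrame([{
            "comparison": "accuracy_vs_confidence", "rho": sp.statistic,
            "p": sp.p, "significant": sp.significant}])

    # fNIRS connectivity contrast, channel-wise
    if fnirs_rows:
        conn_rest = np.vstack([r["conn_rest"] for r in fnirs_rows])
        conn_cnt = np.vstack([r["conn_counting"] for r in fnirs_rows])
        rows = []
        for c in range(conn_rest.shape[1]):
            r = _mc_row(conn_cnt[:, c], conn_rest[:, c], config, seed0 + 4 + c)
            rows.append({"channel": c + 1,
                         "counting_median": r["median_a"], "rest_median": r["median_b"],
                         "z": r["z"], "p": r["p"], "p_mc": r["p_mc"],
                         "significant": r["significant"]})
        tables["fnirs_connectivity"] = pd.DataFrame(rows)
    return tables


def run_study(config: PipelineConfig, outdir: str | Path | None = None,
              with_fnirs: bool = True, write_recordings: bool = False,
              progress: bool = False) -> StudyResults:
    """Simulate and analyze a full cohort; optionally write result tables."""
    config.validate()
    rows: list[dict] = []
    fnirs_rows: list[dict] = []
    for s in range(config.n_subjects):
        has_fnirs = with_fnirs and s < config.n_fnirs_subjects
        sim = subject_sim_config(config, s, has_fnirs)
        rec = simulate_recording(sim, with_fnirs=has_fnirs)
        if progress:
            print(f"subject {s + 1}/{config.n_subjects}", file=sys.stderr)
        if write_recordings and outdir is not None:
            write_recording(rec, Path(outdir) / f"sub-{s + 1:02d}")
        row = analyze_subject(rec, config, subject=s)
        if has_fnirs:
            _analyze_fnirs_subject(rec, config, row)
            fnirs_rows.append(row)
        rows.append(row)

    scalar_cols = [k for k in rows[0] if not isinstance(rows[0][k], np.ndarray)]
    df = pd.DataFrame([{k: r.get(k, np.nan) for k in scalar_cols} for r in rows])
    tables = _build_tables(df, fnirs_rows, config)
    provenance = {
        "package": "interopipe",
        "version": __version__,
        "config": config.to_dict(),
        "n_subjects": config.n_subjects,
    }
    results = StudyResults(subjects=df, tables=tables, provenance=provenance)
    if outdir is not None:
        results.write(outdir)
    return results
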