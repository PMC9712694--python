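"""fNIRS-layer tests: MBLL, filtering, connectivity, PCA breathing response."""

import numpy as np
import pytest

from interopipe.fnirs import (
    HbOSeries,
    OpticalDensitySeries,
    breathing_response_lag,
    channel_connectivity,
    extract_breathing_response,
    filter_fnirs,
    intensities_to_od,
    mbll_forward,
    od_to_hbo,
)
from interopipe.simulate import (
    SimConfig,
    generate_protocol,
    simulate_breathing,
    simulate_fnirs,
    simulate_heartbeats,
)

from conftest import free_breathing_config

FS = 50.0


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = intensities_to_od(np.full((3, 2, 100), 7.5))
        assert np.allclose(od.od, 0.0)

    def test_log10_definition(self):
        i = np.full((1, 2, 100), 10.0)
        i[0, 0, 50] = 1.0  # mean ~ 9.91, OD ~ log10(mean/1)
        od = intensities_to_od(i)
        assert od.od[0, 0, 50] == pytest.approx(np.log10(i[0, 0].mean()), abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        i = 5.0 + rng.random((2, 2, 200))
        a = intensities_to_od(i).od
        b = intensities_to_od(2 * i).od
        assert np.allclose(a, b)

    def test_nonpositive_intensity_rejected(self):
        i = np.ones((1, 2, 10))
        i[0, 0, 3] = 0.0
        with pytest.raises(ValueError):
            intensities_to_od(i)


class TestMbll:
    def test_zero_od_gives_zero_concentration(self):
        out = od_to_hbo(OpticalDensitySeries(od=np.zeros((2, 2, 50))))
        assert np.allclose(out.hbo, 0.0)

    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        hbo = rng.normal(0, 1, (4, 300))
        od = mbll_forward(hbo, -0.3 * hbo)
        back = od_to_hbo(OpticalDensitySeries(od=od))
        assert np.max(np.abs(back.hbo - hbo)) <= 1e-6

    def test_dpf_scaling_linearity(self):
        rng = np.random.default_rng(2)
        od = OpticalDensitySeries(od=rng.normal(0, 0.01, (2, 2, 100)))
        a = od_to_hbo(od, dpf=6.0).hbo
        b = od_to_hbo(od, dpf=12.0).hbo
        assert np.allclose(b, a / 2)

    def test_mbll_linearity(self):
        rng = np.random.default_rng(3)
        od1 = rng.normal(0, 0.01, (2, 2, 100))
        od2 = rng.normal(0, 0.01, (2, 2, 100))
        h1 = od_to_hbo(OpticalDensitySeries(od=od1)).hbo
        h2 = od_to_hbo(OpticalDensitySeries(od=od2)).hbo
        h12 = od_to_hbo(OpticalDensitySeries(od=2 * od1 + 3 * od2)).hbo
        assert np.allclose(h12, 2 * h1 + 3 * h2, atol=1e-9)


class TestFilterFnirs:
    def _tone(self, freq, duration=120.0):
        t = np.arange(int(duration * FS)) / FS
        return HbOSeries(hbo=np.sin(2 * np.pi * freq * t)[None, :], fs=FS)

    def test_cardiac_pulse_attenuated(self):
        out = filter_fnirs(self._tone(1.2))
        assert np.abs(out.hbo[0, 1000:-1000]).max() <= 0.1

    def test_breathing_band_preserved(self):
        out = filter_fnirs(self._tone(0.2))
        assert np.abs(out.hbo[0, 1000:-1000]).max() >= 0.9

    def test_dc_removed(self):
        x = HbOSeries(hbo=np.full((1, 3000), 4.0), fs=FS)
        out = filter_fnirs(x)
        assert abs(out.hbo.mean()) < 1e-6


class TestConnectivity:
    def test_identical_channels_fully_connected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, int(60 * FS))
        hbo = HbOSeries(hbo=np.tile(base, (5, 1)), fs=FS)
        conn = channel_connectivity(hbo)
        assert np.allclose(conn.matrix, 1.0)
        assert np.allclose(conn.per_channel_median, 1.0)

    def test_independent_channels_weakly_connected(self):
        rng = np.random.default_rng(1)
        hbo = HbOSeries(hbo=rng.normal(0, 1, (8, int(60 * FS))), fs=FS)
        conn = channel_connectivity(hbo)
        off = conn.matrix[~np.eye(8, dtype=bool)]
        assert np.median(np.abs(off)) < 0.2

    def test_symmetry_diagonal_and_monotone_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (4, int(40 * FS)))
        conn = channel_connectivity(HbOSeries(hbo=x, fs=FS))
        assert np.allclose(conn.matrix, conn.matrix.T)
        assert np.allclose(np.diag(conn.matrix), 1.0)
        # Spearman invariance under channel-wise monotone transforms
        y = x.copy()
        y[0] = np.exp(y[0])
        y[2] = y[2] ** 3
        conn2 = channel_connectivity(HbOSeries(hbo=y, fs=FS))
        assert np.allclose(conn.matrix, conn2.matrix, atol=1e-12)

    def test_shared_gain_raises_connectivity(self):
        meds = []
        for gain in (0.2, 1.0):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(300 + seed)
                shared = rng.normal(0, 1, int(60 * FS))
                hbo = gain * shared[None, :] + rng.normal(0, 1, (6, shared.size))
                vals.append(channel_connectivity(HbOSeries(hbo=hbo, fs=FS)).per_channel_median.mean())
            meds.append(np.median(vals))
        assert meds[1] > meds[0]

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            channel_connectivity(HbOSeries(hbo=np.zeros((3, int(10 * FS))), fs=FS))


def _coupled_fnirs(seed, gain, lags, rate=0.25, jitter=0.1, noise=0.1):
    sched = generate_protocol(1)
    cfg = SimConfig(duration_s=300, breathing_mode="free", free_breathing_rate=rate,
                    breathing_jitter=jitter, fnirs_breathing_gain=gain,
                    fnirs_breathing_lag_s=lags, fnirs_noise_sd=noise, seed=seed)
    b = simulate_breathing(sched, cfg)
    beats = simulate_heartbeats(b, cfg)
    hbo, od, comp = simulate_fnirs(b, beats, cfg)
    filt = filter_fnirs(od_to_hbo(OpticalDensitySeries(od=od)))
    return filt, b[::5], comp


class TestBreathingResponse:
    def test_injected_component_recovered(self):
        filt, b50, comp = _coupled_fnirs(11, 1.0, 5.0)
        resp = extract_breathing_response(filt, b50)
        assert not resp.empty
        comp_f = filter_fnirs(HbOSeries(hbo=comp, fs=FS)).hbo
        rhos = [np.corrcoef(resp.response[c], comp_f[c])[0, 1] for c in range(23)]
        assert min(rhos) >= 0.9
        lags = breathing_response_lag(resp, b50)
        assert np.max(np.abs(lags - 5.0)) <= 0.5

    def test_zero_gain_gives_empty_flagged_result(self):
        empty = 0
        for seed in (14, 15, 16):
            filt, b50, _ = _coupled_fnirs(seed, 0.0, 5.0)
            resp = extract_breathing_response(filt, b50)
            empty += resp.empty and np.allclose(resp.response, 0.0)
        assert empty >= 2

    def test_distinct_channel_lags_keep_ordering(self):
        lags_true = np.where(np.arange(23) < 12, 2.0, 8.0)
        filt, b50, _ = _coupled_fnirs(13, 1.0, lags_true, rate=0.12, jitter=0.15)
        resp = extract_breathing_response(filt, b50)
        lags = breathing_response_lag(resp, b50)
        assert lags[:12].mean() < lags[12:].mean()
        assert abs(lags[:12].mean() - 2.0) < 1.0
        assert abs(lags[12:].mean() - 8.0) < 1.0

    def test_breathing_copy_channel_reproduced(self):
        rng = np.random.default_rng(5)
        from scipy import signal as sps

        sos = sps.butter(2, [0.1, 0.4], btype="band", fs=FS, output="sos")
        b = sps.sosfiltfilt(sos, rng.normal(0, 1, int(200 * FS)))
        hbo = np.vstack([b, rng.normal(0, 1, (3, b.size))])
        resp = extract_breathing_response(HbOSeries(hbo=hbo, fs=FS), b)
        assert not resp.empty
        r = np.corrcoef(resp.response[0], b)[0, 1]
        assert r > 0.95
        assert breathing_response_lag(resp, b)[0] == pytest.approx(0.0, abs=0.25)

    def test_lag_of_breathing_vs_itself_is_zero(self):
        rng = np.random.default_rng(6)
        from interopipe.fnirs import lagged_spearman

        b = np.cumsum(rng.normal(0, 1, int(100 * FS)))
        lags_s, rho = lagged_spearman(b, b, FS, lag_step_s=0.5)
        assert lags_s[np.argmax(np.abs(rho))] == 0.0

    def test_reconstruction_matches_eigendecomposition_oracle(self):
        # small instance: selected-component reconstruction must equal the
        # projection from a direct eigendecomposition of the correlation matrix
        rng = np.random.default_rng(7)
        n, p = 400, 5
        x = rng.normal(0, 1, (p, n))
        xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        corr = (xz @ xz.T) / n
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        u, s, vt = np.linalg.svd(xz.T, full_matrices=False)
        scores = u * s
        for k in range(p):
            recon_svd = np.outer(scores[:, k], vt[k])
            proj = v[:, k : k + 1] @ (v[:, k : k + 1].T @ xz)
            assert np.max(np.abs(recon_svd.T - proj)) < 1e-8

    def test_empty_response_lag_rejected(self):
        filt, b50, _ = _coupled_fnirs(14, 0.0, 5.0)
        resp = extract_breathing_response(filt, b50)
        if resp.empty:
            with pytest.raises(ValueError):
                breathing_response_lag(resp, b50)
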