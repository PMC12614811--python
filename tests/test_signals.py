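"""Filtering, event detection and segmentation contracts."""

import numpy as np
import pytest

from statefield.signals import (BAND_EDGES, BroadbandRecording, LFPChannelSet,
                                MUAEventSeries, bandpass_band, extract_lfp,
                                extract_mua, remove_spillover, segment_lfp,
                                segment_mua)

FS = 30000.0


def sine_rec(freq, dur=10.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return BroadbandRecording(amp * np.sin(2 * np.pi * freq * t)[None, :], fs)


class TestExtractLfp:
    def test_dc_passes_unchanged(self):
        rec = BroadbandRecording(np.full((1, int(6 * FS)), 3.7), FS)
        lfp = extract_lfp(rec)
        # clear of FIR warm-up and of the high-Q notch's edge ringing
        mid = lfp.samples[0, 4500:-4500]
        assert np.allclose(mid, 3.7, atol=1e-3)

    def test_60hz_notched(self):
        lfp = extract_lfp(sine_rec(60.0))
        mid = lfp.samples[0, 1000:-1000]
        assert np.sqrt((mid ** 2).mean()) < 0.10 / np.sqrt(2)

    def test_200hz_suppressed_60db(self):
        lfp = extract_lfp(sine_rec(200.0))
        mid = lfp.samples[0, 1000:-1000]
        out_rms = np.sqrt((mid ** 2).mean())
        assert out_rms < (1 / np.sqrt(2)) * 10 ** (-60 / 20)

    def test_passband_tone_preserved_zero_phase(self):
        # amplitude and alignment of a 20 Hz tone survive the filter chain
        rec = sine_rec(20.0, dur=5.0)
        lfp = extract_lfp(rec)
        t = np.arange(lfp.samples.shape[1]) / lfp.fs_down
        ref = np.sin(2 * np.pi * 20.0 * t)
        a, b = lfp.samples[0, 700:-700], ref[700:-700]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.999  # zero-phase: no lag against the reference
        assert abs(a.std() / b.std() - 1) < 0.02

    def test_idempotent_on_band_limited_signal(self):
        rec = sine_rec(20.0, dur=5.0)
        once = extract_lfp(rec, decimate=1)
        twice = extract_lfp(BroadbandRecording(once.samples, FS), decimate=1)
        mid = slice(12000, -12000)
        assert np.allclose(once.samples[0, mid], twice.samples[0, mid],
                           atol=5e-3)

    def test_rejects_low_fs_and_short_signal(self):
        with pytest.raises(ValueError):
            extract_lfp(BroadbandRecording(np.zeros((1, 5000)), 500.0))
        with pytest.raises(ValueError, match="shorter"):
            extract_lfp(BroadbandRecording(np.zeros((1, 100)), FS))


class TestExtractMua:
    def test_all_zero_channel_has_no_events(self):
        rec = BroadbandRecording(np.zeros((1, int(FS))), FS)
        with pytest.warns(UserWarning, match="zero variance"):
            mua = extract_mua(rec)
        assert mua.event_times[0].size == 0

    def test_gaussian_false_event_rate_matches_tail(self, rng):
        # expected |z| > thr crossings = 2*Phi(-thr) per sample; a 3.5 SD
        # threshold gives a resolvable count in 20 s, and the excursion
        # merge plus dead time can only reduce it
        from scipy.stats import norm
        dur = 20.0
        x = rng.standard_normal(int(dur * FS))
        rec = BroadbandRecording(x[None], FS)
        mua = extract_mua(rec, threshold_sd=3.5, refractory_s=0.0)
        n = mua.event_times[0].size
        expected = 2 * norm.sf(3.5) * dur * FS
        assert n <= expected + 4 * np.sqrt(expected)
        assert n >= 0.4 * expected

    def test_injected_transient_detected_once(self, rng):
        x = 0.1 * rng.standard_normal(int(FS))
        rec0 = BroadbandRecording(x[None].copy(), FS)
        base = extract_mua(rec0).event_times[0]
        # biphasic 10-sigma transient at 0.5 s, fast enough to pass >600 Hz
        k = int(0.5 * FS)
        x2 = x.copy()
        x2[k:k + 8] += 10 * 0.1 * np.sin(np.arange(8) / 8 * 2 * np.pi)
        rec1 = BroadbandRecording(x2[None], FS)
        ev = extract_mua(rec1).event_times[0]
        new = ev[np.min(np.abs(ev[:, None] - base[None, :]), axis=1) > 2 / FS] \
            if base.size else ev
        assert new.size == 1
        assert abs(new[0] - 0.5) < 20 / FS

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(int(2 * FS))
        a = extract_mua(BroadbandRecording(x[None], FS)).event_times[0]
        b = extract_mua(BroadbandRecording(17.3 * x[None], FS)).event_times[0]
        assert np.array_equal(a, b)


class TestRemoveSpillover:
    def make(self, times):
        return MUAEventSeries([np.asarray(times, float)], 5.0, FS)

    def test_zero_coincidence_identity(self):
        mua = self.make([0.1, 0.2, 0.3])
        out, rep = remove_spillover(mua, np.array([1.0, 2.0]))
        assert np.array_equal(out.event_times[0], mua.event_times[0])
        assert not rep["per_channel"][0]["removed"]

    def test_full_coincidence_empties_channel(self):
        mua = self.make([0.1, 0.2, 0.3])
        out, _ = remove_spillover(mua, np.array([0.1, 0.2, 0.3]))
        assert out.event_times[0].size == 0

    def test_five_percent_untouched(self):
        times = np.arange(100) * 0.01 + 1.0
        spikes = times[:5]  # 5% coincident: below the 10% trigger
        out, rep = remove_spillover(self.make(times), spikes)
        assert out.event_times[0].size == 100
        assert rep["per_channel"][0]["n_coincident"] == 5

    def test_never_deletes_non_coincident(self, rng):
        times = np.sort(rng.uniform(0, 10, 200))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        spikes = times[::2] + 2e-4  # within the 0.5 ms window
        out, _ = remove_spillover(self.make(times), spikes)
        survivors = out.event_times[0]
        non_co = times[np.min(np.abs(times[:, None] - spikes[None, :]),
                              axis=1) > 0.5e-3]
        assert np.all(np.isin(non_co, np.concatenate([survivors, times])))
        assert survivors.size <= times.size


class TestSegmentation:
    def lfp(self, n=2000, fs=3000.0, channels=2, fill=None):
        x = np.tile(np.arange(n, dtype=float), (channels, 1)) if fill is None \
            else np.full((channels, n), fill)
        return LFPChannelSet(x, fs)

    def test_row_count_and_dropping(self):
        lfp = self.lfp(n=3000)
        onsets = np.arange(30) / 75.0  # 40-sample spacing at 3 kHz
        seg = segment_lfp(lfp, onsets, condition=False)
        assert seg.values.shape == (30, 150, 2)
        assert seg.n_dropped == 0
        late = np.array([0.97])  # 2910 + 150 > 3000
        seg2 = segment_lfp(lfp, np.concatenate([onsets, late]), condition=False)
        assert seg2.values.shape[0] == 30
        assert seg2.n_dropped == 1

    def test_ramp_segments_start_at_onset_value(self):
        lfp = self.lfp(n=1000)
        seg = segment_lfp(lfp, np.array([0.0, 0.1]), condition=False)
        assert np.allclose(seg.values[0, :, 0], np.arange(150))
        assert np.allclose(seg.values[1, :, 0], 300 + np.arange(150))

    def test_onset_rounding_rule(self):
        lfp = self.lfp(n=1000)
        exact = segment_lfp(lfp, np.array([0.1]), condition=False)
        jitter = segment_lfp(lfp, np.array([0.1 + 0.4 / 3000.0]),
                             condition=False)
        assert np.array_equal(exact.values, jitter.values)

    def test_mua_event_placement_and_binning(self):
        fs_down = 3000.0
        mua = MUAEventSeries([np.array([23 / 30000.0]),
                              np.array([40 / 30000.0, 42 / 30000.0])],
                             5.0, 30000.0)
        seg = segment_mua(mua, np.array([0.0]), fs_down)
        assert seg.values.shape == (1, 150, 2)
        assert seg.values[0, 23 // 10, 0] == 1
        assert seg.values[0, 4, 1] == 2  # both events in raw bin 40-49
        assert seg.values.sum() == 3

    def test_mua_empty_and_count_conservation(self, rng):
        fs_down = 3000.0
        empty = MUAEventSeries([np.empty(0)], 5.0, 30000.0)
        seg = segment_mua(empty, np.array([0.0, 0.05]), fs_down)
        assert seg.values.sum() == 0
        # non-overlapping full windows conserve the event count
        times = np.sort(rng.choice(np.arange(1, 2999), 60, replace=False)) \
            / 30000.0
        mua = MUAEventSeries([times], 5.0, 30000.0)
        seg2 = segment_mua(mua, np.array([0.0, 0.05]), fs_down)
        assert seg2.values.sum() == np.sum(times < 3000 / 30000.0)


class TestBandpass:
    def test_band_edges_catalog(self):
        assert BAND_EDGES["theta"] == (4.0, 7.5)
        assert set(BAND_EDGES) == {"delta", "theta", "alpha", "beta", "gamma"}

    def test_delta_passes_2hz_with_linear_phase_advance(self):
        fs = 1500.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 2.0 * t)
        band = bandpass_band(x, fs, "delta")
        mid = slice(int(20 * fs), int(40 * fs))
        assert abs(band.filtered[mid].std() / x[mid].std() - 1) < 0.05
        # unwrapped analytic phase advances 2*pi*f per second
        dphi = np.unwrap(band.phase[mid])
        slope = np.polyfit(t[mid], dphi, 1)[0]
        assert abs(slope - 2 * np.pi * 2.0) < 0.05

    def test_gamma_rejects_2hz(self):
        fs = 1500.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 2.0 * t)
        band = bandpass_band(x, fs, "gamma")
        mid = slice(int(10 * fs), int(20 * fs))
        assert band.filtered[mid].std() < 0.01 * x.std()

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            bandpass_band(np.zeros(1000), 1500.0, "mu")
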