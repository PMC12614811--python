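"""VR, PLS, GFI and SI against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statefield.metrics import (TrialResponseMatrix, global_fluctuation_index,
                                phase_locking_strength, synchrony_index,
                                variability_ratio)
from statefield.signals import BandFilteredLFP, LFPChannelSet


def vr_bruteforce(counts):
    """Literal leave-one-out definition, trial by trial."""
    n = counts.shape[0]
    r2 = []
    for i in range(n):
        others = np.delete(counts, i, axis=0).mean(axis=0)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(counts[i], others)[0, 1]
        r2.append(0.0 if np.isnan(r) else r * r)
    return 1.0 - np.mean(r2)


def band_from_phase(phase, fs=1000.0):
    return BandFilteredLFP("delta", (0.5, 4.0), np.zeros_like(phase),
                           phase, fs=fs)


class TestVariabilityRatio:
    def test_scaled_copies_are_perfectly_reliable(self):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        counts = np.stack([1 * base, 2 * base, 3 * base])
        assert variability_ratio(counts).vr == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_counts_as_reliable(self):
        counts = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
        res = variability_ratio(counts)
        assert res.vr == pytest.approx(0.0, abs=1e-12)

    def test_poisson_noise_low_rate_drives_vr_toward_one(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(0.05, size=(20, 375)).astype(float)
        res = variability_ratio(counts)
        assert 0.9 < res.vr <= 1.0

    def test_degenerate_trial_flagged_as_zero(self):
        counts = np.array([[0, 0, 0, 0], [1, 2, 3, 4], [2, 1, 0, 4]],
                          dtype=float)
        res = variability_ratio(counts)
        assert 0 in res.degenerate_trials
        assert res.per_trial_R2[0] == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(2, 8)
            t = rng.integers(5, 30)
            counts = rng.poisson(2.0, size=(n, t)).astype(float)
            assert variability_ratio(counts).vr == \
                pytest.approx(vr_bruteforce(counts), abs=1e-10)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 5.0),
           st.floats(0.01, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_and_affine_invariance(self, seed, scale, rate):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rate, size=(4, 25)).astype(float)
        vr = variability_ratio(counts).vr
        assert 0.0 <= vr <= 1.0
        assert variability_ratio(counts * scale).vr == pytest.approx(vr,
                                                                     abs=1e-9)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            variability_ratio(np.ones((1, 10)))


class TestPhaseLocking:
    def test_single_spike_is_unity(self):
        band = band_from_phase(np.linspace(-np.pi, np.pi, 1000))
        res = phase_locking_strength(np.array([0.25]), band)
        assert res.pls == pytest.approx(1.0)

    def test_opposite_phases_cancel(self):
        phase = np.array([0.0, np.pi, 0.0, np.pi] * 10)
        band = band_from_phase(phase)
        res = phase_locking_strength(np.array([0.0, 1 / 1000.0]), band)
        assert res.pls == pytest.approx(0.0, abs=1e-12)

    def test_two_zeros_one_pi_gives_third(self):
        phase = np.array([0.0, 0.0, np.pi, 0.0])
        band = band_from_phase(phase)
        res = phase_locking_strength(np.array([0.0, 1e-3, 2e-3]), band)
        assert res.pls == pytest.approx(1 / 3)

    def test_no_spikes_is_undefined(self):
        band = band_from_phase(np.zeros(100))
        res = phase_locking_strength(np.array([]), band)
        assert res.undefined and res.pls is None and res.n_spikes == 0

    def test_matches_per_spike_loop_oracle(self, rng):
        for _ in range(100):
            n_samp = int(rng.integers(100, 1000))
            phase = rng.uniform(-np.pi, np.pi, n_samp)
            band = band_from_phase(phase)
            n_spk = int(rng.integers(1, 40))
            spikes = rng.uniform(0, (n_samp - 1) / 1000.0, n_spk)
            res = phase_locking_strength(spikes, band)
            acc = 0j
            for t in spikes:
                acc += np.exp(1j * phase[int(round(t * 1000.0))])
            assert res.pls == pytest.approx(abs(acc) / n_spk, abs=1e-12)
            assert 0.0 <= res.pls <= 1.0 + 1e-12


class TestGFI:
    def test_constant_rates_zero(self):
        assert global_fluctuation_index(np.full((4, 10), 3.0)) == 0.0

    def test_hand_computed_example(self):
        # channel-averaged series [2,0,2,0]: sample SD sqrt(4/3), mean 1
        val = global_fluctuation_index(np.array([[2.0, 0.0, 2.0, 0.0]]))
        assert val == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    def test_scale_and_permutation_invariance(self, rng):
        rates = rng.poisson(3.0, size=(6, 50)).astype(float)
        v = global_fluctuation_index(rates)
        assert global_fluctuation_index(7.7 * rates) == pytest.approx(v)
        perm = rng.permutation(6)
        assert global_fluctuation_index(rates[perm]) == pytest.approx(v)

    def test_zero_mean_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(global_fluctuation_index(np.zeros((2, 5))))


class TestSynchronyIndex:
    def test_pure_5hz_tone_si_near_one(self):
        fs = 300.0
        t = np.arange(int(90 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        res = synchrony_index(x, fs=fs)
        assert np.all(res.si > 0.99)

    def test_pure_40hz_tone_si_near_zero(self):
        fs = 300.0
        t = np.arange(int(90 * fs)) / fs
        x = np.sin(2 * np.pi * 40.0 * t)
        res = synchrony_index(x, fs=fs)
        assert np.all(res.si < 0.01)

    def test_white_noise_matches_flat_psd_ratio(self, rng):
        # flat PSD: SI -> (15-0.5)/(100-0.5) ~ 0.1457
        fs = 300.0
        x = rng.standard_normal(int(330 * fs))
        res = synchrony_index(x, fs=fs)
        assert res.si.mean() == pytest.approx(14.5 / 99.5, abs=0.01)

    def test_monotone_in_low_band_power(self, rng):
        fs = 300.0
        t = np.arange(int(60 * fs)) / fs
        noise = rng.standard_normal(t.size)
        lows = [0.0, 0.5, 1.5]
        vals = [synchrony_index(noise + a * np.sin(2 * np.pi * 5 * t),
                                fs=fs, window_s=30.0).si.mean()
                for a in lows]
        assert vals[0] < vals[1] < vals[2]

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            synchrony_index(np.zeros(100), fs=300.0)

    def test_accepts_lfp_channel_set(self, rng):
        fs = 300.0
        lfp = LFPChannelSet(rng.standard_normal((2, int(90 * fs))), fs)
        res = synchrony_index(lfp, channel=1)
        assert res.si.shape == res.si_times.shape
        assert np.all((res.si > 0) & (res.si < 1))
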