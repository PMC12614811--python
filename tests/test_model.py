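"""Forward-model operations against nested-loop oracles and closed forms."""

import numpy as np
import pytest

from statefield.model import (OutputNonlinearity, RFEstimate,
                              StatePathwayParams, StimulusPathwayParams,
                              combine, forward_state, forward_stimulus,
                              render_map, restore_rf, rf_zscore, spatial_conv)


def loop_forward(c, alpha, wmap, s):
    """Nested-loop evaluation of the stimulus pathway on a toy grid."""
    T, H, W = s.shape
    L, K, _ = c.shape
    r = np.zeros(T)
    for t in range(T):
        u = np.zeros((H, W))
        for tau in range(L):
            if t - tau < 0:
                continue
            for x in range(H):
                for y in range(W):
                    for j in range(K):
                        for k in range(K):
                            if 0 <= x - j < H and 0 <= y - k < W:
                                u[x, y] += c[tau, j, k] * s[t - tau, x - j, y - k]
        g = np.where(u > 0, u, alpha * u)
        r[t] = (wmap * g).sum()
    return r


class TestForwardStimulus:
    def test_identity_filter_uniform_map_sums_frame(self, rng):
        s = rng.standard_normal((5, 6, 6))
        c = np.zeros((1, 3, 3))
        c[0, 0, 0] = 1.0
        p = StimulusPathwayParams(c, 1.0, (2.5, 2.5), 1e6, 1.0)
        # sigma huge -> map ~ 1 everywhere
        r = forward_stimulus(p, s)
        assert np.allclose(r, s.sum(axis=(1, 2)), rtol=1e-9)

    def test_zero_stimulus_zero_output(self):
        p = StimulusPathwayParams(np.ones((2, 3, 3)), 0.3, (2, 2), 2.0)
        assert np.all(forward_stimulus(p, np.zeros((4, 6, 6))) == 0)

    def test_alpha_one_is_linear(self, rng):
        c = rng.standard_normal((3, 3, 3))
        p = StimulusPathwayParams(c, 1.0, (2.0, 3.0), 1.5, 0.7)
        s1 = rng.standard_normal((6, 6, 6))
        s2 = rng.standard_normal((6, 6, 6))
        lhs = forward_stimulus(p, 2.0 * s1 - 3.0 * s2)
        rhs = 2.0 * forward_stimulus(p, s1) - 3.0 * forward_stimulus(p, s2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_matches_loop_oracle(self, rng):
        for _ in range(3):
            s = rng.standard_normal((6, 6, 6))
            c = rng.standard_normal((3, 3, 3))
            alpha = float(rng.uniform(-1, 1))
            p = StimulusPathwayParams(c, alpha, (2.5, 3.1), 1.4, 0.9)
            wmap = render_map(p.map_center, p.map_sigma, p.map_gain, (6, 6))
            assert np.allclose(forward_stimulus(p, s),
                               loop_forward(c, alpha, wmap, s), atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        p = StimulusPathwayParams(np.ones((2, 3, 3)), 0.5, (2, 2), 1.0)
        with pytest.raises(ValueError):
            forward_stimulus(p, np.zeros((10, 6)))


class TestForwardState:
    def test_zero_filters_zero_drive(self, rng):
        p = StatePathwayParams(np.zeros((3, 150)), np.zeros((2, 150)))
        segs = rng.standard_normal((7, 150, 3))
        msegs = rng.standard_normal((7, 150, 2))
        m_lfp, m_mua = forward_state(p, segs, msegs)
        assert np.all(m_lfp == 0) and np.all(m_mua == 0)

    def test_impulse_filter_reads_onset_sample(self, rng):
        f = np.zeros((1, 150))
        f[0, 0] = 1.0
        p = StatePathwayParams(f_lfp=f)
        segs = rng.standard_normal((5, 150, 1))
        m_lfp, _ = forward_state(p, segs, None)
        assert np.allclose(m_lfp, segs[:, 0, 0])

    def test_bilinearity(self, rng):
        f = rng.standard_normal((2, 150))
        segs = rng.standard_normal((4, 150, 2))
        m1, _ = forward_state(StatePathwayParams(f_lfp=f), segs, None)
        m2, _ = forward_state(StatePathwayParams(f_lfp=2 * f), 2 * segs, None)
        assert np.allclose(m2, 4 * m1)

    def test_channel_mismatch_rejected(self, rng):
        p = StatePathwayParams(f_lfp=np.zeros((3, 150)))
        with pytest.raises(ValueError):
            forward_state(p, rng.standard_normal((4, 150, 2)), None)


class TestCombine:
    nl = OutputNonlinearity(1.0, 1.0)

    def test_rectification(self):
        r = combine(np.array([-1.0, 2.0]), np.zeros(2), np.zeros(2), self.nl)
        assert np.allclose(r, [0.0, 2.0])

    def test_power_law(self):
        nl = OutputNonlinearity(2.0, 2.0)
        r = combine(np.array([3.0]), np.zeros(1), np.zeros(1), nl)
        assert r[0] == pytest.approx(18.0)

    def test_additive_zero_state_equals_base(self, rng):
        r_stim = rng.standard_normal(20)
        z = np.zeros(20)
        nl = OutputNonlinearity(1.3, 1.7)
        assert np.array_equal(combine(r_stim, z, z, nl, "additive"),
                              combine(r_stim, z, z, nl, "additive"))
        base = np.where(r_stim > 0, 1.3 * np.maximum(r_stim, 0) ** 1.7, 0.0)
        assert np.allclose(combine(r_stim, z, z, nl, "additive"), base)

    def test_additive_permutation_invariant_in_state_drives(self, rng):
        r = rng.standard_normal(10)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert np.allclose(combine(r, a, b, self.nl), combine(r, b, a, self.nl))

    def test_multiplicative_unity_baseline(self, rng):
        r_stim = np.abs(rng.standard_normal(10))
        z = np.zeros(10)
        assert np.allclose(combine(r_stim, z, z, self.nl, "multiplicative"),
                           r_stim)

    def test_divisive_rejects_zero_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            combine(np.ones(3), np.full(3, -2.0), np.zeros(3), self.nl,
                    "divisive", semi_saturation=1.0, state_gain=1.0)

    def test_output_nonnegative_everywhere(self, rng):
        for mode in ("additive", "multiplicative"):
            r = combine(rng.standard_normal(50), rng.standard_normal(50),
                        rng.standard_normal(50), self.nl, mode)
            assert np.all(r >= 0)


class TestRestoreRF:
    def test_impulse_filter_reproduces_map(self):
        c = np.zeros((2, 3, 3))
        c[:, 0, 0] = 1.0
        p = StimulusPathwayParams(c, 0.5, (4.0, 4.0), 1.2, 0.8)
        rf = restore_rf(p, shape=(9, 9))
        wmap = render_map((4.0, 4.0), 1.2, 0.8, (9, 9))
        assert np.allclose(rf.rf[0], wmap, atol=1e-12)

    def test_linearity_in_map_gain(self, rng):
        c = rng.standard_normal((2, 3, 3))
        p1 = StimulusPathwayParams(c, 0.5, (4.0, 4.0), 1.2, 1.0)
        p2 = StimulusPathwayParams(c, 0.5, (4.0, 4.0), 1.2, 2.0)
        assert np.allclose(restore_rf(p2, (9, 9)).rf,
                           2 * restore_rf(p1, (9, 9)).rf)

    def test_matches_double_loop_convolution(self, rng):
        c = rng.standard_normal((2, 3, 3))
        p = StimulusPathwayParams(c, 0.5, (3.0, 2.0), 1.5, 0.9)
        rf = restore_rf(p, shape=(6, 6))
        wmap = render_map(p.map_center, p.map_sigma, p.map_gain, (6, 6))
        for tau in range(2):
            expect = np.zeros((6, 6))
            for x in range(6):
                for y in range(6):
                    for j in range(3):
                        for k in range(3):
                            if 0 <= x - j < 6 and 0 <= y - k < 6:
                                expect[x, y] += c[tau, j, k] * wmap[x - j, y - k]
            assert np.allclose(rf.rf[tau], expect, atol=1e-10)


class TestRFZscore:
    def test_constant_peak_plane_zero(self):
        planes = np.stack([np.random.default_rng(0).normal(size=(5, 5)),
                           np.full((5, 5), 2.0)])
        res = rf_zscore(planes, peak_lag=1)
        assert res.Z == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        planes = rng.standard_normal((3, 6, 6))
        z1 = rf_zscore(planes).Z
        z2 = rf_zscore(7.3 * planes).Z
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_hand_checkable_when_peak_equals_zero_lag(self):
        plane = np.array([[1.0, 2.0, 3.0],
                          [4.0, 5.0, 6.0],
                          [7.0, 8.0, 10.0]])
        planes = np.stack([plane, plane])
        res = rf_zscore(planes, peak_lag=1)
        z_expect = (plane - plane.mean()) / plane.std()
        assert np.allclose(res.zmap, z_expect)
        assert res.Z == pytest.approx(z_expect.var())

    def test_zero_sigma_flagged(self):
        planes = np.stack([np.zeros((4, 4)), np.ones((4, 4))])
        res = rf_zscore(planes, peak_lag=1)
        assert res.Z is None and res.zmap is None


class TestSpatialConv:
    def test_matches_scipy_full_cropped(self, rng):
        from scipy.signal import convolve2d
        img = rng.standard_normal((8, 8))
        ker = rng.standard_normal((3, 3))
        ours = spatial_conv(img, ker)
        ref = convolve2d(img, ker, mode="full")[:8, :8]
        assert np.allclose(ours, ref, atol=1e-10)
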