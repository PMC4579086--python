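"""Receptive-field mapping and movie-feature extraction."""

import numpy as np
import pytest

from gammaflow import rf as rfmod


def _grating(h, w, theta, freq=0.08, phase=0.0):
    """Luminance varying along direction theta (orientation = theta)."""
    yy, xx = np.mgrid[0:h, 0:w]
    return np.cos(2 * np.pi * freq * (xx * np.cos(theta)
                                      + yy * np.sin(theta)) + phase)


class TestRfFromMap:
    def test_delta_peak_gives_one_pixel_rf(self):
        m = np.zeros((15, 15))
        m[7, 7] = 1.0
        rf = rfmod.rf_from_map(m)
        assert rf.center == (7, 7)
        assert rf.half_width == 1
        assert rf.defined

    def test_gaussian_bump_width_matches_contour(self):
        yy, xx = np.mgrid[0:41, 0:41]
        sigma = 4.0
        m = np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * sigma ** 2))
        rf = rfmod.rf_from_map(m, threshold_frac=0.75)
        # 75% contour radius = sigma * sqrt(2 ln(4/3)) ~ 3.03 px
        expected = sigma * np.sqrt(2 * np.log(4 / 3))
        assert rf.center == (20, 20)
        assert abs(rf.half_width - expected) <= 1.0

    def test_flat_map_flagged(self):
        rf = rfmod.rf_from_map(np.ones((9, 9)))
        assert not rf.defined and rf.center is None


class TestReverseCorrelation:
    def _planted(self, rng, coupled=True):
        n_frames, h, w = 240, 48, 48
        movie = rng.standard_normal((n_frames, h, w))
        region = movie[:, 22:30, 10:18].mean(axis=(1, 2))
        fs, fr = 1000.0, 30.0
        n_time = int(n_frames / fr * fs) + 100
        t_frame = (np.arange(n_frames) / fr * fs).astype(int)
        idx = np.clip(np.searchsorted(t_frame + 60, np.arange(n_time),
                                      side="right") - 1, 0, n_frames - 1)
        power = np.zeros((3, n_time))
        for tr in range(3):
            base = region[idx] if coupled else rng.standard_normal(n_time)
            power[tr] = base + 0.3 * rng.standard_normal(n_time)
        return movie, power, fs, fr

    def test_planted_region_recovered(self, rng):
        movie, power, fs, fr = self._planted(rng)
        cmap = rfmod.reverse_correlation_map(power, movie, fs,
                                             frame_rate_hz=fr)
        r, c = np.unravel_index(np.argmax(cmap), cmap.shape)
        assert abs(r - 26 // 4) <= 1 and abs(c - 14 // 4) <= 1

    def test_uncoupled_power_low_z(self, rng):
        movie, power, fs, fr = self._planted(rng, coupled=False)
        cmap = rfmod.reverse_correlation_map(power, movie, fs,
                                             frame_rate_hz=fr)
        assert np.abs(cmap).max() < 5

    def test_svd_removal_noop_flag(self, rng):
        movie, power, fs, fr = self._planted(rng)
        m0 = rfmod.reverse_correlation_map(power, movie, fs,
                                           frame_rate_hz=fr,
                                           n_svd_remove=0)
        m1 = rfmod.reverse_correlation_map(power, movie, fs,
                                           frame_rate_hz=fr,
                                           n_svd_remove=1)
        assert m0.shape == m1.shape
        assert not np.allclose(m0, m1)


class TestTimeContrast:
    def _rf(self):
        m = np.zeros((21, 21))
        m[10, 10] = 1.0
        rf = rfmod.rf_from_map(m)
        rf.half_width = 4
        return rf

    def test_static_movie_zero(self):
        movie = np.ones((30, 21, 21)) * 0.5
        feats = rfmod.time_contrast(movie, self._rf())
        assert np.allclose(feats.tc, 0.0)

    def test_flip_amplitude_homogeneity(self, rng):
        # mean-preserving luminance flips: TC scales with flip amplitude
        base = rng.uniform(0.4, 0.6, size=(21, 21))

        def movie(d):
            return np.stack([base - d / 2, base + d / 2,
                             base - d / 2, base + d / 2])

        t1 = rfmod.time_contrast(movie(0.1), self._rf()).tc
        t2 = rfmod.time_contrast(movie(0.2), self._rf()).tc
        np.testing.assert_allclose(t2[1:], 2 * t1[1:], rtol=1e-9)

    def test_zero_luminance_fallback_flagged(self):
        movie = np.zeros((5, 21, 21))
        feats = rfmod.time_contrast(movie, self._rf())
        assert "unnormalised-zero-luminance" in feats.flags


class TestOrientationActivation:
    def _rf(self):
        m = np.zeros((33, 33))
        m[16, 16] = 1.0
        rf = rfmod.rf_from_map(m)
        rf.half_width = 10
        return rf

    @pytest.mark.parametrize("offset,expected", [
        (0.0, 1.0), (np.pi / 2, 0.0), (np.pi / 4, 0.5)])
    def test_grating_against_preferred(self, offset, expected):
        theta = np.pi / 6
        movie = _grating(33, 33, theta)[None, :, :]
        feats = rfmod.orientation_activation(movie, self._rf(),
                                             theta + offset)
        assert feats.oa[0] == pytest.approx(expected, abs=0.05)

    def test_bounds_and_luminance_invariance(self, rng):
        movie = rng.uniform(size=(10, 33, 33))
        rf = self._rf()
        oa1 = rfmod.orientation_activation(movie, rf, 0.7).oa
        oa2 = rfmod.orientation_activation(3 * movie + 5, rf, 0.7).oa
        assert np.nanmin(oa1) >= 0 and np.nanmax(oa1) <= 1
        np.testing.assert_allclose(oa1, oa2, atol=1e-9)

    def test_gradient_free_frame_masked(self):
        movie = np.ones((2, 33, 33))
        feats = rfmod.orientation_activation(movie, self._rf(), 0.0)
        assert np.isnan(feats.oa).all()


class TestOrientationTuning:
    def _rf(self):
        m = np.zeros((33, 33))
        m[16, 16] = 1.0
        rf = rfmod.rf_from_map(m)
        rf.half_width = 12
        return rf

    def _movie(self, rng, n_frames=160):
        thetas = rng.uniform(0, np.pi, size=n_frames)
        frames = np.stack([_grating(33, 33, th,
                                    phase=rng.uniform(0, 2 * np.pi))
                           for th in thetas])
        return frames, thetas

    def test_planted_tuning_recovered(self, rng):
        frames, thetas = self._movie(rng)
        target = np.deg2rad(45.0)
        mua = np.cos(thetas - target) ** 4 + 0.05 * rng.standard_normal(
            len(thetas))
        curve = rfmod.orientation_tuning(mua, frames, self._rf())
        assert abs(curve.preferred_deg - 45.0) <= 180 / 8

    def test_similarity_signs(self, rng):
        frames, thetas = self._movie(rng)
        mua_a = np.cos(thetas - np.deg2rad(45)) ** 4
        mua_b = np.cos(thetas - np.deg2rad(45)) ** 4 \
            + 0.01 * rng.standard_normal(len(thetas))
        mua_c = np.cos(thetas - np.deg2rad(135)) ** 4
        rf = self._rf()
        ca = rfmod.orientation_tuning(mua_a, frames, rf)
        cb = rfmod.orientation_tuning(mua_b, frames, rf)
        cc = rfmod.orientation_tuning(mua_c, frames, rf)
        assert rfmod.tuning_similarity(ca, cb) > 0
        assert rfmod.tuning_similarity(ca, cc) < 0

    def test_constant_mua_raises(self, rng):
        frames, _ = self._movie(rng, n_frames=20)
        with pytest.raises(ValueError):
            rfmod.orientation_tuning(np.ones(20), frames, self._rf())


class TestDirectedMotion:
    def test_parallel_antiparallel_orthogonal(self):
        u_send, u_recv = np.array([0.0, 0.0]), np.array([1.0, 0.0])
        flow = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 2.0]])
        dm = rfmod.directed_motion(flow, u_send, u_recv).directed_motion
        np.testing.assert_allclose(dm, [2.0, 0.0, 0.0])

    def test_forward_backward_sum_identity(self, rng):
        a, b = np.array([0.0, 1.0]), np.array([2.0, -1.0])
        flow = rng.standard_normal((50, 2))
        fwd = rfmod.directed_motion(flow, a, b).directed_motion
        bwd = rfmod.directed_motion(flow, b, a).directed_motion
        u = (b - a) / np.linalg.norm(b - a)
        np.testing.assert_allclose(fwd + bwd, np.abs(flow @ u), atol=1e-12)

    def test_coincident_centres_raise(self):
        with pytest.raises(ValueError):
            rfmod.directed_motion(np.zeros((3, 2)), np.zeros(2), np.zeros(2))

    def test_rigid_flow_generator(self):
        f = rfmod.rigid_translation_flow(5, np.array([1.0, -2.0]))
        assert f.shape == (5, 2)
        assert np.all(f == [1.0, -2.0])


class TestFeatureSignalCorrelation:
    def test_identity_and_combinations(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        assert rfmod.feature_signal_correlation(x, None, x) == \
            pytest.approx(1.0)
        assert rfmod.feature_signal_correlation(
            x, y, x - y, combine="diff") == pytest.approx(1.0)
        assert abs(rfmod.feature_signal_correlation(
            x, y, rng.standard_normal(200), combine="sum")) < 0.3

    def test_constant_series_raise(self):
        with pytest.raises(ValueError):
            rfmod.feature_signal_correlation(np.ones(50), None,
                                             np.arange(50.0))

    def test_group_signed_rank_detects_positive_shift(self, rng):
        corrs = rng.normal(0.3, 0.1, size=20)
        _, p = rfmod.group_signed_rank(corrs)
        assert p < 0.01
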