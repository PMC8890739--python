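"""Cross-correlation, multipass interrogation, validation, stereo."""

import numpy as np
import pytest

from aneupiv.imaging import CameraModel, ImagePair, make_stereo_pair
from aneupiv.piv import (FLAG_MASKED, FLAG_REPLACED, FLAG_VALID,
                         DisplacementField2C, IllConditionedStereoError,
                         PIVConfig, cross_correlate, multipass_piv,
                         stereo_reconstruct, validate_replace)


def _texture(shape, seed=0, smooth=True):
    rng = np.random.default_rng(seed)
    img = rng.normal(100.0, 30.0, shape)
    if smooth:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 1.2)
    return img


def _spots(shape, centers, sigma=0.9, peak=1000.0):
    """Analytic Gaussian particle image at sub-pixel centres."""
    img = np.zeros(shape)
    vv, uu = np.mgrid[0:shape[0], 0:shape[1]]
    for (u0, v0) in centers:
        img += peak * np.exp(-((uu - u0) ** 2 + (vv - v0) ** 2) / (2 * sigma ** 2))
    return img


def _direct_correlation_peak(wa, wb, search=4):
    """Dense direct (non-FFT) circular-correlation oracle with the same
    3-point Gaussian peak fit as the implementation."""
    a = wa - wa.mean()
    b = wb - wb.mean()
    corr = np.zeros((2 * search + 1, 2 * search + 1))
    for i, dy in enumerate(range(-search, search + 1)):
        for j, dx in enumerate(range(-search, search + 1)):
            corr[i, j] = np.sum(a * np.roll(b, (-dy, -dx), axis=(0, 1)))
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)

    def fit(cm, c0, cp):
        return 0.5 * (np.log(cm) - np.log(cp)) / (np.log(cm) + np.log(cp) - 2 * np.log(c0))
    dx = ix - search + fit(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    dy = iy - search + fit(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    return dx, dy


class TestCrossCorrelate:
    def test_integer_roll_recovered(self):
        wa = _texture((32, 32), seed=1)
        wb = np.roll(wa, (2, 3), axis=(0, 1))     # displacement (dx=3, dy=2)
        res = cross_correlate(wa, wb)
        assert res.dx == pytest.approx(3.0, abs=0.02)
        assert res.dy == pytest.approx(2.0, abs=0.02)
        assert res.peak_ratio > PIVConfig().min_peak_ratio

    def test_subpixel_shift_vs_direct_oracle(self):
        rng = np.random.default_rng(7)
        centers = rng.uniform(4, 28, (25, 2))
        wa = _spots((32, 32), centers)
        wb = _spots((32, 32), centers + [0.25, 0.0])
        res = cross_correlate(wa, wb)
        dx_oracle, dy_oracle = _direct_correlation_peak(wa, wb)
        assert res.dx == pytest.approx(dx_oracle, abs=5e-3)  # float32 FFT + weighting
        assert res.dx == pytest.approx(0.25, abs=0.05)
        assert res.dy == pytest.approx(0.0, abs=0.05)

    def test_uncorrelated_noise_low_peak_ratio(self):
        rng = np.random.default_rng(11)
        wa = rng.normal(size=(32, 32))
        wb = rng.normal(size=(32, 32))
        res = cross_correlate(wa, wb)
        assert res.peak_ratio < 1.5

    def test_constant_tile_raises(self):
        with pytest.raises(ValueError):
            cross_correlate(np.full((32, 32), 7.0), np.full((32, 32), 7.0))

    def test_shift_equivariance(self):
        """Translating both frames identically leaves the displacement unchanged
        (exact for top-hat windows, within 0.02 px for Hann weighting)."""
        wa = _texture((32, 32), seed=3)
        wb = np.roll(wa, (1, 2), axis=(0, 1))
        for weighting, tol in (("uniform", 1e-6), ("hann", 0.02)):
            r1 = cross_correlate(wa, wb, weighting)
            r2 = cross_correlate(np.roll(wa, (5, 5), axis=(0, 1)),
                                 np.roll(wb, (5, 5), axis=(0, 1)), weighting)
            assert r1.dx == pytest.approx(r2.dx, abs=tol)
            assert r1.dy == pytest.approx(r2.dy, abs=tol)


class TestMultipass:
    def test_uniform_shift(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(0, 256, (1500, 2))
        img_a = _spots((256, 256), centers)
        img_b = _spots((256, 256), centers + [4.6, 0.0])
        pair = ImagePair(img_a, img_b, 200.0)
        field = multipass_piv(pair, PIVConfig())
        valid = field.flags == FLAG_VALID
        assert valid.sum() > 0.8 * valid.size
        np.testing.assert_allclose(field.dx[valid], 4.6, atol=0.05)
        # transverse component carries the generic random error of 3-point
        # Gaussian fits under cross-particle correlation noise
        assert np.sqrt(np.mean(field.dy[valid] ** 2)) < 0.06
        assert np.abs(np.mean(field.dy[valid])) < 0.02

    def test_linear_shear_matches_window_response(self):
        """Linear shear: top-hat window averaging leaves a linear field intact."""
        rng = np.random.default_rng(4)
        centers = rng.uniform(0, 256, (1800, 2))
        shift = np.column_stack([1.0 + 0.02 * centers[:, 1], np.zeros(len(centers))])
        img_a = _spots((256, 256), centers)
        img_b = _spots((256, 256), centers + shift)
        field = multipass_piv(ImagePair(img_a, img_b, 200.0), PIVConfig())
        gy = field.y_px[:, None] * np.ones_like(field.dx)
        truth = 1.0 + 0.02 * gy       # window mean of a linear field = centre value
        valid = field.flags == FLAG_VALID
        err = np.abs(field.dx - truth)[valid]
        assert np.sqrt(np.mean(err ** 2)) < 0.1

    def test_grid_pitch_at_sensor_width(self):
        """Default windows on a 2560-wide sensor give vectors every 16 px."""
        rng = np.random.default_rng(8)
        img = _spots((128, 2560), rng.uniform(0, [128, 2560], (4000, 2))[:, ::-1])
        field = multipass_piv(ImagePair(img, img, 200.0), PIVConfig())
        assert np.all(np.diff(field.x_px) == 16)
        # 16 px at 8.8125 um/px = one vector every 141 um
        assert 16 * 8.8125 == pytest.approx(141.0)

    def test_too_small_image_raises(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            multipass_piv(ImagePair(img, img, 200.0), PIVConfig())

    def test_masked_windows_stay_masked(self):
        rng = np.random.default_rng(9)
        img = _spots((192, 192), rng.uniform(0, 192, (900, 2)))
        mask = np.zeros((192, 192), dtype=bool)
        mask[:, :96] = True
        field = multipass_piv(ImagePair(img, img, 200.0), PIVConfig(), mask=mask)
        right = field.x_px > 110
        assert np.all(field.flags[:, right] == FLAG_MASKED)
        assert np.all(np.isnan(field.dx[:, right]))


class TestValidateReplace:
    @staticmethod
    def _smooth_field(ny=8, nx=8):
        gy, gx = np.mgrid[0:ny, 0:nx]
        dx = 2.0 + 0.05 * gx
        dy = -1.0 + 0.03 * gy
        return DisplacementField2C(
            x_px=np.arange(nx, dtype=float), y_px=np.arange(ny, dtype=float),
            dx=dx, dy=dy, peak_ratio=np.full((ny, nx), 5.0),
            flags=np.zeros((ny, nx), np.uint8), pitch_px=16, window_px=32)

    def test_single_spike_replaced(self):
        field = self._smooth_field()
        dx = field.dx.copy()
        dx[4, 4] += 10.0
        field = DisplacementField2C(**{**field.__dict__, "dx": dx})
        out = validate_replace(field, 2.0)
        assert out.flags[4, 4] == FLAG_REPLACED
        assert (out.flags == FLAG_REPLACED).sum() == 1
        assert abs(out.dx[4, 4] - self._smooth_field().dx[4, 4]) < 0.2

    def test_smooth_field_untouched(self):
        out = validate_replace(self._smooth_field(), 2.0)
        assert not np.any(out.flags == FLAG_REPLACED)

    def test_hand_built_normalized_median_case(self):
        """Centre residual / median residual = 4.2 exceeds threshold 2."""
        neigh = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        med = np.median(neigh)                       # 4.5
        rmed = np.median(np.abs(neigh - med))        # 2.0
        center = med + 4.2 * (rmed + 0.1)            # normalized residual = 4.2
        dx = np.array([[1.0, 2, 3], [4, center, 5], [6, 7, 8]])
        field = DisplacementField2C(
            x_px=np.arange(3.0), y_px=np.arange(3.0), dx=dx, dy=np.zeros((3, 3)),
            peak_ratio=np.full((3, 3), 5.0), flags=np.zeros((3, 3), np.uint8),
            pitch_px=16, window_px=32)
        out = validate_replace(field, 2.0)
        assert out.flags[1, 1] == FLAG_REPLACED
        assert out.dx[1, 1] == pytest.approx(med)

    def test_small_grid_rejected(self):
        f = self._smooth_field(2, 2)
        with pytest.raises(ValueError):
            validate_replace(f, 2.0)


class TestStereo:
    @staticmethod
    def _fields_for(cam1, cam2, d_world_mm, nx=9, ny=9, pitch=16):
        """Project a uniform world displacement into both sensors."""
        out = []
        for cam in (cam1, cam2):
            g = cam.gradient()
            duv = g @ d_world_mm
            x = np.arange(nx) * pitch + 100.0
            y = np.arange(ny) * pitch + 100.0
            out.append(DisplacementField2C(
                x_px=x, y_px=y,
                dx=np.full((ny, nx), duv[0]), dy=np.full((ny, nx), duv[1]),
                peak_ratio=np.full((ny, nx), 5.0),
                flags=np.zeros((ny, nx), np.uint8), pitch_px=pitch, window_px=32))
        return out

    def test_pure_out_of_plane_recovered(self):
        cam1, cam2 = make_stereo_pair(35.0, 48.0, (512, 512), (0.0, 0.0))
        dz = 0.05                                    # mm over 200 us -> 0.25 m/s
        f1, f2 = self._fields_for(cam1, cam2, np.array([0.0, 0.0, dz]))
        vf = stereo_reconstruct(f1, f2, cam1, cam2, 200.0)
        w_true = dz * 1e3 / 200.0
        inner = np.isfinite(vf.w)
        assert np.nanmax(np.abs(vf.w[inner] - w_true)) < 0.01 * w_true
        assert np.nanmax(np.abs(vf.u[inner])) < 0.01 * w_true
        assert np.nanmax(np.abs(vf.v[inner])) < 0.01 * w_true

    def test_pure_in_plane_no_w_leak(self):
        cam1, cam2 = make_stereo_pair(35.0, 48.0, (512, 512), (0.0, 0.0))
        f1, f2 = self._fields_for(cam1, cam2, np.array([0.04, 0.02, 0.0]))
        vf = stereo_reconstruct(f1, f2, cam1, cam2, 200.0)
        inplane = np.nanmax(np.hypot(vf.u, vf.v))
        assert np.nanmax(np.abs(vf.w)) < 0.01 * inplane

    def test_unit_conversion(self):
        """1 px at 8.8125 um/px over 200 us is 0.0441 m/s."""
        cam1, cam2 = make_stereo_pair(35.0, 8.8125, (2160, 2560), (0.0, 0.0))
        # a world displacement of one nominal pixel (8.8125 um) in x
        d_mm = np.array([8.8125e-3, 0.0, 0.0])
        f1, f2 = self._fields_for(cam1, cam2, d_mm)
        vf = stereo_reconstruct(f1, f2, cam1, cam2, 200.0)
        speed = np.hypot(vf.u, vf.v)
        assert np.nanmax(speed) == pytest.approx(0.0441, abs=5e-4)

    def test_near_parallel_cameras_rejected(self):
        cam1 = CameraModel(35.0, 48.0, (512, 512))
        cam2 = CameraModel(35.0 + 1e-9, 48.0, (512, 512), camera_id="cam2")
        f1, f2 = self._fields_for(cam1, cam2, np.array([0.01, 0.0, 0.0]))
        with pytest.raises(IllConditionedStereoError):
            stereo_reconstruct(f1, f2, cam1, cam2, 200.0)
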