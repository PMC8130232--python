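import numpy as np
import pytest

from dirval.mvct import (
    MVCTParams,
    RadialNPS,
    estimate_nps,
    gaussian_mtf_power,
    kv_to_mv_intensity,
    make_mvct,
    synth_noise_slice,
)
from dirval.phantom import centered_grid
from dirval.volumes import Image3D


def flat_nps(spacing=(1.0, 1.0), power=10.0):
    nyq = 0.5 / max(spacing)
    f = np.linspace(0.0, nyq, 33)
    return RadialNPS(freq=f, power=np.full_like(f, power), pixel_spacing=spacing)


def uniform_volume(size=(64, 64, 8), spacing=(1.0, 1.0, 3.0), hu=50.0):
    grid = centered_grid(size, spacing)
    return Image3D(grid, np.full(grid.size, hu))


class TestRadialNPS:
    def test_validation(self):
        with pytest.raises(ValueError):
            RadialNPS(freq=np.array([0.0, 0.2, 0.1]), power=np.ones(3), pixel_spacing=(1, 1))
        with pytest.raises(ValueError):
            RadialNPS(freq=np.array([0.0, 0.9]), power=np.ones(2), pixel_spacing=(1, 1))
        with pytest.raises(ValueError):
            RadialNPS(freq=np.array([0.0, 0.2]), power=np.array([1.0, -1.0]), pixel_spacing=(1, 1))

    def test_csv_roundtrip(self, tmp_path):
        nps = flat_nps()
        nps.to_csv(tmp_path / "nps.csv")
        back = RadialNPS.from_csv(tmp_path / "nps.csv", nps.pixel_spacing)
        assert np.allclose(back.freq, nps.freq)
        assert np.allclose(back.power, nps.power)


class TestEstimateNPS:
    def test_identical_scans_zero_power(self):
        v = uniform_volume()
        rng = np.random.default_rng(0)
        v = Image3D(v.grid, v.values + rng.normal(0, 5, v.grid.size))
        nps = estimate_nps(v, v, roi_size=16)
        assert np.allclose(nps.power, 0.0)

    def test_white_noise_flat_and_parseval(self):
        """Independent white noise: flat radial profile whose 2D integral is
        the noise variance."""
        grid = centered_grid((128, 128, 12), (1.0, 1.0, 3.0))
        rng = np.random.default_rng(1)
        sigma = 20.0
        s1 = Image3D(grid, rng.normal(0, sigma, grid.size))
        s2 = Image3D(grid, rng.normal(0, sigma, grid.size))
        positions = [(i * 16, j * 16) for i in range(8) for j in range(8)]
        nps = estimate_nps(s1, s2, roi_size=16, roi_positions=positions)
        # flat: integral over the 2D plane = mean power * (1/dx)*(1/dy)
        recovered_var = nps.power.mean() * 1.0 * 1.0
        assert recovered_var == pytest.approx(sigma**2, rel=0.05)
        assert nps.power.std() / nps.power.mean() < 0.1

    def test_gaussian_filtered_noise_matches_mtf_squared(self):
        """1-px Gaussian-filtered white noise has NPS = flat x MTF^2."""
        from scipy import ndimage

        grid = centered_grid((128, 128, 48), (1.0, 1.0, 3.0))
        rng = np.random.default_rng(2)
        vols = []
        for _ in range(2):
            w = rng.normal(0, 30, grid.size)
            vols.append(Image3D(grid, ndimage.gaussian_filter(w, (1.0, 1.0, 0.0), mode="wrap")))
        positions = [(i * 32, j * 32) for i in range(4) for j in range(4)]
        nps = estimate_nps(vols[0], vols[1], roi_size=32, roi_positions=positions)
        expect = gaussian_mtf_power(nps.freq, 1.0, 1.0)
        a = nps.power / nps.power[0]
        b = expect / expect[0]
        rel_rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
        assert rel_rms < 0.10

    def test_roi_outside_volume_rejected(self):
        v = uniform_volume((32, 32, 4))
        from dirval.volumes import GeometryError

        with pytest.raises(GeometryError):
            estimate_nps(v, v, roi_size=16, roi_positions=[(20, 20)])


class TestSynthNoise:
    def test_seeded_determinism(self):
        nps = flat_nps()
        p = MVCTParams(seed=3)
        a = synth_noise_slice((64, 64), nps, p, seed=42)
        b = synth_noise_slice((64, 64), nps, p, seed=42)
        assert np.array_equal(a, b)
        c = synth_noise_slice((64, 64), nps, p, seed=43)
        assert not np.array_equal(a, c)

    def test_flat_nps_identity_filter(self):
        """Flat NPS with no blur: the shaping filter is the identity, so the
        output equals the white input."""
        nps = flat_nps()
        p = MVCTParams(smooth_noise_px=0.0)
        out = synth_noise_slice((64, 64), nps, p, seed=0)
        rng = np.random.default_rng(0)
        white = rng.normal(0.0, p.sigma_frac * p.ref_scale_hu, (64, 64))
        assert np.allclose(out, white, atol=1e-9)

    def test_pos_neg_split_equals_direct_filtering(self):
        """Filtering positive and negative parts separately and recombining
        is algebraically the same as filtering the signed mask."""
        from dirval.mvct import _amplitude_filter

        nps = RadialNPS(
            freq=np.linspace(0, 0.5, 20),
            power=np.exp(-np.linspace(0, 0.5, 20) * 4),
            pixel_spacing=(1.0, 1.0),
        )
        p = MVCTParams(smooth_noise_px=0.0)
        out = synth_noise_slice((32, 32), nps, p, seed=9)
        rng = np.random.default_rng(9)
        white = rng.normal(0.0, p.sigma_frac * p.ref_scale_hu, (32, 32))
        h = _amplitude_filter((32, 32), nps, (1.0, 1.0))
        direct = np.fft.ifft2(np.fft.fft2(white) * h).real
        assert np.allclose(out, direct, atol=1e-9)

    def test_band_limited_target_recovered(self):
        """Empirical radial NPS of many synthesized slices matches the target
        shape."""
        f = np.linspace(0, 0.5, 33)
        target = RadialNPS(freq=f, power=f * np.exp(-((f / 0.2) ** 2)) + 0.05, pixel_spacing=(1.0, 1.0))
        p = MVCTParams(smooth_noise_px=0.0)
        acc = np.zeros((64, 64))
        n = 200
        for i in range(n):
            sl = synth_noise_slice((64, 64), target, p, seed=[5, i])
            sl = sl - sl.mean()
            acc += np.abs(np.fft.fft2(sl)) ** 2
        nps2d = acc / n / (64 * 64)
        fx = np.fft.fftfreq(64, 1.0)
        fr = np.hypot(*np.meshgrid(fx, fx, indexing="ij"))
        expect = target.interp_power(fr)
        sel = fr > 0
        a = nps2d[sel] / nps2d[sel].mean()
        b = expect[sel] / expect[sel].mean()
        rel_rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2))
        assert rel_rms < 0.10

    def test_zero_nps_rejected(self):
        z = RadialNPS(freq=np.linspace(0, 0.5, 5), power=np.zeros(5), pixel_spacing=(1, 1))
        with pytest.raises(ValueError, match="degenerate"):
            synth_noise_slice((16, 16), z, MVCTParams(), seed=0)


class TestIntensityCurve:
    def test_identity_curve(self):
        img = uniform_volume(hu=123.0)
        out = kv_to_mv_intensity(img, [(-1000, -1000), (3000, 3000)])
        assert np.allclose(out.values, img.values)

    def test_linear_compression_pointwise(self):
        grid = centered_grid((8, 8, 4), (1, 1, 1))
        rng = np.random.default_rng(7)
        vals = rng.uniform(-1000, 3000, grid.size)
        img = Image3D(grid, vals)
        out = kv_to_mv_intensity(img, [(-1000.0, -1000.0), (3000.0, 1500.0)])
        expect = -1000.0 + (vals + 1000.0) * (2500.0 / 4000.0)
        assert np.allclose(out.values, expect)

    def test_clamped_below_first_point(self):
        img = uniform_volume(hu=-500.0)
        out = kv_to_mv_intensity(img, [(0.0, 0.0), (100.0, 50.0)])
        assert np.allclose(out.values, 0.0)

    def test_non_monotone_rejected(self):
        img = uniform_volume()
        with pytest.raises(ValueError):
            kv_to_mv_intensity(img, [(0.0, 10.0), (100.0, 5.0)])


class TestMakeMVCT:
    def test_zero_noise_limit(self):
        img = uniform_volume((32, 32, 4))
        nps = flat_nps()
        p = MVCTParams(sigma_frac=1e-12, presmooth_px=0.0, n_realizations=1)
        out = make_mvct(img, nps, p)[0]
        assert np.allclose(out.values, img.values, atol=1e-6)

    def test_three_realizations_differ_only_in_noise(self):
        img = uniform_volume((32, 32, 6))
        nps = flat_nps()
        p = MVCTParams(seed=1)
        vols = make_mvct(img, nps, p)
        assert len(vols) == 3
        assert not np.array_equal(vols[0].values, vols[1].values)
        assert not np.array_equal(vols[1].values, vols[2].values)
        # identical deterministic component: the realization difference is
        # pure zero-mean noise
        diff = vols[0].values - vols[1].values
        sem = diff.std() / np.sqrt(diff.size)
        assert abs(diff.mean()) < 4 * sem

    def test_noise_stationary_across_slices(self):
        img = uniform_volume((64, 64, 20))
        from dirval.study import default_study_nps

        vols = make_mvct(img, default_study_nps((1.0, 1.0)), MVCTParams(seed=2))
        sds = [vols[0].values[:, :, k].std() for k in range(20)]
        assert np.std(sds) / np.mean(sds) < 0.10

    def test_sigma_linearity(self):
        """Doubling sigma_frac doubles the output noise SD (within 2%)."""
        img = uniform_volume((64, 64, 8))
        nps = flat_nps()
        sd1 = make_mvct(img, nps, MVCTParams(seed=3, sigma_frac=0.04))[0].values.std()
        sd2 = make_mvct(img, nps, MVCTParams(seed=3, sigma_frac=0.08))[0].values.std()
        assert sd2 / sd1 == pytest.approx(2.0, rel=0.02)

    def test_mean_preserved_in_uniform_region(self):
        img = uniform_volume((64, 64, 16), hu=80.0)
        from dirval.study import default_study_nps

        out = make_mvct(img, default_study_nps((1.0, 1.0)), MVCTParams(seed=4))[0]
        n = out.values.size
        sem = out.values.std() / np.sqrt(n)
        assert abs(out.values.mean() - 80.0) < 3 * sem + 1e-6
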