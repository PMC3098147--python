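"""Forward imaging model: Beer-Lambert projection, noise, normalization,
patchworking."""

import numpy as np
import pytest

from txmquant import (ConfigError, GeometryError, NormalizationError,
                      add_photon_noise, normalize_background, patchwork, project)
from txmquant.errors import PatchworkGapWarning

from oracles import ray_sum


class TestProject:
    def test_empty_volume_gives_unit_transmission(self):
        pset = project(np.zeros((8, 16, 16)), [0.0, 45.0, 90.0], 15.0)
        assert np.allclose(pset.images, 1.0)

    def test_homogeneous_cube_beer_lambert(self):
        # 3 um cube of mu = 0.1 um^-1: central transmission exp(-0.3)
        pitch = 100.0  # nm; 30 voxels -> 3 um
        n = 40
        vol = np.zeros((n, n, n))
        vol[5:35, 5:35, 5:35] = 0.1
        pset = project(vol, [0.0], pitch)
        center = pset.images[0][n // 2, n // 2]
        assert center == pytest.approx(np.exp(-0.3), rel=1e-6)

    def test_noiseless_frames_bounded_by_one(self, small_phantom):
        pset = project(small_phantom.attenuation_volume, [0.0, 70.0], 15.0)
        assert pset.images.max() <= 1.0 + 1e-9

    @pytest.mark.parametrize("angle", [0.0, 33.0, 90.0, 127.5])
    def test_line_integrals_match_ray_stepping_oracle(self, angle, rng):
        n = 32
        vol = np.zeros((3, n, n))
        # smooth random blob structure confined to the inscribed circle
        yy, xx = np.meshgrid(np.arange(n) + 0.5 - n / 2, np.arange(n) + 0.5 - n / 2,
                             indexing="ij")
        disk = (yy**2 + xx**2) <= (n / 2 - 3) ** 2
        base = rng.random((n, n))
        from scipy.ndimage import gaussian_filter
        slice2d = gaussian_filter(base, 2.0) * disk
        vol[1] = slice2d
        pitch = 50.0
        pset = project(vol, [angle], pitch)
        measured = -np.log(pset.images[0][1])
        oracle = ray_sum(slice2d, angle, pitch)
        rms = np.sqrt(np.mean((measured - oracle) ** 2))
        assert rms < 0.01 * max(oracle.max(), 1e-12)

    def test_monotonicity_adding_material(self, rng):
        vol = rng.random((6, 20, 20)) * 0.05
        angles = [0.0, 40.0, 111.0]
        base = project(vol, angles, 30.0).images
        vol2 = vol.copy()
        vol2[3, 10, 12] += 0.5
        denser = project(vol2, angles, 30.0).images
        assert np.all(denser <= base + 1e-12)

    def test_energy_bookkeeping_axis_aligned(self, rng):
        vol = rng.random((4, 24, 24)) * 0.02
        pitch = 40.0
        pset = project(vol, [0.0], pitch)
        line = -np.log(pset.images[0])
        # 0 deg rays run along +x; detector axis is flipped y
        expected = (vol.sum(axis=2) * pitch / 1000.0)[:, ::-1]
        assert np.allclose(line, expected, rtol=1e-6, atol=1e-9)

    def test_angle_equivariance_on_smooth_phantom(self, small_phantom):
        from scipy.ndimage import gaussian_filter, rotate
        vol = gaussian_filter(small_phantom.attenuation_volume.astype(float), 2.0)
        alpha = 25.0
        rotated = np.clip(rotate(vol, -alpha, axes=(1, 2), reshape=False, order=1), 0, None)
        a = -np.log(project(rotated, [0.0], 15.0).images[0])
        b = -np.log(project(vol, [alpha], 15.0).images[0])
        rms = np.sqrt(np.mean((a - b) ** 2))
        assert rms < 0.02 * max(b.max(), 1e-12)

    def test_anisotropic_pitch_rejected(self):
        with pytest.raises(GeometryError):
            project(np.zeros((4, 8, 8)), [0.0], (15.0, 15.0, 20.0))

    def test_negative_attenuation_rejected(self):
        vol = np.full((4, 8, 8), -0.1)
        with pytest.raises(ConfigError):
            project(vol, [0.0], 15.0)


class TestPhotonNoise:
    def test_huge_count_approaches_noiseless(self, small_phantom):
        pset = project(small_phantom.attenuation_volume[:, :32, :32][:8], [0.0], 15.0)
        noisy = add_photon_noise(pset, 1e9, seed=5)
        # 3 standard errors at N=1e9: ~1e-4 absolute
        assert np.max(np.abs(noisy.images - pset.images)) < 1e-3

    def test_zero_transmission_stays_zero(self):
        pset = project(np.zeros((1, 4, 4)), [0.0], 15.0)
        pset.images[:] = 0.0
        noisy = add_photon_noise(pset, 1000.0, seed=1)
        assert np.all(noisy.images == 0.0)

    def test_poisson_variance(self):
        pset = project(np.zeros((100, 100, 100)), [0.0], 15.0)
        pset.images[:] = 0.5
        noisy = add_photon_noise(pset, 1000.0, seed=2)
        var = noisy.images.var()
        expected = 0.5 / 1000.0
        assert abs(var - expected) / expected < 0.20

    def test_deterministic_given_seed(self):
        pset = project(np.zeros((1, 16, 16)), [0.0], 15.0)
        a = add_photon_noise(pset, 500.0, seed=7).images
        b = add_photon_noise(pset, 500.0, seed=7).images
        assert np.array_equal(a, b)

    def test_nonpositive_count_rejected(self):
        pset = project(np.zeros((1, 4, 4)), [0.0], 15.0)
        with pytest.raises(ConfigError):
            add_photon_noise(pset, 0.0, seed=0)


class TestNormalizeBackground:
    def test_identity(self, rng):
        flat = rng.random((16, 16)) + 0.5
        assert np.allclose(normalize_background(flat, flat), 1.0)

    def test_ratio(self, rng):
        flat = rng.random((16, 16)) + 0.5
        assert np.allclose(normalize_background(0.5 * flat, flat), 0.5)

    def test_matches_elementwise_division(self, rng):
        raw = rng.random((8, 8)) + 0.1
        flat = rng.random((8, 8)) + 0.5
        assert np.array_equal(normalize_background(raw, flat), raw / flat)

    def test_bad_flatfield_reports_pixel_count(self):
        flat = np.ones((4, 4))
        flat[0, 0] = 0.0
        flat[1, 1] = -2.0
        with pytest.raises(NormalizationError, match="2 non-positive"):
            normalize_background(np.ones((4, 4)), flat)


class TestPatchwork:
    def test_single_tile_identity(self, rng):
        tile = rng.random((10, 12))
        mosaic, cov = patchwork([tile], [(0, 0)])
        assert np.array_equal(mosaic, tile)
        assert cov.max() == 1

    def test_overlap_of_identical_tiles(self):
        tile = np.full((8, 8), 0.7)
        mosaic, _ = patchwork([tile, tile], [(0, 0), (0, 4)])
        assert np.allclose(mosaic, 0.7)

    def test_overlap_averages_values(self):
        a = np.full((6, 6), 0.4)
        b = np.full((6, 6), 0.8)
        mosaic, cov = patchwork([a, b], [(0, 0), (0, 3)])
        assert np.allclose(mosaic[:, 3:6], 0.6)
        assert np.allclose(mosaic[:, :3], 0.4)
        assert np.allclose(mosaic[:, 6:], 0.8)
        assert cov[:, 3:6].max() == 2

    def test_gap_warning_counts_pixels(self):
        a = np.ones((4, 4))
        with pytest.warns(PatchworkGapWarning, match=r"\d+ uncovered"):
            patchwork([a, a], [(0, 0), (0, 8)])
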