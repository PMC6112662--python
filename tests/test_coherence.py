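"""Spatial-coherence curves and SLSC/MLSC images."""

import dataclasses

import numpy as np
import pytest

import oracles
import stonebeam as sb
from stonebeam.beamform import ImageGrid, coherence_grid
from stonebeam.coherence import (CoherenceConfig, default_mid_lags,
                                 default_short_lag)
from stonebeam.exceptions import (InsufficientAnglesError,
                                  InvalidParameterError, UndefinedMetricError)
from stonebeam.synthetic_scene import point_scene


# ---------------------------------------------------------------------------
# coherence curve
# ---------------------------------------------------------------------------


def test_identical_signals_fully_coherent():
    s = np.sin(np.linspace(0.0, 6.0, 15))
    curve = sb.coherence_curve(np.tile(s, (8, 1)))
    assert np.allclose(curve.R_hat, 1.0, atol=1e-12)
    assert np.array_equal(curve.lags, np.arange(1, 8))


def test_alternating_sign_gives_alternating_coherence():
    s = np.sin(np.linspace(0.0, 6.0, 15))
    patch = np.array([(-1.0) ** i * s for i in range(8)])
    curve = sb.coherence_curve(patch)
    assert np.allclose(curve.R_hat, (-1.0) ** curve.lags, atol=1e-12)


def test_white_noise_channels_are_incoherent():
    rng = np.random.default_rng(11)
    n_patches = 600
    curves = np.array([sb.coherence_curve(rng.standard_normal((64, 15))).R_hat
                       for _ in range(n_patches)])
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(n_patches)
    assert np.all(np.abs(mean) <= 3.0 * se + 1e-12)


def test_all_zero_patch_undefined():
    with pytest.raises(UndefinedMetricError):
        sb.coherence_curve(np.zeros((8, 9)))


def test_zero_energy_channels_excluded_from_average():
    s = np.sin(np.linspace(0.0, 6.0, 9))
    patch = np.tile(s, (4, 1))
    patch[2] = 0.0
    curve = sb.coherence_curve(patch)
    # remaining live pairs are still perfectly coherent at every lag
    assert np.allclose(curve.R_hat, 1.0, atol=1e-12)


def test_curve_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        patch = rng.standard_normal((8, 9))
        got = sb.coherence_curve(patch).R_hat
        ref = oracles.coherence_curve_loop(patch)
        assert np.allclose(got, ref, rtol=0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# SLSC
# ---------------------------------------------------------------------------


def _point_cfg(n_elements=128, angles=(-5.0, 0.0, 5.0)):
    return sb.in_vitro_preset(seed=0, n_elements=n_elements,
                              angles_deg=np.array(angles))


def test_slsc_point_target_equals_Q():
    cfg = _point_cfg()
    data = sb.simulate_channel_data(point_scene(0.0, 40.0), cfg)
    grid = ImageGrid(x=np.array([0.0]), z=np.array([40e-3]))
    img = sb.slsc_image(data, grid)
    q = default_short_lag(128)
    assert img.params["Q"] == q == 6
    assert img.values[0, 0] == pytest.approx(q, rel=0.01)


def test_speckle_coherence_follows_vcz_triangle(speckle_coherence_mean):
    m = np.arange(1, 33)  # m <= N/4 for N = 128
    expected = oracles.vcz_triangle(m, 128)
    got = speckle_coherence_mean[:32]
    assert np.all(np.abs(got - expected) <= 0.15 * expected)


def test_speckle_slsc_level_matches_triangle_sum():
    """Mean speckle SLSC with Q=5 on a 64-element aperture is close to
    sum_{m=1..5}(1 - m/64) ~ 4.77 when the synthesized transmit aperture
    matches the receive aperture (angles up to atan((D/2)/z))."""
    scene = sb.make_speckle_phantom(x_span_mm=(-6.0, 6.0),
                                    z_span_mm=(35.0, 45.0), seed=13,
                                    density=30.0)
    cfg = sb.in_vitro_preset(seed=13, n_elements=64,
                             angles_deg=np.arange(-13.0, 13.5, 1.0))
    data = sb.simulate_channel_data(scene, cfg)
    grid = coherence_grid((-3.0, 3.0), (38.0, 42.0), data)
    img = sb.slsc_image(data, grid, CoherenceConfig(lag_lo=1, lag_hi=5))
    expected = float(np.sum(oracles.vcz_triangle(np.arange(1, 6), 64)))
    assert expected == pytest.approx(4.77, abs=0.01)
    assert img.values.mean() == pytest.approx(expected, rel=0.05)


def test_slsc_matches_pixel_oracle(tiny_data, tiny_cfg):
    grid = ImageGrid(x=np.array([0.0, 0.4e-3]), z=np.array([20e-3, 20.4e-3]))
    img = sb.slsc_image(tiny_data, grid, CoherenceConfig(lag_lo=1, lag_hi=3,
                                                         kernel_samples=13))
    for iz in range(2):
        for ix in range(2):
            ref = oracles.slsc_pixel_loop(
                tiny_data.samples, tiny_data.t0, tiny_data.fs, tiny_cfg.c,
                tiny_cfg.geometry.element_x, tiny_cfg.angles_rad,
                grid.x[ix], grid.z[iz], 6, 3)
            assert img.values[iz, ix] == pytest.approx(ref, rel=1e-6, abs=1e-9)


def test_slsc_rejects_bad_configs(tiny_data):
    grid = ImageGrid(x=np.array([0.0]), z=np.array([20e-3]))
    with pytest.raises(InvalidParameterError):
        sb.slsc_image(tiny_data, grid, CoherenceConfig(lag_lo=1, lag_hi=8))
    with pytest.raises(InvalidParameterError):
        sb.slsc_image(tiny_data, grid,
                      CoherenceConfig(lag_lo=2, lag_hi=4,
                                      compounding="coherent_prefocus"))


# ---------------------------------------------------------------------------
# MLSC
# ---------------------------------------------------------------------------


def test_mlsc_point_target_equals_angle_lag_product():
    cfg = _point_cfg()
    data = sb.simulate_channel_data(point_scene(0.0, 40.0), cfg)
    grid = ImageGrid(x=np.array([0.0]), z=np.array([40e-3]))
    img = sb.mlsc_image(data, grid)
    m1, m2 = default_mid_lags(128)
    assert (m1, m2) == (26, 64)
    expected = cfg.n_angles * (m2 - m1 + 1)
    assert img.values[0, 0] == pytest.approx(expected, rel=0.05)


def test_mlsc_matches_pixel_oracle(tiny_data, tiny_cfg):
    grid = ImageGrid(x=np.array([0.0, 0.4e-3]), z=np.array([20e-3, 20.4e-3]))
    cfg = CoherenceConfig(lag_lo=3, lag_hi=5, kernel_samples=13,
                          compounding="incoherent_per_angle")
    img = sb.mlsc_image(tiny_data, grid, cfg)
    for iz in range(2):
        for ix in range(2):
            ref = oracles.mlsc_pixel_loop(
                tiny_data.samples, tiny_data.t0, tiny_data.fs, tiny_cfg.c,
                tiny_cfg.geometry.element_x, tiny_cfg.angles_rad,
                grid.x[ix], grid.z[iz], 6, 3, 5)
            assert img.values[iz, ix] == pytest.approx(ref, rel=1e-6, abs=1e-9)


def test_mlsc_suppresses_speckle_relative_to_stone(stone_data_noiseless):
    scene, data = stone_data_noiseless
    stone_grid = coherence_grid((-4.0, 4.0), (78.0, 80.5), data)
    bg_grid = coherence_grid((9.0, 13.0), (78.0, 80.5), data)
    stone = sb.mlsc_image(data, stone_grid).values.mean()
    speckle = sb.mlsc_image(data, bg_grid).values.mean()
    assert stone > speckle


def test_mlsc_requires_multiple_angles():
    cfg = _point_cfg(angles=(0.0,))
    data = sb.simulate_channel_data(point_scene(0.0, 40.0), cfg)
    grid = ImageGrid(x=np.array([0.0]), z=np.array([40e-3]))
    with pytest.raises(InsufficientAnglesError):
        sb.mlsc_image(data, grid)


def test_mlsc_rejects_short_lag_start(tiny_data):
    grid = ImageGrid(x=np.array([0.0]), z=np.array([20e-3]))
    with pytest.raises(InvalidParameterError):
        sb.mlsc_image(tiny_data, grid,
                      CoherenceConfig(lag_lo=1, lag_hi=4,
                                      compounding="incoherent_per_angle"))


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_pixel_values_bounded(tiny_data):
    grid = ImageGrid(x=np.linspace(-1e-3, 1e-3, 4),
                     z=np.linspace(19e-3, 21e-3, 4))
    slsc = sb.slsc_image(tiny_data, grid)
    q = slsc.params["Q"]
    assert np.all(slsc.values >= 0.0)
    assert np.all(slsc.values <= q + 1e-9)
    mlsc = sb.mlsc_image(tiny_data, grid)
    n_lags = mlsc.params["M2"] - mlsc.params["M1"] + 1
    bound = tiny_data.config.n_angles * n_lags
    assert np.all(mlsc.values >= 0.0)
    assert np.all(mlsc.values <= bound + 1e-9)


def test_amplitude_invariance(tiny_data):
    grid = ImageGrid(x=np.linspace(-1e-3, 1e-3, 3),
                     z=np.linspace(19e-3, 21e-3, 3))
    # power-of-two gain, so scaling the float32 samples is lossless
    scaled = dataclasses.replace(tiny_data, samples=tiny_data.samples * 8.0)
    for fn in (sb.slsc_image, sb.mlsc_image):
        a = fn(tiny_data, grid).values
        b = fn(scaled, grid).values
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9)


def test_lag_band_contrast_grows_into_mid_lags(stone_data_noiseless):
    """Stone-to-background ratio of coherence band sums is non-decreasing as
    the band moves from short into mid lags (coherent targets keep long-range
    coherence; speckle loses it)."""
    scene, data = stone_data_noiseless
    stone_grid = coherence_grid((-3.0, 3.0), (78.5, 80.0), data)
    bg_grid = coherence_grid((8.0, 12.0), (78.5, 80.0), data)
    bands = [(1, 6), (13, 32), (26, 64)]

    def band_means(grid):
        ap = sb.delay_align(data, grid, angle_index="all")
        nz, nx = grid.shape
        sums = np.zeros(len(bands))
        for iz in range(nz):
            for ix in range(nx):
                curve = sb.coherence_curve(ap.patch(iz, ix))
                for k, (lo, hi) in enumerate(bands):
                    sums[k] += max(curve.band_sum(lo, hi), 0.0)
        return sums / (nz * nx)

    ratios = band_means(stone_grid) / band_means(bg_grid)
    assert ratios[0] <= ratios[1] <= ratios[2]
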