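"""Shared fixtures.

Heavy simulations are session-scoped so the full-scale study runs (cohort,
width-recovery, speckle statistics) are computed once and shared between the
unit suites and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import stonebeam as sb
from stonebeam.acquisition import AcquisitionConfig, linear_array
from stonebeam.beamform import envelope_grid
from stonebeam.synthetic_scene import Scene


# ---------------------------------------------------------------------------
# tiny problems (oracle comparisons, interface tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def tiny_cfg() -> AcquisitionConfig:
    """8 elements, 3 angles: small enough for brute-force oracles."""
    return AcquisitionConfig(
        geometry=linear_array(n_elements=8),
        angles_deg=np.array([-5.0, 0.0, 5.0]),
        f0=5.2e6, n_cycles=2.0, fs=12.0 * 5.2e6, c=1480.0, depth_max=0.03)


@pytest.fixture(scope="session")
def tiny_scene() -> Scene:
    pts = np.array([[0.0e-3, 20.0e-3, 1.0],
                    [0.6e-3, 21.0e-3, -0.7],
                    [-0.8e-3, 19.4e-3, 0.4]])
    return Scene(diffuse_scatterers=pts, stone=None, shadow_transmission=1.0,
                 field_of_view=(-2e-3, 2e-3, 18e-3, 22e-3))


@pytest.fixture(scope="session")
def tiny_data(tiny_scene, tiny_cfg):
    return sb.simulate_channel_data(tiny_scene, tiny_cfg)


# ---------------------------------------------------------------------------
# speckle physics (criteria 3 and 4)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def speckle_data():
    """Fully developed speckle block imaged with the full in vitro preset.

    The block is kept narrower than the synthesized-transmit replica spacing
    lambda/delta_theta (~16 mm for 1-degree steps) so that the discrete-angle
    grating replicas of the synthetic transmit beam carry no scatterers and
    the van Cittert-Zernike premises hold cleanly.  density=30 keeps the
    speckle fully developed at the compounded (transmit-focused) resolution:
    the compounded point-spread cell is ~3x smaller than a single plane
    wave's, so the generator's default density leaves too few scatterers per
    cell and the envelope falls measurably short of Rayleigh statistics.
    """
    scene = sb.make_speckle_phantom(x_span_mm=(-6.0, 6.0),
                                    z_span_mm=(35.0, 45.0), seed=7,
                                    density=30.0)
    cfg = sb.in_vitro_preset(seed=7)
    return sb.simulate_channel_data(scene, cfg)


@pytest.fixture(scope="session")
def speckle_envelope(speckle_data):
    """PWSF envelope of the interior of the speckle block (>= 1e4 pixels)."""
    grid = envelope_grid((-4.0, 4.0), (37.0, 43.0), speckle_data)
    img = sb.pwsf(speckle_data, grid)
    assert img.values.size >= 10_000
    return img


@pytest.fixture(scope="session")
def speckle_patches(speckle_data):
    """Aligned patches at >= 1000 speckle pixels (all angles compounded)."""
    from stonebeam.beamform import coherence_grid

    grid = coherence_grid((-4.0, 4.0), (36.0, 44.5), speckle_data, dz_mm=0.22)
    assert grid.shape[0] * grid.shape[1] >= 1000
    return sb.delay_align(speckle_data, grid, angle_index="all")


# ---------------------------------------------------------------------------
# study-scale runs (criteria 6 and 7)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_cohort():
    """The 10-phantom synthetic in vitro cohort at the study operating point."""
    return sb.run_cohort(seed=1)


@pytest.fixture(scope="session")
def width_recovery_runs():
    """Shadow-width measurements over widths {2, 5, 10, 18} mm x 5 seeds on
    the standard (noise-free) phantom, segmented on PWSF images."""
    rows = []
    for width in (2.0, 5.0, 10.0, 18.0):
        for seed in range(1, 6):
            res = sb.run_phantom(width, seed, methods=("pwsf",),
                                 noise_rms=0.0)
            meas = res.shadow_measurements["pwsf"]
            rows.append({"width_mm": width, "seed": seed,
                         "detected": meas.detected,
                         "measured_mm": meas.width_mm})
    return rows


@pytest.fixture(scope="session")
def speckle_coherence_mean(speckle_patches):
    """Mean coherence curve over all speckle patches (van Cittert-Zernike)."""
    nz, nx = speckle_patches.grid.shape
    curves = [sb.coherence_curve(speckle_patches.patch(iz, ix)).R_hat
              for iz in range(nz) for ix in range(nx)]
    return np.mean(curves, axis=0)


@pytest.fixture(scope="session")
def stone_data_noiseless():
    """Noise-free channel data of the standard 10 mm stone phantom."""
    scene = sb.make_stone_phantom(10.0, seed=1)
    cfg = sb.in_vitro_preset(seed=1)
    return scene, sb.simulate_channel_data(scene, cfg)
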