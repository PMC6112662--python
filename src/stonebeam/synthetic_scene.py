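"""Phantom scenes and plane-wave channel-data simulation.

The scene model is the one the downstream analysis assumes: fully developed
speckle (many sub-resolution scatterers per cell, zero-mean amplitudes), a
stone represented as a dense grid of strong coherent scatterers, and a
posterior shadow in which echoes are attenuated.  Propagation is single
scattering with exact plane-wave transmit and two-way geometric delays; no
frequency-dependent attenuation and no multiple scattering.

The posterior shadow is modelled on both legs of the echo path: a scatterer
behind the stone is attenuated for a steering angle whose (tilted) geometric
shadow covers it, and additionally for each receive element whose straight
ray back to the array crosses the stone.  Optional zero-mean Gaussian
receiver noise can be added; it is off by default and enabled by the study
presets, because a noise floor is what limits the detectability of a shadow
on a real receive chain.
"""

from __future__ import annotations

import ast
import configparser
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from ._kernels import deposit_spikes, rx_sample_table
from .acquisition import AcquisitionConfig
from .exceptions import InvalidParameterError, OutOfBoundsError

__all__ = [
    "Stone",
    "Scene",
    "ChannelData",
    "make_stone_phantom",
    "make_speckle_phantom",
    "simulate_channel_data",
    "transmit_pulse",
    "write_scene_ini",
    "read_scene_ini",
    "IN_VITRO_WAVELENGTH",
]

#: wavelength of the bench-top preset (5.2 MHz in 1480 m/s water/gel)
IN_VITRO_WAVELENGTH = 1480.0 / 5.2e6


@dataclass(frozen=True)
class Stone:
    """Coherent specular-like target: centre, extent and reflectivity."""

    x: float
    z: float
    width: float
    thickness: float
    reflectivity: float = 30.0

    @property
    def z_bottom(self) -> float:
        return self.z + self.thickness / 2.0

    @property
    def z_top(self) -> float:
        return self.z - self.thickness / 2.0


@dataclass(frozen=True)
class Scene:
    """Scatterer content of one phantom.

    diffuse_scatterers and stone_scatterers are (n, 3) arrays of
    (x, z, amplitude) in metres; field_of_view is (x_min, x_max, z_min, z_max).
    """

    diffuse_scatterers: np.ndarray
    stone: Optional[Stone]
    shadow_transmission: float
    field_of_view: tuple
    stone_scatterers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.diffuse_scatterers, dtype=float).reshape(-1, 3)
        s = np.asarray(self.stone_scatterers, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "diffuse_scatterers", d)
        object.__setattr__(self, "stone_scatterers", s)
        if not (0.0 <= self.shadow_transmission <= 1.0):
            raise InvalidParameterError("shadow_transmission must lie in [0, 1]")
        if self.stone is not None and self.stone.width <= 0:
            raise InvalidParameterError("stone width must be positive")
        x0, x1, z0, z1 = self.field_of_view
        for arr in (d, s):
            if arr.size:
                if not np.all(np.isfinite(arr)):
                    raise InvalidParameterError("scatterer positions/amplitudes must be finite")
                eps = 1e-12
                if (arr[:, 0].min() < x0 - eps or arr[:, 0].max() > x1 + eps
                        or arr[:, 1].min() < z0 - eps or arr[:, 1].max() > z1 + eps):
                    raise OutOfBoundsError("scatterers outside field_of_view")

    @property
    def n_scatterers(self) -> int:
        return self.diffuse_scatterers.shape[0] + self.stone_scatterers.shape[0]

    def union(self, other: "Scene") -> "Scene":
        """Scene containing both scatterer sets (for linearity checks)."""
        fov = (min(self.field_of_view[0], other.field_of_view[0]),
               max(self.field_of_view[1], other.field_of_view[1]),
               min(self.field_of_view[2], other.field_of_view[2]),
               max(self.field_of_view[3], other.field_of_view[3]))
        if self.stone is not None and other.stone is not None:
            raise InvalidParameterError("cannot union two scenes that both hold a stone")
        stone = self.stone if self.stone is not None else other.stone
        keep = self if self.stone is not None else other
        return Scene(
            diffuse_scatterers=np.vstack([self.diffuse_scatterers, other.diffuse_scatterers]),
            stone=stone,
            shadow_transmission=keep.shadow_transmission if stone is not None else 1.0,
            field_of_view=fov,
            stone_scatterers=np.vstack([self.stone_scatterers, other.stone_scatterers]),
        )


@dataclass(frozen=True)
class ChannelData:
    """Raw per-angle, per-element, per-sample echo records.

    samples is (n_angles, n_elements, n_samples) float32; t0 is the time of
    the first sample relative to the plane wave crossing the array origin.
    """

    samples: np.ndarray
    t0: float
    fs: float
    config: AcquisitionConfig

    def __post_init__(self):
        s = self.samples
        if s.ndim != 3:
            raise InvalidParameterError("samples must be (angle, element, sample)")
        if s.shape[0] != self.config.n_angles or s.shape[1] != self.config.geometry.n_elements:
            raise InvalidParameterError("samples shape inconsistent with config")
        if not np.all(np.isfinite(s)):
            raise InvalidParameterError("channel data must be finite")
        if self.t0 > 2.0 * self.config.depth_max / self.config.c + 1e-12:
            raise InvalidParameterError("t0 exceeds the round trip to depth_max")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[2])

    def scaled(self, k: float) -> "ChannelData":
        return ChannelData(samples=(self.samples * np.float32(k)), t0=self.t0,
                           fs=self.fs, config=self.config)


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------


def _uniform_scatterers(rng, n, x0, x1, z0, z1, exclude_box=None):
    """n uniform scatterer positions; positions inside exclude_box are
    re-drawn so the count stays exactly n (the stone displaces gel)."""
    xs = rng.uniform(x0, x1, size=n)
    zs = rng.uniform(z0, z1, size=n)
    if exclude_box is not None:
        bx0, bx1, bz0, bz1 = exclude_box
        bad = (xs > bx0) & (xs < bx1) & (zs > bz0) & (zs < bz1)
        while np.any(bad):
            m = int(bad.sum())
            xs[bad] = rng.uniform(x0, x1, size=m)
            zs[bad] = rng.uniform(z0, z1, size=m)
            bad = (xs > bx0) & (xs < bx1) & (zs > bz0) & (zs < bz1)
    return xs, zs


def make_stone_phantom(width_mm: float, depth_cm: float = 8.0,
                       shadow_transmission: float = 0.1, density: float = 10.0,
                       seed: int = 0, *, wavelength_m: float = IN_VITRO_WAVELENGTH,
                       margin_mm: float = 8.0, field_width_mm: float | None = None,
                       field_height_mm: float = 19.0, field_top_offset_mm: float = 5.0,
                       reflectivity: float = 30.0, thickness_mm: float | None = None) -> Scene:
    """Speckle phantom with one embedded stone and its posterior shadow.

    The diffuse scatterer count is density * field_area / wavelength**2
    (``density`` scatterers per resolution cell of area lambda^2), with
    amplitudes drawn standard normal.  The stone is a grid of scatterers at
    lambda/4 spacing with constant amplitude ``reflectivity`` (in units of the
    background RMS); each grid point is jittered uniformly by up to
    +-lambda/8 per axis so the stone face is rough on a sub-wavelength scale
    (a perfectly regular grid would act as a flat specular mirror, which is
    not how real calculi scatter).  Identical arguments reproduce the
    identical scene.
    """
    if width_mm <= 0:
        raise InvalidParameterError("width_mm must be positive")
    if density <= 0:
        raise InvalidParameterError("density must be positive")
    if not (0.0 <= shadow_transmission <= 1.0):
        raise InvalidParameterError("shadow_transmission must lie in [0, 1]")

    w = width_mm * 1e-3
    zc = depth_cm * 1e-2
    th = (min(width_mm, 1.5) if thickness_mm is None else thickness_mm) * 1e-3
    if field_width_mm is None:
        half_x = w / 2.0 + (margin_mm + 1.0) * 1e-3
    else:
        half_x = field_width_mm * 1e-3 / 2.0
    z0 = zc - field_top_offset_mm * 1e-3
    z1 = z0 + field_height_mm * 1e-3
    area = (2.0 * half_x) * (z1 - z0)
    n = int(round(density * area / wavelength_m ** 2))

    rng = np.random.default_rng(seed)
    stone_box = (-w / 2.0, w / 2.0, zc - th / 2.0, zc + th / 2.0)
    xs, zs = _uniform_scatterers(rng, n, -half_x, half_x, z0, z1, exclude_box=stone_box)
    amps = rng.standard_normal(n)
    diffuse = np.column_stack([xs, zs, amps])

    step = wavelength_m / 4.0
    gx = np.arange(-w / 2.0 + step / 2.0, w / 2.0, step)
    gz = np.arange(zc - th / 2.0 + step / 2.0, zc + th / 2.0, step)
    sx, sz = np.meshgrid(gx, gz)
    sx = sx.ravel() + rng.uniform(-step / 2.0, step / 2.0, sx.size)
    sz = sz.ravel() + rng.uniform(-step / 2.0, step / 2.0, sz.size)
    stone_scat = np.column_stack([sx, sz,
                                  np.full(sx.size, float(reflectivity))])

    params = dict(width_mm=width_mm, depth_cm=depth_cm,
                  shadow_transmission=shadow_transmission, density=density,
                  seed=int(seed), wavelength_m=wavelength_m, margin_mm=margin_mm,
                  field_height_mm=field_height_mm,
                  field_top_offset_mm=field_top_offset_mm,
                  reflectivity=reflectivity,
                  thickness_mm=th * 1e3)
    if field_width_mm is not None:
        params["field_width_mm"] = field_width_mm
    return Scene(diffuse_scatterers=diffuse,
                 stone=Stone(x=0.0, z=zc, width=w, thickness=th, reflectivity=reflectivity),
                 shadow_transmission=shadow_transmission,
                 field_of_view=(-half_x, half_x, z0, z1),
                 stone_scatterers=stone_scat, params=params)


def make_speckle_phantom(x_span_mm=(-10.0, 10.0), z_span_mm=(35.0, 45.0),
                         density: float = 10.0, seed: int = 0, *,
                         wavelength_m: float = IN_VITRO_WAVELENGTH) -> Scene:
    """Stone-free fully developed speckle block (for statistics tests)."""
    if density <= 0:
        raise InvalidParameterError("density must be positive")
    x0, x1 = (v * 1e-3 for v in x_span_mm)
    z0, z1 = (v * 1e-3 for v in z_span_mm)
    area = (x1 - x0) * (z1 - z0)
    n = int(round(density * area / wavelength_m ** 2))
    rng = np.random.default_rng(seed)
    xs, zs = _uniform_scatterers(rng, n, x0, x1, z0, z1)
    amps = rng.standard_normal(n)
    return Scene(diffuse_scatterers=np.column_stack([xs, zs, amps]), stone=None,
                 shadow_transmission=1.0, field_of_view=(x0, x1, z0, z1),
                 params=dict(density=density, seed=int(seed), wavelength_m=wavelength_m))


def point_scene(x_mm: float, z_mm: float, amplitude: float = 1.0,
                pad_mm: float = 1.0) -> Scene:
    """Single point scatterer (resolution / delay checks)."""
    x, z = x_mm * 1e-3, z_mm * 1e-3
    p = pad_mm * 1e-3
    return Scene(diffuse_scatterers=np.array([[x, z, amplitude]]), stone=None,
                 shadow_transmission=1.0,
                 field_of_view=(x - p, x + p, z - p, z + p))


def empty_scene(x_span_mm=(-5.0, 5.0), z_span_mm=(30.0, 50.0)) -> Scene:
    return Scene(diffuse_scatterers=np.zeros((0, 3)), stone=None,
                 shadow_transmission=1.0,
                 field_of_view=(x_span_mm[0] * 1e-3, x_span_mm[1] * 1e-3,
                                z_span_mm[0] * 1e-3, z_span_mm[1] * 1e-3))


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def transmit_pulse(config: AcquisitionConfig):
    """Sampled transmit pulse: n_cycles of the carrier under a raised-cosine
    (Hann) envelope, centred on t=0.  Returns (waveform, centre_index)."""
    T = config.n_cycles / config.f0
    half = int(np.ceil(T / 2.0 * config.fs))
    k = np.arange(-half, half + 1)
    t = k / config.fs
    env = np.where(np.abs(t) <= T / 2.0, 0.5 * (1.0 + np.cos(2.0 * np.pi * t / T)), 0.0)
    return (np.cos(2.0 * np.pi * config.f0 * t) * env), half


def _delay_bounds(scene: Scene, config: AcquisitionConfig):
    pts = np.vstack([scene.diffuse_scatterers[:, :2], scene.stone_scatterers[:, :2]])
    x, z = pts[:, 0], pts[:, 1]
    ang = config.angles_rad
    tau_tx = (z[:, None] * np.cos(ang)[None, :] + x[:, None] * np.sin(ang)[None, :]) / config.c
    ex = config.geometry.element_x
    near = np.clip(x, ex[0], ex[-1])
    rx_min = np.sqrt((x - near) ** 2 + z ** 2) / config.c
    far = np.maximum(np.abs(x - ex[0]), np.abs(x - ex[-1]))
    rx_max = np.sqrt(far ** 2 + z ** 2) / config.c
    return float((tau_tx.min(axis=1) + rx_min).min()), float((tau_tx.max(axis=1) + rx_max).max())


def simulate_channel_data(scene: Scene, config: AcquisitionConfig, *,
                          noise_rms: float = 0.0,
                          occlude_receive: bool = True) -> ChannelData:
    """Single-scattering plane-wave simulation.

    For each angle theta and scatterer (x, z, a), the echo on element i is
    a * T * p(t - tau_tx - tau_rx_i) with tau_tx = (z cos(theta) + x sin(theta))/c
    and tau_rx_i = sqrt((x - x_i)^2 + z^2)/c.  T multiplies in the shadow
    transmission once if the scatterer sits in the stone's tilted transmit
    shadow for that angle and once per occluded receive element.  Echoes are
    positioned to sub-sample precision with a cubic fractional-delay kernel
    and superpose linearly.

    noise_rms > 0 adds white Gaussian receiver noise of that RMS (in the same
    units as the scatterer amplitudes' echoes) from a stream derived from
    config.seed, so identical inputs give bit-identical output.
    """
    x0f, x1f, z0f, z1f = scene.field_of_view
    if z1f > config.depth_max + 1e-12:
        raise OutOfBoundsError(
            f"scene extends to z={z1f:g} m beyond depth_max={config.depth_max:g} m")
    if scene.diffuse_scatterers.size and scene.diffuse_scatterers[:, 1].min() <= 0:
        raise OutOfBoundsError("scatterers must lie at positive depth")

    pulse, ic = transmit_pulse(config)
    T_pulse = config.n_cycles / config.f0
    if scene.n_scatterers == 0:
        t0 = 0.0
        n_samples = int(np.ceil((2.0 * config.depth_max / config.c + T_pulse) * config.fs))
        samples = np.zeros((config.n_angles, config.geometry.n_elements, n_samples),
                           dtype=np.float32)
        return ChannelData(samples=samples, t0=t0, fs=config.fs, config=config)

    tau_min, tau_max = _delay_bounds(scene, config)
    guard = 4.0 / config.fs
    t0 = max(0.0, tau_min - T_pulse / 2.0 - guard)
    t0 = np.floor(t0 * config.fs) / config.fs
    n_samples = int(np.ceil((tau_max + T_pulse / 2.0 + guard - t0) * config.fs)) + 1

    diffuse = scene.diffuse_scatterers
    stone_scat = scene.stone_scatterers
    xs = np.concatenate([diffuse[:, 0], stone_scat[:, 0]])
    zs = np.concatenate([diffuse[:, 1], stone_scat[:, 1]])
    amps = np.concatenate([diffuse[:, 2], stone_scat[:, 2]])
    has_stone = scene.stone is not None
    if has_stone:
        zb = scene.stone.z_bottom
        shadow_ok = np.concatenate([diffuse[:, 1] > zb,
                                    np.zeros(stone_scat.shape[0], dtype=bool)])
        sx, hw = scene.stone.x, scene.stone.width / 2.0
    else:
        zb, sx, hw = 0.0, 0.0, 0.0
        shadow_ok = np.zeros(xs.shape[0], dtype=bool)

    elem_x = config.geometry.element_x
    ang = config.angles_rad
    out = np.empty((config.n_angles, elem_x.size, n_samples), dtype=np.float32)
    # receive delays are angle-independent: tabulate once in sample units
    # (float32 keeps the table small; the <1e-3-sample rounding is far below
    # the fractional-delay kernel's own accuracy)
    rx_samples = np.empty((xs.size, elem_x.size), dtype=np.float32)
    rx_sample_table(xs, zs, elem_x, 1.0 / config.c, config.fs, rx_samples)
    spikes = np.empty((elem_x.size, n_samples), dtype=np.float64)
    for a in range(config.n_angles):
        spikes[:] = 0.0
        deposit_spikes(xs, zs, amps, rx_samples, shadow_ok, elem_x,
                       np.sin(ang[a]), np.cos(ang[a]), 1.0 / config.c,
                       config.fs, t0, has_stone, sx, zb, hw,
                       scene.shadow_transmission, occlude_receive, spikes)
        rf = fftconvolve(spikes, pulse[None, :], mode="full", axes=1)
        out[a] = rf[:, ic:ic + n_samples].astype(np.float32)

    if noise_rms > 0.0:
        rng = np.random.default_rng([int(config.seed), 0x6E015E])
        out = out + rng.standard_normal(out.shape, dtype=np.float32) * np.float32(noise_rms)
    return ChannelData(samples=out, t0=t0, fs=config.fs, config=config)


# --------------------------------------------------------------------------
# plain-text scene serialization
# --------------------------------------------------------------------------


def write_scene_ini(path, scene: Scene) -> None:
    """Write the generating parameters of a phantom scene as a [scene] section."""
    if not scene.params:
        raise InvalidParameterError("scene carries no generating parameters to serialize")
    cp = configparser.ConfigParser()
    cp["scene"] = {k: repr(v) for k, v in scene.params.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def read_scene_ini(path) -> Scene:
    """Rebuild a phantom scene from a [scene] parameter section."""
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise InvalidParameterError(f"cannot read scene file {path}")
    raw = {k: ast.literal_eval(v) for k, v in cp["scene"].items()}
    raw["seed"] = int(raw["seed"])
    return make_stone_phantom(**raw)
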