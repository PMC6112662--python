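"""Delay-and-sum reconstruction: fixed-focus B-mode and plane-wave synthetic
focusing (PWSF), plus per-pixel aligned channel patches for the coherence
beamformers.

All images are returned on a linear scale (analytic-signal envelope);
``envelope_logcompress`` is for display only and no metric is ever computed on
log-compressed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from . import _kernels
from .exceptions import (InvalidParameterError, OutOfBoundsError,
                         PatchTruncationError)
from .synthetic_scene import ChannelData

__all__ = [
    "ImageGrid",
    "BeamformedImage",
    "AlignedPatches",
    "delay_align",
    "das_bmode",
    "pwsf",
    "das_rf_image",
    "envelope_logcompress",
    "envelope_grid",
    "coherence_grid",
]


@dataclass(frozen=True)
class ImageGrid:
    """Pixel-centre axes in metres: x lateral, z axial."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        for name, ax in (("x", x), ("z", z)):
            if ax.ndim != 1 or ax.size < 1:
                raise InvalidParameterError(f"{name} axis must be a 1-D array")
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise InvalidParameterError(f"{name} axis must be strictly increasing")

    @property
    def shape(self):
        return (self.z.size, self.x.size)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if self.z.size > 1 else 0.0

    def validate_axial_sampling(self, fs: float, c: float) -> None:
        """Envelope beamformers need at least one pixel per pair of RF samples
        (axial spacing <= c/fs) so the analytic signal is well sampled."""
        if self.z.size > 1 and self.dz > c / fs * (1 + 1e-9):
            raise InvalidParameterError(
                f"axial pixel spacing {self.dz:g} m exceeds c/fs = {c / fs:g} m; "
                "refine the grid for envelope detection")


def envelope_grid(x_span_mm, z_span_mm, data: ChannelData, dx_mm: float | None = None) -> ImageGrid:
    """RF-rate grid for B-mode/PWSF: axial step c/fs, lateral step pitch/2."""
    c, fs = data.config.c, data.fs
    dz = c / fs
    dx = (data.config.geometry.pitch / 2.0) if dx_mm is None else dx_mm * 1e-3
    x = np.arange(x_span_mm[0] * 1e-3, x_span_mm[1] * 1e-3 + dx / 2, dx)
    z = np.arange(z_span_mm[0] * 1e-3, z_span_mm[1] * 1e-3 + dz / 2, dz)
    return ImageGrid(x=x, z=z)


def coherence_grid(x_span_mm, z_span_mm, data: ChannelData,
                   dx_mm: float = 0.298, dz_mm: float = 0.3) -> ImageGrid:
    """Coarser grid for SLSC/MLSC (lag sums vary on the speckle scale)."""
    x = np.arange(x_span_mm[0] * 1e-3, x_span_mm[1] * 1e-3 + dx_mm * 1e-3 / 2, dx_mm * 1e-3)
    z = np.arange(z_span_mm[0] * 1e-3, z_span_mm[1] * 1e-3 + dz_mm * 1e-3 / 2, dz_mm * 1e-3)
    return ImageGrid(x=x, z=z)


@dataclass(frozen=True)
class BeamformedImage:
    """Linear-scale image values on a grid, with method provenance."""

    grid: ImageGrid
    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.shape:
            raise InvalidParameterError("image shape does not match grid")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("image values must be finite")
        if np.any(v < 0):
            raise InvalidParameterError("linear-scale image values must be non-negative")


@dataclass(frozen=True)
class AlignedPatches:
    """Per-pixel delay-aligned channel segments s_i(n).

    patches has shape (nz, nx, n_elements, kernel_samples); truncated flags
    pixels whose kernel would need samples beyond the recorded trace.
    """

    grid: ImageGrid
    patches: np.ndarray
    kernel_samples: int
    angle_index: object
    truncated: np.ndarray

    def patch(self, iz: int, ix: int) -> np.ndarray:
        return self.patches[iz, ix]


def _angle_args(data: ChannelData):
    ang = data.config.angles_rad
    return (np.sin(ang), np.cos(ang))


def delay_align(data: ChannelData, grid: ImageGrid, angle_index="all",
                kernel_samples: int = None, strict: bool = True) -> AlignedPatches:
    """Transmit+receive delay alignment of the channel data for every pixel.

    angle_index="all" coherently sums the per-angle aligned patches
    (synthetic transmit focusing); an integer selects a single plane wave.
    kernel_samples must be odd; default is one carrier wavelength of samples
    rounded up to odd.  Pixels needing samples beyond the trace raise
    PatchTruncationError (strict=True) or are flagged in ``truncated``.
    """
    cfg = data.config
    if kernel_samples is None:
        kernel_samples = int(round(data.fs / cfg.f0)) | 1
    if kernel_samples < 1 or kernel_samples % 2 == 0:
        raise InvalidParameterError("kernel_samples must be odd and >= 1")
    if grid.z.max() > cfg.depth_max + 1e-12 or grid.z.min() <= 0:
        raise OutOfBoundsError("grid outside the imaging depth range")
    ai = -1 if angle_index == "all" else int(angle_index)
    if ai >= cfg.n_angles:
        raise InvalidParameterError("angle_index out of range")
    nz, nx = grid.shape
    n_el = cfg.geometry.n_elements
    patches = np.zeros((nz, nx, n_el, kernel_samples), dtype=np.float64)
    truncated = np.zeros((nz, nx), dtype=np.bool_)
    _kernels.align_patches(data.samples, data.t0, data.fs, 1.0 / cfg.c,
                           cfg.geometry.element_x, *_angle_args(data),
                           grid.x, grid.z, kernel_samples // 2, ai,
                           patches, truncated)
    if strict and truncated.any():
        n_bad = int(truncated.sum())
        raise PatchTruncationError(
            f"{n_bad} pixel(s) need samples beyond the recorded trace; "
            "pass strict=False to get flagged patches")
    return AlignedPatches(grid=grid, patches=patches, kernel_samples=kernel_samples,
                          angle_index=angle_index, truncated=truncated)


def _rx_options(apodization: str, f_number) -> tuple:
    if apodization not in ("uniform", "hann"):
        raise InvalidParameterError("apodization must be 'uniform' or 'hann'")
    if f_number is not None and f_number <= 0:
        raise InvalidParameterError("f_number must be positive (or None for full aperture)")
    return apodization == "hann", 0.0 if f_number is None else float(f_number)


def das_rf_image(data: ChannelData, grid: ImageGrid, *, focus_depth: float | None = None,
                 angle_indices=None, apodization: str = "uniform",
                 f_number: float | None = None) -> np.ndarray:
    """Pre-envelope delay-and-sum RF image.

    focus_depth=None gives exact per-pixel plane-wave transmit delays (PWSF);
    a depth in metres synthesizes a fixed transmit focus there.  angle_indices
    optionally restricts compounding to a subset of the recorded angles.
    apodization/f_number control the receive aperture (defaults: uniform
    weights, full aperture); f_number gates elements to |x - x_i| <= z/(2 F).
    """
    cfg = data.config
    samples = data.samples
    sin_t, cos_t = _angle_args(data)
    hann, fnum = _rx_options(apodization, f_number)
    if angle_indices is not None:
        idx = np.atleast_1d(np.asarray(angle_indices, dtype=int))
        samples = np.ascontiguousarray(samples[idx])
        sin_t, cos_t = sin_t[idx], cos_t[idx]
    out = np.zeros(grid.shape, dtype=np.float64)
    _kernels.das_rf(samples, data.t0, data.fs, 1.0 / cfg.c,
                    cfg.geometry.element_x, sin_t, cos_t, grid.x, grid.z,
                    focus_depth is not None,
                    0.0 if focus_depth is None else float(focus_depth),
                    hann, fnum, out)
    return out


def _envelope(rf: np.ndarray) -> np.ndarray:
    if rf.shape[0] < 2:
        return np.abs(rf)
    return np.abs(hilbert(rf, axis=0))


def das_bmode(data: ChannelData, grid: ImageGrid, focus_depth: float = 0.04,
              *, apodization: str = "uniform",
              f_number: float | None = None) -> BeamformedImage:
    """Fixed-transmit-focus B-mode synthesized from the angled plane waves.

    Each steering angle is delayed so all wavefronts coincide at the focal
    depth on the image line; away from the focus the transmit is modelled as
    a straight-ray arrival, so focusing is exact at z=focus_depth and
    progressively defocused elsewhere.  Receive is full-aperture uniform
    delay-and-sum; the envelope is the analytic-signal magnitude.
    """
    cfg = data.config
    if not (0.0 < focus_depth <= cfg.depth_max):
        raise InvalidParameterError(
            f"focus_depth {focus_depth:g} m outside (0, depth_max={cfg.depth_max:g}]")
    grid.validate_axial_sampling(data.fs, cfg.c)
    rf = das_rf_image(data, grid, focus_depth=focus_depth,
                      apodization=apodization, f_number=f_number)
    return BeamformedImage(grid=grid, values=_envelope(rf), method="bmode",
                           params={"focus_depth": focus_depth,
                                   "apodization": apodization, "f_number": f_number})


def pwsf(data: ChannelData, grid: ImageGrid, angle_indices=None, *,
         apodization: str = "uniform", f_number: float | None = None) -> BeamformedImage:
    """Plane-wave synthetic focusing: per-angle DAS with exact per-pixel
    transmit delays, coherently compounded across angles, then envelope."""
    grid.validate_axial_sampling(data.fs, data.config.c)
    rf = das_rf_image(data, grid, focus_depth=None, angle_indices=angle_indices,
                      apodization=apodization, f_number=f_number)
    n_ang = data.config.n_angles if angle_indices is None else len(np.atleast_1d(angle_indices))
    return BeamformedImage(grid=grid, values=_envelope(rf), method="pwsf",
                           params={"n_angles": n_ang,
                                   "apodization": apodization, "f_number": f_number})


def envelope_logcompress(image: BeamformedImage, dynamic_range_dB: float = 60.0) -> np.ndarray:
    """20*log10(values/max) clipped to [-dynamic_range_dB, 0].  Display only."""
    if dynamic_range_dB <= 0:
        raise InvalidParameterError("dynamic_range_dB must be positive")
    peak = image.values.max()
    if peak <= 0:
        raise InvalidParameterError("cannot log-compress an all-zero image")
    floor = peak * 10.0 ** (-dynamic_range_dB / 20.0 - 2)
    db = 20.0 * np.log10(np.maximum(image.values, floor) / peak)
    return np.clip(db, -dynamic_range_dB, 0.0)
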