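"""Lag-domain spatial coherence imaging (SLSC and MLSC).

The spatial-coherence curve R(m) is the average normalized zero-delay
correlation between receive-element signals m elements apart, computed on a
short axial kernel after focusing delays.  For diffuse scattering and a
uniformly weighted transmit aperture the van Cittert-Zernike theorem predicts
the triangle R(m) ~ 1 - m/N; a specular stone stays coherent out to long
lags, which is what the mid-lag image exploits.

SLSC sums R(m) over the shortest lags on synthetically transmit-focused
channel data (coherent compounding before correlation); MLSC sums a mid-lag
band per steering angle and compounds the clipped per-angle sums
incoherently, which suppresses diffuse tissue while keeping coherent targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .beamform import AlignedPatches, BeamformedImage, ImageGrid
from .exceptions import (InsufficientAnglesError, InvalidParameterError,
                         OutOfBoundsError, UndefinedMetricError)
from .synthetic_scene import ChannelData

__all__ = [
    "CoherenceConfig",
    "CoherenceCurve",
    "coherence_curve",
    "slsc_image",
    "mlsc_image",
    "default_short_lag",
    "default_mid_lags",
]


def default_short_lag(n_elements: int) -> int:
    """Conventional short-lag upper bound Q: 5% of the aperture, at least 2."""
    return max(2, int(round(0.05 * n_elements)))


def default_mid_lags(n_elements: int) -> tuple:
    """Mid-lag band [M1, M2]: 20% to 50% of the aperture."""
    return (int(round(0.20 * n_elements)), int(round(0.50 * n_elements)))


@dataclass(frozen=True)
class CoherenceConfig:
    """Lag band and kernel for a coherence image.

    compounding is "coherent_prefocus" (sum angles before correlating; SLSC)
    or "incoherent_per_angle" (correlate each angle, sum clipped values; MLSC).
    """

    lag_lo: int
    lag_hi: int
    kernel_samples: int | None = None
    compounding: str = "coherent_prefocus"

    def __post_init__(self):
        if self.lag_lo < 1 or self.lag_hi < self.lag_lo:
            raise InvalidParameterError("need 1 <= lag_lo <= lag_hi")
        if self.compounding not in ("coherent_prefocus", "incoherent_per_angle"):
            raise InvalidParameterError(f"unknown compounding '{self.compounding}'")

    @property
    def n_lags(self) -> int:
        return self.lag_hi - self.lag_lo + 1


@dataclass(frozen=True)
class CoherenceCurve:
    """Normalized correlation per element lag, lags 1..N-1."""

    lags: np.ndarray
    R_hat: np.ndarray

    def __post_init__(self):
        if np.any(np.abs(self.R_hat) > 1.0 + 1e-9):
            raise InvalidParameterError("coherence values must lie in [-1, 1]")

    def band_sum(self, lag_lo: int, lag_hi: int) -> float:
        sel = (self.lags >= lag_lo) & (self.lags <= lag_hi)
        return float(self.R_hat[sel].sum())


def coherence_curve(patch: np.ndarray) -> CoherenceCurve:
    """R(m) for one aligned patch s_i(n), shape (n_elements, kernel_samples).

    R(m) = mean over element pairs (i, i+m) of the zero-delay normalized
    correlation of their kernels; pairs where either kernel has zero energy
    are excluded (the divisor shrinks accordingly).
    """
    p = np.asarray(getattr(patch, "patch", patch), dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise InvalidParameterError("patch must be (n_elements >= 2, kernel_samples)")
    n = p.shape[0]
    energy = np.einsum("ik,ik->i", p, p)
    if not np.any(energy > 0):
        raise UndefinedMetricError("coherence undefined for an all-zero patch")
    lags = np.arange(1, n)
    r = np.empty(n - 1, dtype=float)
    for m in lags:
        num = np.einsum("ik,ik->i", p[:-m], p[m:])
        e = energy[:-m] * energy[m:]
        ok = e > 0
        r[m - 1] = float((num[ok] / np.sqrt(e[ok])).mean()) if ok.any() else 0.0
    r = np.clip(r, -1.0, 1.0)
    return CoherenceCurve(lags=lags, R_hat=r)


def _common(data: ChannelData, grid: ImageGrid, config: CoherenceConfig):
    cfg = data.config
    n = cfg.geometry.n_elements
    if config.lag_hi >= n:
        raise InvalidParameterError(f"lag_hi={config.lag_hi} must be < n_elements={n}")
    if grid.z.max() > cfg.depth_max + 1e-12 or grid.z.min() <= 0:
        raise OutOfBoundsError("grid outside the imaging depth range")
    k = config.kernel_samples
    if k is None:
        k = int(round(data.fs / cfg.f0)) | 1
    if k < 3 or k % 2 == 0:
        raise InvalidParameterError("kernel_samples must be odd and >= 3")
    ang = cfg.angles_rad
    return (data.samples, data.t0, data.fs, 1.0 / cfg.c, cfg.geometry.element_x,
            np.sin(ang), np.cos(ang), grid.x, grid.z, k // 2)


def slsc_image(data: ChannelData, grid: ImageGrid,
               config: CoherenceConfig | None = None) -> BeamformedImage:
    """Short-lag spatial coherence image on synthetically focused data.

    Pixel value = sum of R(m) for m = 1..Q computed on the coherently
    angle-compounded aligned patch; negative sums are clipped to 0.
    """
    if config is None:
        config = CoherenceConfig(lag_lo=1,
                                 lag_hi=default_short_lag(data.config.geometry.n_elements))
    if config.lag_lo != 1 or config.compounding != "coherent_prefocus":
        raise InvalidParameterError(
            "SLSC requires lag_lo=1 and coherent_prefocus compounding")
    args = _common(data, grid, config)
    out = np.zeros(grid.shape, dtype=np.float64)
    _kernels.slsc_kernel(*args, config.lag_hi, out)
    return BeamformedImage(grid=grid, values=out, method="slsc",
                           params={"Q": config.lag_hi,
                                   "kernel_samples": 2 * args[-1] + 1})


def mlsc_image(data: ChannelData, grid: ImageGrid,
               config: CoherenceConfig | None = None) -> BeamformedImage:
    """Mid-lag spatial coherence with incoherent angle compounding.

    Per angle: coherence on that angle's plane-wave-aligned patch, summed over
    lags [M1, M2] and clipped at 0; the pixel is the sum of those non-negative
    per-angle values.  Never coherently sums across angles, so it needs at
    least two transmissions.
    """
    n = data.config.geometry.n_elements
    if config is None:
        m1, m2 = default_mid_lags(n)
        config = CoherenceConfig(lag_lo=m1, lag_hi=m2,
                                 compounding="incoherent_per_angle")
    if config.lag_lo <= 1 or config.compounding != "incoherent_per_angle":
        raise InvalidParameterError(
            "MLSC requires lag_lo > 1 and incoherent_per_angle compounding")
    if data.config.n_angles < 2:
        raise InsufficientAnglesError(
            "incoherent compounding needs at least 2 plane-wave angles")
    args = _common(data, grid, config)
    out = np.zeros(grid.shape, dtype=np.float64)
    _kernels.mlsc_kernel(*args, config.lag_lo, config.lag_hi, out)
    return BeamformedImage(grid=grid, values=out, method="mlsc",
                           params={"M1": config.lag_lo, "M2": config.lag_hi,
                                   "kernel_samples": 2 * args[-1] + 1,
                                   "n_angles": data.config.n_angles})
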