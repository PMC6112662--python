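"""ROI-based image-quality metrics: stone/shadow contrast, CNR, SNR, sizing.

Every metric is computed on linear-scale image values (envelope or coherence),
never on log-compressed displays, so all dB metrics are invariant to global
gain.  Sign conventions: stone contrast is 20*log10(mu_stone/mu_background);
shadow contrast carries a leading minus so that a darker shadow (an easier
detection task) scores higher; sizing error is measured minus reference, so
overestimation is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beamform import BeamformedImage, ImageGrid
from .exceptions import EmptyDetectionError, InvalidParameterError, UndefinedMetricError

__all__ = [
    "ROI",
    "ROIStats",
    "MeasurementRecord",
    "rect_roi",
    "roi_stats",
    "stone_contrast",
    "shadow_contrast",
    "cnr",
    "snr",
    "sizing_error",
    "measure_stone_width",
]


@dataclass(frozen=True)
class ROI:
    """Pixel-membership mask over an image grid, with a semantic label."""

    mask: np.ndarray
    label: str

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if not m.any():
            raise InvalidParameterError(f"ROI '{self.label}' is empty")


def rect_roi(grid: ImageGrid, x_mm, z_mm, label: str) -> ROI:
    """Rectangular ROI from lateral and axial extents in millimetres."""
    x0, x1 = (v * 1e-3 for v in x_mm)
    z0, z1 = (v * 1e-3 for v in z_mm)
    mask = ((grid.z[:, None] >= z0) & (grid.z[:, None] <= z1)
            & (grid.x[None, :] >= x0) & (grid.x[None, :] <= x1))
    return ROI(mask=mask, label=label)


@dataclass(frozen=True)
class ROIStats:
    """Mean/standard deviation of linear image values inside one region."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InvalidParameterError("ROI must contain at least one pixel")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be non-negative")


def roi_stats(image: BeamformedImage, roi: ROI) -> ROIStats:
    if roi.mask.shape != image.values.shape:
        raise InvalidParameterError("ROI mask shape does not match image")
    vals = image.values[roi.mask]
    return ROIStats(mu=float(vals.mean()), sigma=float(vals.std(ddof=0)), n=int(vals.size))


@dataclass(frozen=True)
class MeasurementRecord:
    """One stone under one method: the row unit of the study tables."""

    phantom_id: str
    method: str
    contrast_dB: float
    cnr_dB: float
    snr: float
    measured_size_mm: float
    reference_size_mm: float
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def sizing_error_mm(self) -> float:
        return self.measured_size_mm - self.reference_size_mm


def stone_contrast(stone: ROIStats, background: ROIStats) -> float:
    """20*log10(mu_stone / mu_background) in dB."""
    if background.mu <= 0:
        raise UndefinedMetricError("contrast undefined: background mean is zero")
    if stone.mu == 0:
        return -math.inf
    return 20.0 * math.log10(stone.mu / background.mu)


def shadow_contrast(shadow: ROIStats, gel: ROIStats) -> float:
    """-20*log10(mu_shadow / mu_gel): darker shadow gives a higher value."""
    if shadow.mu <= 0 or gel.mu <= 0:
        raise UndefinedMetricError("shadow contrast undefined: zero region mean")
    return -20.0 * math.log10(shadow.mu / gel.mu)


def cnr(stone: ROIStats, background: ROIStats) -> float:
    """20*log10(|mu_s - mu_b| / sqrt(sigma_s^2 + sigma_b^2)) in dB."""
    var = stone.sigma ** 2 + background.sigma ** 2
    if var <= 0:
        raise UndefinedMetricError("CNR undefined: both region variances are zero")
    diff = abs(stone.mu - background.mu)
    if diff == 0:
        return -math.inf
    return 20.0 * math.log10(diff / math.sqrt(var))


def snr(stone: ROIStats, background: ROIStats) -> float:
    """Lesion signal-to-noise ratio |mu_s - mu_b| / sigma_b (dimensionless)."""
    if background.sigma <= 0:
        raise UndefinedMetricError("SNR undefined: background sigma is zero")
    return abs(stone.mu - background.mu) / background.sigma


def sizing_error(measured_mm: float, reference_mm: float) -> float:
    """Signed sizing error in mm; positive means overestimation."""
    if measured_mm < 0 or reference_mm <= 0:
        raise InvalidParameterError("sizes must be positive")
    return measured_mm - reference_mm


def measure_stone_width(image: BeamformedImage, stone_roi: ROI,
                        threshold_dB: float = -6.0) -> float:
    """Lateral extent (mm) of in-ROI pixels within threshold_dB of the ROI peak.

    An automated stand-in for the study's manual caliper measurement: the
    width is max-min lateral coordinate of pixels brighter than
    peak * 10^(threshold_dB/20) inside the search region.
    """
    if threshold_dB >= 0:
        raise InvalidParameterError("threshold_dB must be negative")
    if stone_roi.mask.shape != image.values.shape:
        raise InvalidParameterError("ROI mask shape does not match image")
    vals = np.where(stone_roi.mask, image.values, -np.inf)
    peak = vals.max()
    if not np.isfinite(peak) or peak <= 0:
        raise EmptyDetectionError("no positive pixel inside the stone search region")
    above = vals >= peak * 10.0 ** (threshold_dB / 20.0)
    cols = np.where(above.any(axis=0))[0]
    if cols.size == 0:
        raise EmptyDetectionError("no pixel above the sizing threshold")
    return float((image.grid.x[cols[-1]] - image.grid.x[cols[0]]) * 1e3)
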