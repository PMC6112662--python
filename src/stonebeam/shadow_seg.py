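"""Automated posterior-shadow delineation.

A neighbourhood-aware intensity-class segmentation (iterated conditional
modes) splits the log-compressed display image into k intensity classes; the
shadow candidate is the darkest class laterally connected to the stone's
position inside a band reaching 1 cm below the stone.  The shadow's lateral
width is the difference between the average left and right edges over the
band's rows, and never uses the reference stone size.

Detection is decided by the image alone: the candidate must cover a minimum
fraction of the band's rows and sit several dB below the surrounding
same-depth pixels; otherwise the outcome is "no shadow detected", which is a
valid, reportable state (coherence images of well-insonified tissue show no
shadow at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import icm_sweeps
from .beamform import ImageGrid
from .exceptions import (DegenerateSegmentationError, InvalidParameterError,
                         OutOfBoundsError)

__all__ = [
    "SegmentationResult",
    "ShadowMeasurement",
    "segment_classes",
    "segmentation_energy",
    "extract_shadow",
    "shadow_sizing_error",
]


@dataclass(frozen=True)
class SegmentationResult:
    """Per-pixel class map with class means sorted ascending (0 = darkest)."""

    class_map: np.ndarray
    class_means: np.ndarray
    n_iterations: int
    converged: bool
    beta: float
    normalized_means: np.ndarray
    normalization: tuple


def segment_classes(image: np.ndarray, k_classes: int = 3, beta: float = 1.0,
                    max_iter: int = 50) -> SegmentationResult:
    """Iterative intensity-class segmentation of a display-scale image.

    The image is normalized to [0, 1]; classes are initialized from intensity
    quantiles; each raster sweep reassigns every pixel to the class minimizing
    (I - mu_c)^2 + beta * (number of disagreeing 8-neighbours) and recomputes
    the class means, stopping when no pixel changes.  beta is therefore in
    units of the squared normalized intensity.  Deterministic given inputs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    if k_classes < 2:
        raise InvalidParameterError("k_classes must be >= 2")
    if beta < 0:
        raise InvalidParameterError("beta must be non-negative")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        raise DegenerateSegmentationError("constant image cannot be segmented")
    norm = (img - lo) / (hi - lo)

    qs = np.quantile(norm, np.linspace(0, 1, k_classes + 1)[1:-1])
    labels = np.digitize(norm, qs).astype(np.int32)
    means = np.empty(k_classes, dtype=np.float64)
    for c in range(k_classes):
        sel = labels == c
        means[c] = norm[sel].mean() if sel.any() else float(c) / max(k_classes - 1, 1)

    n_iter, converged = icm_sweeps(norm, labels, means, float(beta), int(max_iter))

    order = np.argsort(means, kind="stable")
    relabel = np.empty(k_classes, dtype=np.int32)
    relabel[order] = np.arange(k_classes, dtype=np.int32)
    labels = relabel[labels]
    norm_means = means[order]
    class_means = norm_means * (hi - lo) + lo
    return SegmentationResult(class_map=labels, class_means=class_means,
                              n_iterations=int(n_iter), converged=bool(converged),
                              beta=float(beta), normalized_means=norm_means,
                              normalization=(lo, hi))


def segmentation_energy(image: np.ndarray, seg: SegmentationResult) -> float:
    """ICM objective: sum of squared class deviations (normalized intensity)
    plus beta times the number of disagreeing 8-neighbour pairs."""
    lo, hi = seg.normalization
    norm = (np.asarray(image, dtype=float) - lo) / (hi - lo)
    mu = seg.normalized_means[seg.class_map]
    data_term = float(((norm - mu) ** 2).sum())
    lab = seg.class_map
    pairs = 0
    pairs += int((lab[1:, :] != lab[:-1, :]).sum())
    pairs += int((lab[:, 1:] != lab[:, :-1]).sum())
    pairs += int((lab[1:, 1:] != lab[:-1, :-1]).sum())
    pairs += int((lab[1:, :-1] != lab[:-1, 1:]).sum())
    return data_term + seg.beta * pairs


@dataclass(frozen=True)
class ShadowMeasurement:
    """Shadow band measurement: average edges and lateral width in mm."""

    shadow_mask: np.ndarray
    detected: bool
    left_edge_mm: float
    right_edge_mm: float
    width_mm: float
    band_depth_mm: float
    row_coverage: float
    depth_below_surround_dB: float

    def __post_init__(self):
        if self.detected and self.width_mm < 0:
            raise InvalidParameterError("shadow width must be non-negative")


def extract_shadow(seg: SegmentationResult, grid: ImageGrid,
                   stone_bottom_z_mm: float, stone_center_x_mm: float,
                   display: np.ndarray | None = None, *,
                   band_depth_mm: float = 10.0,
                   min_row_coverage: float = 0.4,
                   min_depth_dB: float = 2.0,
                   search_halfwidth_mm: float = 1.0) -> ShadowMeasurement:
    """Shadow selection in the band from the stone's bottom to 1 cm below it.

    Per band row, the shadow pixels are the laterally connected run of
    darkest-class pixels containing (or within search_halfwidth_mm of) the
    stone's lateral position; rows without such a run are excluded from the
    edge averages.  left/right edges are the means over contributing rows and
    width their difference.  The shadow counts as detected only if the
    candidate covers at least min_row_coverage of the band's rows and, when a
    display image is supplied, lies at least min_depth_dB below the mean of
    the other same-depth pixels.  The 2 dB default reflects that genuine
    fixed-focus B-mode stone shadows are only a few dB deep; a stricter
    threshold would reject shadows a reader can plainly see.
    """
    z0 = stone_bottom_z_mm * 1e-3
    z1 = z0 + band_depth_mm * 1e-3
    rows = np.where((grid.z >= z0) & (grid.z <= z1))[0]
    if rows.size == 0 or z1 > grid.z.max() + grid.dz:
        raise OutOfBoundsError("the 1 cm shadow band does not fit inside the image")
    lab = seg.class_map
    nz, nx = lab.shape
    jc = int(np.argmin(np.abs(grid.x - stone_center_x_mm * 1e-3)))
    j_win = np.where(np.abs(grid.x - stone_center_x_mm * 1e-3) <= search_halfwidth_mm * 1e-3)[0]
    if j_win.size == 0:
        j_win = np.array([jc])

    mask = np.zeros((nz, nx), dtype=bool)
    lefts, rights = [], []
    for i in rows:
        dark = lab[i] == 0
        seeds = j_win[dark[j_win]]
        if seeds.size == 0:
            continue
        j = int(seeds[0])
        a = j
        while a > 0 and dark[a - 1]:
            a -= 1
        b = j
        while b < nx - 1 and dark[b + 1]:
            b += 1
        # merge runs of any other seeds (disconnected from the first run)
        for j2 in seeds:
            if not (a <= j2 <= b):
                aa = int(j2)
                while aa > 0 and dark[aa - 1]:
                    aa -= 1
                bb = int(j2)
                while bb < nx - 1 and dark[bb + 1]:
                    bb += 1
                a, b = min(a, aa), max(b, bb)
        mask[i, a:b + 1] = dark[a:b + 1]
        lefts.append(grid.x[a] * 1e3)
        rights.append(grid.x[b] * 1e3)

    coverage = len(lefts) / rows.size
    depth_db = math.nan
    if display is not None and mask.any():
        band_mask = np.zeros_like(mask)
        band_mask[rows, :] = True
        other = band_mask & ~mask
        if other.any():
            depth_db = float(display[other].mean() - display[mask].mean())
    detected = coverage >= min_row_coverage
    if detected and display is not None and np.isfinite(depth_db):
        detected = depth_db >= min_depth_dB
    if not lefts:
        detected = False

    if detected:
        left = float(np.mean(lefts))
        right = float(np.mean(rights))
        width = right - left
    else:
        left = right = width = math.nan
    return ShadowMeasurement(shadow_mask=mask, detected=detected,
                             left_edge_mm=left, right_edge_mm=right,
                             width_mm=width, band_depth_mm=band_depth_mm,
                             row_coverage=coverage,
                             depth_below_surround_dB=depth_db)


def shadow_sizing_error(measurement: ShadowMeasurement,
                        stone_width_mm: float) -> float | None:
    """Signed shadow-width error (mm) vs the reference stone width; None when
    no shadow was detected (excluded from summaries, with a logged count)."""
    if stone_width_mm <= 0:
        raise InvalidParameterError("reference stone width must be positive")
    if not measurement.detected:
        return None
    return measurement.width_mm - stone_width_mm
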