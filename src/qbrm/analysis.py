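"""Quantification utilities: ROI retardance statistics, percent change,
focus stacking, and optical-resolution arithmetic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import BirefringenceResults

__all__ = ["ROIMask", "MicroscopeSpec", "roi_mean_retardance",
           "percent_change", "focus_stack", "abbe_resolution",
           "retardance_change_report"]


@dataclass(frozen=True)
class ROIMask:
    """Boolean region mask with a label for reporting."""
    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class MicroscopeSpec:
    """Objective/illumination description for resolution arithmetic."""
    wavelength_nm: float
    numerical_aperture: float
    magnification: str = ""

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.numerical_aperture <= 1.7:
            raise ValueError("numerical aperture must lie in (0, 1.7]")


def roi_mean_retardance(results: BirefringenceResults, roi: ROIMask,
                        restrict_to_valid: bool = True):
    """Mean relative retardance over an ROI.

    The effective region is the ROI intersected with the validity mask
    (pass ``restrict_to_valid=False`` to include sub-threshold background
    pixels).  Returns ``(mean, n_pixels)``; an empty effective region is
    an error.
    """
    if roi.mask.shape != results.shape:
        raise ValueError("ROI shape does not match maps")
    eff = roi.mask & results.valid_mask if restrict_to_valid else roi.mask
    n = int(eff.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.label!r} selects no pixels")
    return float(results.retardance[eff].mean()), n


def percent_change(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after``; positive = loss."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (before - after) / before


def retardance_change_report(before: BirefringenceResults,
                             after: BirefringenceResults,
                             rois: list[ROIMask]) -> pd.DataFrame:
    """Before/after mean retardance and percent change per ROI.

    Both the valid-masked and unrestricted (all-ROI-pixel) means are
    reported, since whether sub-threshold pixels belong in the average is
    a judgement call that changes the statistic.
    """
    rows = []
    for roi in rois:
        mb, nb = roi_mean_retardance(before, roi)
        ma, na = roi_mean_retardance(after, roi)
        mb_all, _ = roi_mean_retardance(before, roi, restrict_to_valid=False)
        ma_all, _ = roi_mean_retardance(after, roi, restrict_to_valid=False)
        rows.append({
            "roi": roi.label,
            "n_before": nb, "n_after": na,
            "mean_before": mb, "mean_after": ma,
            "percent_change": percent_change(mb, ma),
            "mean_before_all": mb_all, "mean_after_all": ma_all,
            "percent_change_all": percent_change(mb_all, ma_all),
        })
    return pd.DataFrame(rows)


def focus_stack(zstack: np.ndarray, window: int = 9,
                metric: str = "laplacian_variance"):
    """All-in-focus composite of a z-stack by per-pixel plane selection.

    For each pixel the plane maximizing the local variance of the
    Laplacian (computed over an odd ``window``) is selected; ties break
    toward the lowest z index, and composite values are copied, never
    blended, so every output pixel comes from exactly one input plane.
    Returns ``(composite, depth_index)``.
    """
    z = np.asarray(zstack, dtype=float)
    if z.ndim == 2:
        z = z[None]
    if z.ndim != 3 or z.shape[0] < 1:
        raise ValueError("zstack must be a (n_planes, H, W) array")
    if metric != "laplacian_variance":
        raise ValueError(f"unknown focus metric {metric!r}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(z.shape[1:]):
        raise ValueError("window larger than image")
    sharp = np.empty_like(z)
    for i, plane in enumerate(z):
        lap = ndimage.laplace(plane)
        mean = ndimage.uniform_filter(lap, window)
        mean_sq = ndimage.uniform_filter(lap * lap, window)
        sharp[i] = mean_sq - mean * mean
    depth = np.argmax(sharp, axis=0)  # first max wins: lowest-z tie-break
    composite = np.take_along_axis(z, depth[None], axis=0)[0]
    return composite, depth


def abbe_resolution(spec: MicroscopeSpec) -> float:
    """Abbe diffraction-limited lateral resolution, lambda/(2 NA), in nm."""
    return spec.wavelength_nm / (2.0 * spec.numerical_aperture)
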