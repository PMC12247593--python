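"""Visualizations of qBRM data.

Three renderings are produced:

* **raw RGB** — the unprocessed frames at 0/60/120 deg stored directly as
  the R, G and B channels.  Because the three angles uniformly sample the
  pixel sinusoid, hue qualitatively encodes optic-axis orientation and
  brightness encodes transmittance/retardance, with zero computation.
* **grayscale maps** — transmittance or retardance displayed directly,
  with percentile clipping and gamma.
* **retardance-weighted orientation map** — each pixel coloured by its
  optic-axis orientation (hue = 2*phi, so phi and phi+180 coincide) with
  brightness given by retardance, which automatically darkens pixels with
  no birefringent structure.  A matching colour-wheel legend is generated
  with the identical hue mapping.

The exact hue anchor (which orientation is red) and wheel rotation are
configurable; rotating the wheel by 90 deg recolours maps by fiber
direction instead of the (radial) myelin optic axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .model import BirefringenceResults
from .stack import PolStack

__all__ = ["RenderConfig", "render_raw_rgb", "render_orientation_map",
           "render_grayscale", "color_wheel_legend"]


@dataclass(frozen=True)
class RenderConfig:
    wheel_rotation_deg: float = 0.0
    intensity_gamma: float = 1.0
    percentile_clip: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        if self.intensity_gamma <= 0:
            raise ValueError("gamma must be positive")
        lo, hi = self.percentile_clip
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentiles must be ordered within [0, 100]")


def _scale(values: np.ndarray, config: RenderConfig) -> np.ndarray:
    """Percentile-clip to [0, 1] then apply gamma; monotone in the input."""
    lo, hi = np.percentile(values, config.percentile_clip)
    if hi <= lo:
        # degenerate (constant) display range: positive signal shows at
        # full brightness, zero stays black
        return (values > 0).astype(float)
    out = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    return out ** config.intensity_gamma


def render_raw_rgb(stack: PolStack) -> np.ndarray:
    """Stack the 0/60/120 deg frames as R, G, B with one shared scale.

    A single global factor (the stack maximum) scales all three channels;
    per-channel normalization would destroy the orientation encoding.
    Returns a float RGB image in [0, 1].
    """
    r = stack.frame(0.0)
    g = stack.frame(60.0)
    b = stack.frame(120.0)
    rgb = np.stack([r, g, b], axis=-1)
    peak = float(rgb.max())
    if peak > 0:
        rgb = rgb / peak
    return np.clip(rgb, 0.0, 1.0)


def render_orientation_map(results: BirefringenceResults,
                           config: RenderConfig = RenderConfig()):
    """Retardance-weighted orientation colouring.

    hue = 2 * (phi + wheel_rotation) mod 360; saturation = 1;
    value = scaled retardance; masked pixels are black.  Returns the RGB
    image and a colour-wheel legend using the identical hue mapping.
    """
    hue = (2.0 * (results.orientation_deg + config.wheel_rotation_deg)) % 360.0
    value = _scale(results.retardance, config)
    value = np.where(results.valid_mask, value, 0.0)
    hsv = np.stack([hue / 360.0, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv), color_wheel_legend(config)


def color_wheel_legend(config: RenderConfig = RenderConfig(),
                       size: int = 128) -> np.ndarray:
    """Colour wheel with the same hue = 2*(phi + rotation) mapping.

    Full saturation/value inside the unit disk, transparent-black outside;
    the angular position of a wheel pixel is the orientation it encodes
    (period 180 deg, so the wheel repeats twice around).
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    dy, dx = cy - yy, xx - cx  # y up
    radius = np.hypot(dy, dx) / (size / 2.0)
    phi = np.rad2deg(np.arctan2(dy, dx)) % 180.0
    hue = (2.0 * (phi + config.wheel_rotation_deg)) % 360.0
    inside = radius <= 1.0
    hsv = np.stack([hue / 360.0, np.ones_like(hue),
                    inside.astype(float)], axis=-1)
    return hsv_to_rgb(hsv)


def render_grayscale(values: np.ndarray,
                     config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Display a single parameter map with percentile clip and gamma."""
    return _scale(np.asarray(values, dtype=float), config)
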