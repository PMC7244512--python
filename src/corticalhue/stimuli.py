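"""Synthetic colour stimuli: uniform hue fields, hue-circle sample sets, hue wheel.

All stimuli are defined in HSL (hue in degrees, saturation and lightness in
[0, 1]) and delivered to the network as H x W x 3 LMS cone images.  The
tuning protocol keeps saturation at 1 and lightness at 0.5 and varies only
the hue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colourspace import hsl_to_rgb, rgb_to_lms
from .errors import InputDomainError

__all__ = ["StimulusSpec", "uniform_hue_field", "hue_circle_samples", "hue_wheel_image"]


@dataclass(frozen=True)
class StimulusSpec:
    """A uniform colour field: one HSL colour filling a square image."""

    hue_deg: float
    saturation: float = 1.0
    lightness: float = 0.5
    size_px: int = 256

    def validate(self) -> None:
        if self.size_px <= 0:
            raise InputDomainError("size_px must be positive")
        if not 0 <= self.saturation <= 1:
            raise InputDomainError("saturation must lie in [0, 1]")
        if not 0 <= self.lightness <= 1:
            raise InputDomainError("lightness must lie in [0, 1]")


def uniform_hue_field(spec: StimulusSpec) -> np.ndarray:
    """A size x size x 3 cone image where every pixel is the same colour."""
    spec.validate()
    lms = rgb_to_lms(hsl_to_rgb(spec.hue_deg, spec.saturation, spec.lightness))
    return np.broadcast_to(lms, (spec.size_px, spec.size_px, 3)).copy()


def hue_circle_samples(n: int, start_deg: float = 0.0) -> np.ndarray:
    """``n`` equally spaced HSL hue angles on [0, 360), starting at ``start_deg``."""
    if n < 1:
        raise InputDomainError("n must be >= 1")
    return np.mod(start_deg + np.arange(n) * (360.0 / n), 360.0)


def hue_wheel_image(size_px: int, saturation: float = 1.0, lightness: float = 0.5) -> np.ndarray:
    """A full-disc hue wheel on a mid-grey background, as a cone image.

    The HSL hue at each pixel is the polar angle around the image centre;
    pixels outside the inscribed disc, and the centre itself, are achromatic
    mid-grey.
    """
    if size_px <= 0:
        raise InputDomainError("size_px must be positive")
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px].astype(float)
    dx, dy = xx - c, yy - c
    r = np.hypot(dx, dy)
    ang = np.mod(np.degrees(np.arctan2(-dy, dx)), 360.0)
    inside = (r <= size_px / 2.0) & (r > 0)
    h = np.where(inside, ang, 0.0)
    s = np.where(inside, saturation, 0.0)
    l = np.full_like(h, lightness)
    return rgb_to_lms(hsl_to_rgb(h, s, l))
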