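"""Colour-space conversions: HSL, sRGB, LMS cone space and MacLeod-Boynton chromaticity.

The model works on LMS cone activations.  Stimuli are specified in HSL,
converted to sRGB, gamma-linearized, mapped to CIE XYZ (D65) and finally to
LMS cone excitations with a Stockman-Sharpe-based transformation.  Tuning is
reported as a hue angle in the MacLeod-Boynton (MB) chromaticity plane, whose
abscissa is L/(L+M) and whose ordinate is S/(L+M).

Cone fundamentals carry an arbitrary per-cone scale.  The S-cone row of the
transformation is multiplied by :data:`S_AXIS_SCALE`, a calibration constant
fixed once so that the HSL red primary (hue 0 deg, s=1, l=0.5) lands at
18 deg in the MB plane -- the conventional anchor for this stimulus set.
Because the same scaled cone signals feed the opponent network, the S-opponent
and L/M-opponent channels also end up with commensurate response magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AchromaticError, DegenerateChromaticityError, InputDomainError

__all__ = [
    "MBPoint",
    "RGB_TO_XYZ",
    "XYZ_TO_LMS",
    "S_AXIS_SCALE",
    "rgb_to_lms_matrix",
    "hsl_to_rgb",
    "linearize_srgb",
    "rgb_to_lms",
    "white_point_lms",
    "mb_coordinates",
    "mb_hue_angle",
]

#: sRGB (linear) -> CIE XYZ, D65 white point.
RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: CIE XYZ -> LMS, Stockman-Sharpe cone-fundamental transformation.
XYZ_TO_LMS = np.array(
    [
        [0.210576, 0.855098, -0.0396983],
        [-0.417076, 1.177260, 0.0786283],
        [0.0, 0.0, 0.5168350],
    ]
)

#: Calibrated S-cone scale: places HSL hue 0 (red) at 18 deg in the MB plane.
S_AXIS_SCALE = 0.27787217823481836


def rgb_to_lms_matrix(
    rgb_to_xyz: np.ndarray | None = None,
    xyz_to_lms: np.ndarray | None = None,
    s_scale: float = S_AXIS_SCALE,
) -> np.ndarray:
    """Composite linear-RGB -> LMS matrix with the S row scaled by ``s_scale``."""
    a = RGB_TO_XYZ if rgb_to_xyz is None else np.asarray(rgb_to_xyz, float)
    b = XYZ_TO_LMS if xyz_to_lms is None else np.asarray(xyz_to_lms, float)
    m = b @ a
    m = m.copy()
    m[2] *= s_scale
    return m


_DEFAULT_M = rgb_to_lms_matrix()


@dataclass(frozen=True)
class MBPoint:
    """A point in the MacLeod-Boynton plane.

    ``l_mb`` is L/(L+M), ``s_mb`` is S/(L+M) and ``angle_deg`` is the hue
    angle of the chromatic vector relative to the white point, in [0, 360).
    """

    l_mb: float
    s_mb: float
    angle_deg: float


def hsl_to_rgb(h, s, l) -> np.ndarray:
    """Convert HSL to sRGB.  Accepts scalars or broadcastable arrays.

    Hue ``h`` is in degrees (any finite value, wrapped mod 360); saturation
    ``s`` and lightness ``l`` must lie in [0, 1].  Returns an array with a
    trailing axis of length 3 holding (r, g, b) in [0, 1].
    """
    h = np.asarray(h, float)
    s = np.asarray(s, float)
    l = np.asarray(l, float)
    if not np.all(np.isfinite(h)):
        raise InputDomainError("hue must be finite")
    if np.any((s < 0) | (s > 1)):
        raise InputDomainError("saturation must lie in [0, 1]")
    if np.any((l < 0) | (l > 1)):
        raise InputDomainError("lightness must lie in [0, 1]")

    h = np.mod(h, 360.0)
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4, sector == 5],
                   [c, x, z, z, x, c])
    g1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4, sector == 5],
                   [x, c, c, x, z, z])
    b1 = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4, sector == 5],
                   [z, z, x, c, c, x])
    m = l - c / 2.0
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


def linearize_srgb(rgb: np.ndarray) -> np.ndarray:
    """Undo the sRGB transfer function (gamma) componentwise."""
    c = np.asarray(rgb, float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def rgb_to_lms(rgb: np.ndarray, matrix: np.ndarray | None = None) -> np.ndarray:
    """Map sRGB values in [0, 1] to LMS cone activations.

    ``rgb`` may be a single triple or an H x W x 3 raster.  The conversion is
    sRGB gamma linearization followed by the composite linear matrix (see
    :func:`rgb_to_lms_matrix`); the result is clipped at zero.
    """
    rgb = np.asarray(rgb, float)
    if rgb.shape[-1] != 3:
        raise InputDomainError("rgb must have a trailing axis of length 3")
    if np.any((rgb < 0) | (rgb > 1)):
        raise InputDomainError("rgb components must lie in [0, 1]")
    m = _DEFAULT_M if matrix is None else np.asarray(matrix, float)
    lms = linearize_srgb(rgb) @ m.T
    return np.maximum(lms, 0.0)


def white_point_lms(matrix: np.ndarray | None = None) -> np.ndarray:
    """LMS of the reference white: the mid-grey HSL stimulus (any h, s=0, l=0.5)."""
    return rgb_to_lms(hsl_to_rgb(0.0, 0.0, 0.5), matrix=matrix)


def mb_coordinates(lms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MacLeod-Boynton coordinates (l_mb, s_mb) = (L/(L+M), S/(L+M))."""
    lms = np.asarray(lms, float)
    lum = lms[..., 0] + lms[..., 1]
    if np.any(lum <= 0):
        raise DegenerateChromaticityError("L + M must be positive")
    return lms[..., 0] / lum, lms[..., 2] / lum


def mb_hue_angle(lms: np.ndarray, white: np.ndarray | None = None) -> np.ndarray:
    """Hue angle in the MB plane, degrees in [0, 360).

    The angle is measured for the chromatic vector (l_mb - l_w, -(s_mb - s_w))
    via the two-argument arctangent; the sign flip on the S ordinate puts lime
    hues at the top of the circle (90 deg) and violet at the bottom.
    Raises :class:`AchromaticError` for a zero chromatic vector.
    """
    if white is None:
        white = white_point_lms()
    l_mb, s_mb = mb_coordinates(lms)
    l_w, s_w = mb_coordinates(white)
    dx = l_mb - l_w
    dy = -(s_mb - s_w)
    if np.any((dx == 0) & (dy == 0)):
        raise AchromaticError("stimulus is achromatic: hue angle undefined")
    return np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)


def mb_point(lms: np.ndarray, white: np.ndarray | None = None) -> MBPoint:
    """Bundle MB coordinates and hue angle for a single LMS triple."""
    l_mb, s_mb = mb_coordinates(lms)
    return MBPoint(float(l_mb), float(s_mb), float(mb_hue_angle(lms, white)))
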