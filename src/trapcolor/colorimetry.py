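"""CIELAB color mathematics for the ΔE bubble-trap analysis.

The pipeline converts camera RGB (normalized to [0, 1]) to CIE XYZ
tristimulus values with the CIE 1931 / sRGB primaries matrix, then to
L*A*B* with the classical piecewise cube-root compression, and finally
measures color change as the Euclidean distance ΔE between two L*A*B*
triples.  All functions accept either scalars/triples or NumPy arrays
whose last axis holds the three channels, and operate in double
precision.

Conventions
-----------
* RGB is treated as already linear: no gamma step is applied by default
  (the conversion matrix is applied directly to the normalized camera
  values).  Pass ``linearize=True`` to apply the sRGB EOTF first for a
  standards-compliant conversion.
* The default reference white is the image of unit RGB under the
  conversion matrix, (0.9505, 1.0000, 1.0890) — i.e. the white the
  matrix itself implies (numerically the D65 white).
* The compression threshold is 0.00886 and the linear-branch slope is
  7.787 with offset 16/116.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "LAB_F_THRESHOLD",
    "LAB_F_SLOPE",
    "LAB_F_OFFSET",
    "ReferenceWhite",
    "default_white",
    "srgb_linearize",
    "rgb_to_xyz",
    "lab_f",
    "xyz_to_lab",
    "rgb_to_lab",
    "delta_e",
    "normalize_frame",
]

#: CIE 1931 RGB→XYZ matrix (sRGB primaries, D65), applied to normalized RGB.
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: Piecewise-compression constants: f(t) = t^(1/3) above the threshold,
#: slope*t + offset at or below it.
LAB_F_THRESHOLD = 0.00886
LAB_F_SLOPE = 7.787
LAB_F_OFFSET = 16.0 / 116.0


@dataclass(frozen=True)
class ReferenceWhite:
    """Tristimulus values (x0, y0, z0) of the reference white.

    All components must be strictly positive; they normalize the XYZ
    values before the L*A*B* compression.
    """

    x0: float
    y0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.x0 > 0 and self.y0 > 0 and self.z0 > 0):
            raise ValueError(
                f"reference white must be strictly positive, got "
                f"({self.x0}, {self.y0}, {self.z0})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0])


def default_white() -> ReferenceWhite:
    """Reference white implied by the conversion matrix: XYZ of unit RGB."""
    w = RGB_TO_XYZ_MATRIX @ np.ones(3)
    return ReferenceWhite(*w)


def srgb_linearize(rgb: np.ndarray) -> np.ndarray:
    """Apply the sRGB EOTF (gamma expansion) to normalized RGB values."""
    rgb = np.asarray(rgb, dtype=float)
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected 3 channels on the last axis, got shape {rgb.shape}")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("RGB channels must lie in [0, 1]; divide 8-bit values by 255")
    return rgb


def rgb_to_xyz(rgb, *, linearize: bool = False) -> np.ndarray:
    """Convert normalized RGB (last axis = channels) to XYZ tristimulus values.

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        Channel values in [0, 1].
    linearize : bool
        If True, apply the sRGB EOTF before the matrix (off by default:
        the matrix is applied directly to the camera values).
    """
    rgb = _validate_rgb(rgb)
    if linearize:
        rgb = srgb_linearize(rgb)
    return rgb @ RGB_TO_XYZ_MATRIX.T


def lab_f(t):
    """Piecewise lightness-compression function.

    ``t**(1/3)`` for t > 0.00886, else ``7.787*t + 16/116``.  Models the
    nonlinear response of human vision; monotone and nearly continuous
    at the branch point.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lab_f requires t >= 0")
    # Evaluate cbrt everywhere (well-defined for t>=0), select by branch.
    out = np.where(t > LAB_F_THRESHOLD, np.cbrt(t), LAB_F_SLOPE * t + LAB_F_OFFSET)
    return out if out.ndim else float(out)


def xyz_to_lab(xyz, white: ReferenceWhite | None = None) -> np.ndarray:
    """Convert XYZ to L*A*B* relative to a reference white.

    L* = 116 f(y/y0) − 16, A* = 500 [f(x/x0) − f(y/y0)],
    B* = 200 [f(y/y0) − f(z/z0)].
    """
    if white is None:
        white = default_white()
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"expected 3 components on the last axis, got shape {xyz.shape}")
    ratios = xyz / white.as_array()
    fx = lab_f(ratios[..., 0])
    fy = lab_f(ratios[..., 1])
    fz = lab_f(ratios[..., 2])
    L = 116.0 * fy - 16.0
    A = 500.0 * (fx - fy)
    B = 200.0 * (fy - fz)
    return np.stack([L, A, B], axis=-1)


def rgb_to_lab(rgb, white: ReferenceWhite | None = None, *, linearize: bool = False) -> np.ndarray:
    """Normalized RGB → L*A*B*: composition of :func:`rgb_to_xyz` and
    :func:`xyz_to_lab`."""
    return xyz_to_lab(rgb_to_xyz(rgb, linearize=linearize), white)


def delta_e(lab_a, lab_b) -> np.ndarray | float:
    """Euclidean color difference ΔE between two L*A*B* triples.

    sqrt((L−L0)² + (A−A0)² + (B−B0)²); symmetric and non-negative.
    Broadcasts over leading axes.
    """
    lab_a = np.asarray(lab_a, dtype=float)
    lab_b = np.asarray(lab_b, dtype=float)
    d = np.sqrt(np.sum((lab_a - lab_b) ** 2, axis=-1))
    return d if d.ndim else float(d)


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Scale an integer image to unit range: 8-bit / 255, 16-bit / 65535.

    Float frames are validated to lie in [0, 1] and passed through.
    NaNs are rejected.
    """
    frame = np.asarray(frame)
    if frame.dtype == np.uint8:
        return frame.astype(float) / 255.0
    if frame.dtype == np.uint16:
        return frame.astype(float) / 65535.0
    out = frame.astype(float)
    if np.any(~np.isfinite(out)):
        raise ValueError("frame contains non-finite pixel values")
    if np.any(out < 0) or np.any(out > 1):
        raise ValueError(f"float frames must lie in [0, 1]; dtype {frame.dtype}")
    return out
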