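"""Representative colour of the retinal background, in CIELAB.

The background's colour is summarised as the per-channel median RGB over the
background mask (lower median for even counts, so the representative colour
is an actually occurring quantised value), then converted to CIELAB under
the sRGB-native convention: IEC 61966-2-1 piecewise linearisation, the D65 /
2-degree-observer XYZ matrix, and the standard f-function with the 6/29
cube-root threshold. Only the chromatic opponent axes (a*, b*) feed the
score; lightness L* is retained for diagnostics but deliberately discarded
by the scale, which is what makes the score robust to illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GradabilityError
from .fundus_io import BinaryMask, FundusImage

#: sRGB (linear) -> CIE XYZ under D65 / 2-degree observer, full published
#: precision. The reverse matrix is its numerical inverse, so the round trip
#: is exact to float precision.
XYZ_FROM_LINRGB = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
LINRGB_FROM_XYZ = np.linalg.inv(XYZ_FROM_LINRGB)

#: D65 reference white (2-degree observer), taken as the XYZ the matrix maps
#: RGB (1,1,1) to, so pure white is exactly achromatic with L* = 100.
WHITE_D65 = XYZ_FROM_LINRGB @ np.ones(3)

_DELTA = 6.0 / 29.0


def _srgb_decode(rgb01: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 piecewise electro-optical transfer function."""
    return np.where(
        rgb01 <= 0.04045, rgb01 / 12.92, ((rgb01 + 0.055) / 1.055) ** 2.4
    )


def _srgb_encode(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(lin, 0.0, None)
    return np.where(
        lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1.0 / 2.4) - 0.055
    )


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(f: np.ndarray) -> np.ndarray:
    return np.where(f > _DELTA, f**3, 3 * _DELTA**2 * (f - 4.0 / 29.0))


def rgb_to_lab_array(rgb255: np.ndarray) -> np.ndarray:
    """Vectorised sRGB (0-255 scale) -> CIELAB for an (..., 3) array."""
    rgb = np.asarray(rgb255, dtype=np.float64) / 255.0
    lin = _srgb_decode(rgb)
    xyz = lin @ XYZ_FROM_LINRGB.T
    f = _lab_f(xyz / WHITE_D65)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_to_rgb_array(lab: np.ndarray) -> np.ndarray:
    """Vectorised CIELAB -> sRGB on the [0, 255] scale.

    Out-of-gamut colours are clipped channel-wise; in-gamut colours round-trip
    through :func:`rgb_to_lab_array` exactly (float precision).
    """
    lab = np.asarray(lab, dtype=np.float64)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack(
        [_lab_f_inv(f) for f in (fx, fy, fz)], axis=-1
    ) * WHITE_D65
    lin = xyz @ LINRGB_FROM_XYZ.T
    return np.clip(_srgb_encode(lin), 0.0, 1.0) * 255.0


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def __iter__(self):
        return iter((self.L, self.a, self.b))

    def __getitem__(self, i):
        return (self.L, self.a, self.b)[i]


@dataclass(frozen=True)
class ChromaPoint:
    """The (a*, b*) chromaticity pair of an eye's background tissue."""

    a: float
    b: float
    image_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b], dtype=float)


def _lower_median(values: np.ndarray) -> float:
    """Median taking the lower of the two central elements for even counts."""
    n = values.shape[0]
    k = (n - 1) // 2
    return float(np.partition(values, k)[k])


def median_rgb(
    image: FundusImage, background: BinaryMask
) -> tuple[float, float, float]:
    """Per-channel (marginal) median RGB over the background mask."""
    if background.shape != image.pixels.shape[:2]:
        raise GradabilityError("background mask does not match image shape")
    if not background.values.any():
        raise GradabilityError("cannot take median over an empty background")
    px = image.pixels[background.values]
    return tuple(_lower_median(px[:, c].astype(np.float64)) for c in range(3))


def rgb_to_lab(rgb) -> LabColor:
    """Convert one 8-bit-scaled RGB triple to CIELAB (D65, 2-degree observer)."""
    lab = rgb_to_lab_array(np.asarray(rgb, dtype=np.float64))
    return LabColor(L=float(lab[0]), a=float(lab[1]), b=float(lab[2]))


def lab_to_rgb(lab) -> np.ndarray:
    """Inverse conversion; returns a float triple on the [0, 255] scale."""
    return lab_to_rgb_array(np.asarray(tuple(lab), dtype=np.float64))


def pixelwise_lab_median(
    image: FundusImage, background: BinaryMask
) -> LabColor:
    """Alternative convention: convert every background pixel, take Lab medians.

    Provided for sensitivity checks against the default marginal-median-RGB
    reading; not used by the standard pipeline.
    """
    if not background.values.any():
        raise GradabilityError("cannot take median over an empty background")
    lab = rgb_to_lab_array(image.pixels[background.values].astype(np.float64))
    return LabColor(*(_lower_median(lab[:, c].copy()) for c in range(3)))


def extract_chromaticity(lab: LabColor, image_id: str = "") -> ChromaPoint:
    """Keep the (a*, b*) pair; L* is dropped from all downstream scoring."""
    return ChromaPoint(a=lab.a, b=lab.b, image_id=image_id)
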