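"""Retinal-background exclusion masking.

The background tissue whose colour defines the pigment score is whatever is
left of the image after removing (1) the dark surround outside the camera's
field of view, found as all pixels at or below the 0.5th percentile of the
grayscale intensity distribution, (2) the retinal vasculature and (3) the
optic disc, with the union of the three successively dilated to keep partial
volumes and segmentation slop out of the colour estimate. The number of
dilation iterations scales with image width: round(4 * width / 600).

Also here: the one-iteration 3x3 erosion/dilation perturbation used by the
mask-sensitivity analysis, a classical vesselness-based fallback segmenter
for self-contained runs, and the rule-based gradability gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .errors import AlignmentError, GradabilityError
from .fundus_io import BinaryMask, FundusImage

#: Rec.601 luma weights; the conversion used to pool RGB into one intensity.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class MaskingParams:
    """Parameters of the exclusion-mask construction.

    border_percentile
        Grayscale percentile (in percent) at or below which a pixel is
        treated as image border / surround. Default 0.5.
    dilation_scale, reference_width
        Dilation iterations = round(dilation_scale * width / reference_width),
        half-to-even rounding. Defaults 4 and 600 px.
    connectivity
        Neighbourhood order of the structuring element; 2 means the full
        8-connected 3x3 element.
    """

    border_percentile: float = 0.5
    dilation_scale: float = 4.0
    reference_width: int = 600
    connectivity: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.border_percentile < 100.0):
            raise ValueError("border_percentile must lie in (0, 100)")
        if self.reference_width <= 0:
            raise ValueError("reference_width must be positive")


@dataclass
class QualityParams:
    """Thresholds of the rule-based gradability gate."""

    min_background_frac: float = 0.10   # of total image area
    max_saturated_frac: float = 0.20    # of background pixels, any channel >= sat_level
    sat_level: int = 250
    min_gray_iqr: float = 5.0           # grayscale IQR over the whole image


def to_grayscale(image: FundusImage) -> np.ndarray:
    """Rec.601 luma (0.299 R + 0.587 G + 0.114 B), float in [0, 255]."""
    px = image.pixels.astype(np.float64)
    w = GRAY_WEIGHTS
    return w[0] * px[..., 0] + w[1] * px[..., 1] + w[2] * px[..., 2]


def detect_border(gray: np.ndarray, params: MaskingParams | None = None) -> BinaryMask:
    """Flag all pixels at or below the given grayscale percentile (inclusive).

    The percentile is the linear-interpolation percentile of the full pixel
    population; ties at the threshold are all flagged. On a constant image
    the threshold equals the constant, so the whole image is flagged — the
    gradability gate then rejects such frames downstream.
    """
    params = params or MaskingParams()
    threshold = np.percentile(gray, params.border_percentile, method="linear")
    return BinaryMask(values=gray <= threshold, kind="border", source="derived")


def dilation_iterations(width: int, params: MaskingParams | None = None) -> int:
    """round(dilation_scale * width / reference_width), half-to-even."""
    params = params or MaskingParams()
    if width <= 0:
        raise ValueError("width must be positive")
    return int(round(params.dilation_scale * width / params.reference_width))


def _structuring_element(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, connectivity)


def build_exclusion_mask(
    vessel: BinaryMask,
    disc: BinaryMask,
    border: BinaryMask,
    params: MaskingParams | None = None,
    width: int | None = None,
    iterations: int | None = None,
) -> BinaryMask:
    """Union of vessel, disc and border masks, then iterated binary dilation.

    ``iterations`` defaults to :func:`dilation_iterations` evaluated at
    ``width`` (or the mask width when neither is given).
    """
    params = params or MaskingParams()
    shapes = {vessel.shape, disc.shape, border.shape}
    if len(shapes) != 1:
        raise AlignmentError(f"mask shapes disagree: {sorted(shapes)}")
    union = vessel.values | disc.values | border.values
    if iterations is None:
        iterations = dilation_iterations(
            width if width is not None else union.shape[1], params
        )
    if iterations > 0 and union.any():
        union = ndi.binary_dilation(
            union,
            structure=_structuring_element(params.connectivity),
            iterations=iterations,
        )
    return BinaryMask(values=union, kind="combined", source="derived")


def retinal_background_mask(
    image: FundusImage,
    vessel: BinaryMask,
    disc: BinaryMask,
    params: MaskingParams | None = None,
    border: BinaryMask | None = None,
) -> tuple[BinaryMask, int]:
    """Complement of the dilated exclusion mask, with its pixel count.

    Raises :class:`GradabilityError` when nothing remains.
    """
    params = params or MaskingParams()
    if border is None:
        border = detect_border(to_grayscale(image), params)
    if vessel.shape != image.pixels.shape[:2] or disc.shape != image.pixels.shape[:2]:
        raise AlignmentError(
            f"mask shape {vessel.shape}/{disc.shape} does not match image "
            f"shape {image.pixels.shape[:2]}"
        )
    exclusion = build_exclusion_mask(
        vessel, disc, border, params, width=image.width
    )
    background = BinaryMask(
        values=~exclusion.values, kind="retinal_background", source="derived"
    )
    count = background.count()
    if count == 0:
        raise GradabilityError(
            "empty retinal background: exclusion mask covers the whole image"
        )
    return background, count


def perturb_mask(mask: BinaryMask, seed: int) -> tuple[BinaryMask, str]:
    """Randomly erode or dilate a mask once with a full 3x3 kernel.

    The seeded generator chooses erosion or dilation with probability 1/2
    each; the choice is returned alongside the perturbed mask. The kernel is
    the full 3x3 square of ones — explicitly distinct from the pipeline's
    connectivity-2 structuring element (identical in shape, but fixed by the
    perturbation definition rather than by ``MaskingParams``).
    """
    rng = np.random.default_rng(seed)
    kernel = np.ones((3, 3), dtype=bool)
    if rng.random() < 0.5:
        out = ndi.binary_erosion(mask.values, structure=kernel)
        choice = "erosion"
    else:
        out = ndi.binary_dilation(mask.values, structure=kernel)
        choice = "dilation"
    return BinaryMask(values=out, kind=mask.kind, source="derived"), choice


def segment_baseline(image: FundusImage) -> tuple[BinaryMask, BinaryMask]:
    """Classical fallback segmenter for vessels and optic disc.

    Vessels: Frangi vesselness on the inverted green-weighted intensity
    (vessels are dark ridges), thresholded by Otsu within an eroded
    field-of-view. Disc: brightest compact region — smoothed intensity
    thresholded near its in-field maximum, largest connected component.
    Deterministic; may return empty masks (downstream area checks flag
    quality).
    """
    gray = to_grayscale(image) / 255.0
    h, w = gray.shape

    # Approximate field of view: anything clearly above the black surround,
    # eroded so rim gradients do not masquerade as ridges.
    field = gray > 0.02
    margin = max(3, int(0.04 * min(h, w)))
    field_core = ndi.binary_erosion(
        field, structure=np.ones((3, 3), bool), iterations=margin
    )

    vessel = np.zeros_like(field)
    if field_core.any():
        smoothed = ndi.gaussian_filter(gray, 0.5)
        ridge = filters.frangi(
            smoothed, sigmas=np.arange(1.0, 3.5, 0.5), black_ridges=True
        )
        ridge = np.where(field_core, ridge, 0.0)
        vals = ridge[field_core]
        if vals.max() > 0:
            # hysteresis: strong ridges seed, weak ridges join if connected
            thr_high = filters.threshold_otsu(vals)
            vessel = filters.apply_hysteresis_threshold(
                ridge, thr_high / 4.0, thr_high
            ).astype(bool)
            vessel = morphology.remove_small_objects(vessel, max_size=7)

    disc = np.zeros_like(field)
    if field_core.any():
        bright = ndi.gaussian_filter(gray, 2.0)
        infield = bright[field_core]
        thr = np.percentile(infield, 98.0)
        cand = (bright >= thr) & field_core
        cand = ndi.binary_opening(cand, structure=np.ones((3, 3), bool))
        labels = measure.label(cand)
        if labels.max() > 0:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            disc = labels == int(np.argmax(sizes))

    return (
        BinaryMask(values=vessel, kind="vessel", source="baseline_segmenter"),
        BinaryMask(values=disc, kind="disc", source="baseline_segmenter"),
    )


def assess_gradability(
    image: FundusImage,
    background: BinaryMask,
    params: QualityParams | None = None,
) -> tuple[bool, list[str]]:
    """Rule-based image quality gate.

    Fails when the background is too small, too saturated, or the image has
    almost no grayscale contrast (interquartile range below the floor).
    """
    params = params or QualityParams()
    reasons: list[str] = []
    total = image.pixels.shape[0] * image.pixels.shape[1]
    n_bg = background.count()
    if n_bg < params.min_background_frac * total:
        reasons.append("empty background")
    if n_bg > 0:
        bg_px = image.pixels[background.values]
        saturated = (bg_px >= params.sat_level).any(axis=1)
        if saturated.mean() > params.max_saturated_frac:
            reasons.append("saturation")
    gray = to_grayscale(image)
    q1, q3 = np.percentile(gray, [25.0, 75.0])
    if (q3 - q1) < params.min_gray_iqr:
        reasons.append("low contrast")
    return (len(reasons) == 0), reasons
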