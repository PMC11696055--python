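"""End-to-end scoring: image -> background mask -> chromaticity -> score.

The per-image path mirrors the method's order of operations: grayscale
border detection, union with the (ingested or baseline-segmented) vessel
and disc masks, iterated dilation, complement to the retinal background,
gradability gate, per-channel median RGB, CIELAB conversion, and — once a
scale is fitted — projection onto the dominant eigenvector. The CLI wraps
these functions; tests and the acceptance experiments call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chromaticity, fundus_io, masking, rps_model
from .errors import GradabilityError
from .fundus_io import BinaryMask, FundusImage
from .masking import MaskingParams, QualityParams
from .rps_model import RPSModel


@dataclass
class ScoreRecord:
    """Everything the scores CSV carries for one image."""

    image_id: str
    participant_id: str
    eye: str
    repeat_index: int
    gradable: bool
    reasons: list[str] = field(default_factory=list)
    n_background: int = 0
    dilation_iterations: int = 0
    median_rgb: tuple[float, float, float] | None = None
    lab: tuple[float, float, float] | None = None
    rps: float | None = None


def score_image(
    image: FundusImage,
    vessel: BinaryMask | None = None,
    disc: BinaryMask | None = None,
    *,
    masking_params: MaskingParams | None = None,
    quality_params: QualityParams | None = None,
    median_space: str = "rgb",
) -> ScoreRecord:
    """Score one image (without projection; see :func:`attach_scores`).

    When vessel/disc masks are not supplied the classical baseline
    segmenter provides them. ``median_space`` selects the representative
    colour convention: ``"rgb"`` (default, marginal per-channel median RGB
    then one conversion) or ``"lab"`` (convert all pixels, Lab medians).
    """
    masking_params = masking_params or MaskingParams()
    record = ScoreRecord(
        image_id=image.image_id,
        participant_id=image.participant_id,
        eye=image.eye,
        repeat_index=image.repeat_index,
        gradable=False,
    )
    record.dilation_iterations = masking.dilation_iterations(
        image.width, masking_params
    )
    if vessel is None or disc is None:
        vessel, disc = masking.segment_baseline(image)
    try:
        background, count = masking.retinal_background_mask(
            image, vessel, disc, masking_params
        )
    except GradabilityError:
        record.reasons = ["empty background"]
        return record
    record.n_background = count
    ok, reasons = masking.assess_gradability(image, background, quality_params)
    record.reasons = reasons
    if not ok:
        return record
    if median_space == "lab":
        lab = chromaticity.pixelwise_lab_median(image, background)
        med = tuple(chromaticity.lab_to_rgb(lab))
    else:
        med = chromaticity.median_rgb(image, background)
        lab = chromaticity.rgb_to_lab(med)
    record.median_rgb = tuple(float(v) for v in med)
    record.lab = (lab.L, lab.a, lab.b)
    record.gradable = True
    return record


def score_records(
    items,
    *,
    masking_params: MaskingParams | None = None,
    quality_params: QualityParams | None = None,
    median_space: str = "rgb",
    use_truth_masks: bool = True,
) -> list[ScoreRecord]:
    """Score a synthetic cohort's records in memory."""
    out = []
    for rec in items:
        vessel = rec.fundus.vessel if use_truth_masks else None
        disc = rec.fundus.disc if use_truth_masks else None
        out.append(
            score_image(
                rec.fundus.image,
                vessel,
                disc,
                masking_params=masking_params,
                quality_params=quality_params,
                median_space=median_space,
            )
        )
    return out


def records_to_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [fundus_io.record_to_row(r) for r in records],
        columns=list(fundus_io.SCORE_COLUMNS),
    )


def chroma_points(frame: pd.DataFrame) -> np.ndarray:
    """Gradable (a, b) pairs from a score frame, in row order."""
    ok = frame[frame["gradable"].astype(bool)]
    return ok[["a", "b"]].to_numpy(dtype=float)


def fit_model(frame: pd.DataFrame) -> RPSModel:
    """Fit the PCA scale to all gradable images in a score frame."""
    return rps_model.fit(chroma_points(frame))


def attach_scores(frame: pd.DataFrame, model: RPSModel) -> pd.DataFrame:
    """Add the ``rps`` column (NaN for ungradable rows)."""
    frame = frame.copy()
    rps = np.full(len(frame), np.nan)
    ok = frame["gradable"].astype(bool).to_numpy()
    if ok.any():
        pts = frame.loc[ok, ["a", "b"]].to_numpy(dtype=float)
        rps[ok] = rps_model.project_many(model, pts)
    frame["rps"] = rps
    return frame


def score_manifest(
    manifest_file,
    *,
    masking_params: MaskingParams | None = None,
    quality_params: QualityParams | None = None,
    median_space: str = "rgb",
) -> list[ScoreRecord]:
    """Score every image referenced by a manifest CSV.

    Vessel/disc masks are ingested when the manifest provides paths,
    otherwise the baseline segmenter runs.
    """
    manifest = fundus_io.load_manifest(manifest_file)
    records = []
    for _, row in manifest.iterrows():
        image = fundus_io.read_image(
            fundus_io.manifest_path(manifest_file, row["image_path"]),
            image_id=str(row["image_path"]),
            participant_id=str(row["participant_id"]),
            eye=row["eye"],
            repeat_index=int(row["repeat_index"]),
        )
        shape = image.pixels.shape[:2]
        vessel = disc = None
        if "vessel_mask_path" in row and isinstance(row.get("vessel_mask_path"), str):
            vessel = fundus_io.read_mask(
                fundus_io.manifest_path(manifest_file, row["vessel_mask_path"]),
                shape,
                "vessel",
            )
        if "disc_mask_path" in row and isinstance(row.get("disc_mask_path"), str):
            disc = fundus_io.read_mask(
                fundus_io.manifest_path(manifest_file, row["disc_mask_path"]),
                shape,
                "disc",
            )
        records.append(
            score_image(
                image,
                vessel,
                disc,
                masking_params=masking_params,
                quality_params=quality_params,
                median_space=median_space,
            )
        )
    return records


def rescore_with_perturbed_masks(
    image: FundusImage,
    vessel: BinaryMask,
    disc: BinaryMask,
    model: RPSModel,
    seed: int,
    *,
    masking_params: MaskingParams | None = None,
) -> tuple[float, str]:
    """Score one image after randomly eroding/dilating its vessel+disc mask.

    The perturbation applies to the combined vessel-and-disc mask (before
    the border union and the pipeline's own dilation), as in the mask
    sensitivity analysis.
    """
    masking_params = masking_params or MaskingParams()
    combined = BinaryMask(values=vessel.values | disc.values, kind="combined")
    perturbed, choice = masking.perturb_mask(combined, seed)
    empty = BinaryMask(values=np.zeros_like(perturbed.values), kind="disc")
    background, _ = masking.retinal_background_mask(
        image, perturbed, empty, masking_params
    )
    med = chromaticity.median_rgb(image, background)
    lab = chromaticity.rgb_to_lab(med)
    point = chromaticity.extract_chromaticity(lab, image.image_id)
    return rps_model.project(model, point), choice


def sensitivity_analysis(
    items,
    model: RPSModel,
    *,
    n_seeds: int = 10,
    seed: int = 0,
    masking_params: MaskingParams | None = None,
) -> pd.DataFrame:
    """Mask-perturbation sensitivity over a scored cohort.

    For every image and every perturbation seed, the combined vessel+disc
    mask is randomly eroded or dilated once (3x3 kernel) and the image is
    rescored with the given model. Returns one row per (image, seed) with
    the baseline score, the perturbed score and their difference.
    """
    rows = []
    seed_rng = np.random.default_rng(seed)
    for rec in items:
        base = score_image(
            rec.fundus.image, rec.fundus.vessel, rec.fundus.disc,
            masking_params=masking_params,
        )
        if not base.gradable:
            continue
        rps0 = rps_model.project(model, np.array(base.lab[1:]))
        for _ in range(n_seeds):
            s = int(seed_rng.integers(0, 2**31 - 1))
            rps1, choice = rescore_with_perturbed_masks(
                rec.fundus.image, rec.fundus.vessel, rec.fundus.disc,
                model, s, masking_params=masking_params,
            )
            rows.append(
                {
                    "image_id": rec.image_id,
                    "seed": s,
                    "choice": choice,
                    "rps_baseline": rps0,
                    "rps_perturbed": rps1,
                    "delta": rps1 - rps0,
                }
            )
    return pd.DataFrame(rows)
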