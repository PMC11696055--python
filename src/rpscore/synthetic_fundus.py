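"""Synthetic fundus images with exact ground truth.

Generates fundus-like rasters — a circular field of view on a black
surround, a background colour driven by a scalar pigment parameter, a
random-walk vessel tree, a bright optic disc, an illumination plane and
sensor noise — together with pixel-exact vessel/disc masks and the true
background Lab colour, so every pipeline stage is testable without any
real imagery.

The pigment parameter p in [0, 1] maps linearly to the background CIELAB
triple: L* 75 -> 35, a* 10 -> 30, b* 25 -> 45 as p goes 0 -> 1 (a light
yellow-orange fundus darkening to a red-brown one). The ramp anchors are
synthetic conventions chosen for plausibility and unambiguous ordering.

Noise model: ``noise_sd`` scales two components added within the field of
view — a per-image per-channel offset (acquisition-level exposure /
white-balance jitter, the component that actually moves a masked median
between repeat captures) and i.i.d. per-pixel Gaussian noise (shot noise,
which a median over thousands of pixels suppresses). Illumination is a
random affine L*-plane (offset plus tilt, each scaled by
``illumination_sd``) applied before conversion to RGB — exactly the
nuisance dimension the chromaticity-only score is designed to discard.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chromaticity import LabColor, lab_to_rgb_array
from .fundus_io import (
    BinaryMask,
    FundusImage,
    write_image,
    write_mask,
)

#: Background Lab at pigment 0 and pigment 1.
RAMP_LIGHT = np.array([75.0, 10.0, 25.0])
RAMP_DARK = np.array([35.0, 30.0, 45.0])

# Lab offsets of rendered structures relative to the local background.
VESSEL_OFFSET = np.array([-22.0, 6.0, -4.0])
DISC_OFFSET = np.array([18.0, -4.0, 6.0])


@dataclass
class SynthParams:
    """Knobs of the synthetic fundus generator (all deterministic per seed)."""

    width: int = 128
    height: int = 128
    pigment: float = 0.5
    vessel_density: float = 0.05      # target vessel fraction of the field
    disc_radius_frac: float = 0.16    # of the field radius
    illumination_sd: float = 0.0      # L*-units of the random affine light plane
    noise_sd: float = 0.0             # 8-bit units; offset + per-pixel components
    l_shift: float = 0.0              # deterministic L* offset of the background
    field_radius_frac: float = 0.94   # of min(width, height)/2
    quantize: bool = True             # False -> float pixels, no 8-bit rounding
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pigment <= 1.0):
            raise ValueError("pigment must lie in [0, 1]")
        if self.illumination_sd < 0 or self.noise_sd < 0 or self.vessel_density < 0:
            raise ValueError("spreads and densities must be non-negative")
        if self.disc_radius_frac >= 0.45:
            raise ValueError("disc does not fit inside the field of view")


@dataclass
class SyntheticFundus:
    """One rendered image plus its exact ground truth."""

    image: FundusImage
    vessel: BinaryMask
    disc: BinaryMask
    field: np.ndarray          # boolean field-of-view mask
    true_lab: LabColor         # background Lab incl. l_shift, excl. illumination
    pigment: float


def pigment_ramp(pigment: float) -> LabColor:
    """Background Lab triple for a pigment value in [0, 1] (linear ramp)."""
    lab = RAMP_LIGHT + pigment * (RAMP_DARK - RAMP_LIGHT)
    return LabColor(*lab)


def _draw_disk(canvas: np.ndarray, cy: float, cx: float, radius: float) -> None:
    y0 = max(0, int(cy - radius - 1))
    y1 = min(canvas.shape[0], int(cy + radius + 2))
    x0 = max(0, int(cx - radius - 1))
    x1 = min(canvas.shape[1], int(cx + radius + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _render_vessels(
    rng: np.random.Generator,
    field: np.ndarray,
    disc_c: tuple[float, float],
    target_density: float,
) -> np.ndarray:
    """Random-walk vessel tree growing outward from the disc."""
    vessel = np.zeros_like(field)
    if target_density <= 0:
        return vessel
    n_field = field.sum()
    h, w = field.shape
    max_steps = 4 * max(h, w)
    for _ in range(60):  # branch budget
        if vessel[field].sum() / n_field >= target_density:
            break
        angle = rng.uniform(0, 2 * np.pi)
        y, x = disc_c
        thickness = rng.uniform(1.0, 1.9)
        for _ in range(max_steps):
            angle += rng.normal(0.0, 0.22)
            y += 1.4 * np.sin(angle)
            x += 1.4 * np.cos(angle)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w) or not field[iy, ix]:
                break
            _draw_disk(vessel, y, x, thickness)
    return vessel & field


def generate_image(params: SynthParams) -> SyntheticFundus:
    """Render one synthetic fundus with exact truth masks.

    Fully deterministic given ``params.seed``: the same parameters yield a
    bit-identical raster.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = params.field_radius_frac * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    field = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2

    base = np.array(
        [
            RAMP_LIGHT[0] + params.pigment * (RAMP_DARK[0] - RAMP_LIGHT[0])
            + params.l_shift,
            RAMP_LIGHT[1] + params.pigment * (RAMP_DARK[1] - RAMP_LIGHT[1]),
            RAMP_LIGHT[2] + params.pigment * (RAMP_DARK[2] - RAMP_LIGHT[2]),
        ]
    )

    # Optic disc: offset horizontally (nasal side chosen by the seed).
    disc_r = params.disc_radius_frac * radius
    side = 1.0 if rng.random() < 0.5 else -1.0
    disc_cy = cy + rng.uniform(-0.15, 0.15) * radius
    disc_cx = cx + side * 0.55 * radius
    disc = np.zeros_like(field)
    if disc_r > 0:
        _draw_disk(disc, disc_cy, disc_cx, disc_r)
        disc &= field

    vessel = _render_vessels(rng, field, (disc_cy, disc_cx), params.vessel_density)

    lab = np.empty((h, w, 3), dtype=np.float64)
    lab[..., 0] = base[0]
    lab[..., 1] = base[1]
    lab[..., 2] = base[2]

    if params.illumination_sd > 0:
        offset = rng.normal(0.0, params.illumination_sd)
        tilt = rng.normal(0.0, params.illumination_sd)
        direction = rng.uniform(0, 2 * np.pi)
        u = ((yy - cy) * np.sin(direction) + (xx - cx) * np.cos(direction)) / radius
        lab[..., 0] += offset + tilt * u

    lab[vessel] += VESSEL_OFFSET
    lab[disc] += DISC_OFFSET
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)

    # Vessel/disc tones may fall slightly out of the sRGB gamut at ramp
    # extremes; those pixels are excluded from scoring, so clipping is fine.
    rgb = lab_to_rgb_array(lab)
    rgb[~field] = 0.0

    if params.noise_sd > 0:
        rgb[field] += rng.normal(0.0, params.noise_sd, size=3)          # acquisition
        rgb[field] += rng.normal(0.0, params.noise_sd, size=(int(field.sum()), 3))
        rgb = np.clip(rgb, 0.0, 255.0)

    if params.quantize:
        pixels: np.ndarray = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    else:
        pixels = rgb

    image = FundusImage(pixels=pixels, image_id=f"synth-{params.seed}")
    return SyntheticFundus(
        image=image,
        vessel=BinaryMask(values=vessel, kind="vessel", source="ingested"),
        disc=BinaryMask(values=disc, kind="disc", source="ingested"),
        field=field,
        true_lab=pigment_ramp(params.pigment)
        if params.l_shift == 0
        else LabColor(base[0], base[1], base[2]),
        pigment=params.pigment,
    )


@dataclass
class CohortRecord:
    fundus: SyntheticFundus
    image_id: str
    participant_id: str
    eye: str
    repeat_index: int


@dataclass
class SyntheticCohort:
    records: list[CohortRecord]
    truth: pd.DataFrame
    manifest: pd.DataFrame | None = None


def generate_cohort(
    n_participants: int,
    params: SynthParams | None = None,
    *,
    seed: int = 0,
    eyes: int = 1,
    repeats: int = 1,
    pigment_range: tuple[float, float] = (0.0, 1.0),
    eye_sd: float = 0.02,
    out_dir: str | os.PathLike | None = None,
) -> SyntheticCohort:
    """Generate a cohort with known pigment truth.

    Participant pigment is uniform over ``pigment_range``; with ``eyes=2``
    each eye's pigment is the participant value plus N(0, eye_sd) (clipped
    to [0, 1]), modelling the high but imperfect left-right symmetry of
    ocular pigmentation. Repeats of the same eye share pigment and differ
    only in illumination and noise draws. When ``out_dir`` is given, images,
    truth masks, a manifest CSV and a truth CSV are written there.
    """
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    params = params or SynthParams()
    rng = np.random.default_rng(seed)
    eye_names = ("right", "left")[:eyes]

    records: list[CohortRecord] = []
    truth_rows = []
    manifest_rows = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    for i in range(n_participants):
        pid = f"P{i:05d}"
        p_subj = rng.uniform(*pigment_range)
        for eye in eye_names:
            p_eye = float(np.clip(p_subj + rng.normal(0.0, eye_sd), 0.0, 1.0))
            for rep in range(1, repeats + 1):
                img_seed = int(rng.integers(0, 2**31 - 1))
                img_params = replace(params, pigment=p_eye, seed=img_seed)
                fundus = generate_image(img_params)
                image_id = f"{pid}_{eye}_{rep}"
                fundus.image.image_id = image_id
                fundus.image.participant_id = pid
                fundus.image.eye = eye  # type: ignore[assignment]
                fundus.image.repeat_index = rep
                rec = CohortRecord(fundus, image_id, pid, eye, rep)
                records.append(rec)
                truth_rows.append(
                    {
                        "image_id": image_id,
                        "participant_id": pid,
                        "eye": eye,
                        "repeat_index": rep,
                        "pigment": p_eye,
                        "true_L": fundus.true_lab.L,
                        "true_a": fundus.true_lab.a,
                        "true_b": fundus.true_lab.b,
                    }
                )
                if out_dir is not None:
                    img_name = f"{image_id}.png"
                    ves_name = f"{image_id}_vessel.png"
                    disc_name = f"{image_id}_disc.png"
                    write_image(fundus.image, os.path.join(out_dir, img_name))
                    write_mask(fundus.vessel, os.path.join(out_dir, ves_name))
                    write_mask(fundus.disc, os.path.join(out_dir, disc_name))
                    manifest_rows.append(
                        {
                            "image_path": img_name,
                            "participant_id": pid,
                            "eye": eye,
                            "repeat_index": rep,
                            "vessel_mask_path": ves_name,
                            "disc_mask_path": disc_name,
                        }
                    )

    truth = pd.DataFrame(truth_rows)
    manifest = None
    if out_dir is not None:
        manifest = pd.DataFrame(manifest_rows)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return SyntheticCohort(records=records, truth=truth, manifest=manifest)
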