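"""On-disk contracts: images, masks, manifests, score tables, scoring models.

Images are 8-bit sRGB PNG/JPEG; masks are 8-bit PNG where any nonzero pixel
is foreground (tolerates antialiased exports); the manifest is a CSV linking
image files to participant/eye/repeat identity; the fitted scoring model is
a versioned JSON file so scales can be transferred across cohorts.

Coordinates are row-major with the origin at the top-left. Masks must match
their image shape exactly — there is no implicit resizing.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import AlignmentError, FormatError, ModelSchemaError, ModelVersionError
from .rps_model import RPSModel

MODEL_FORMAT_VERSION = 1

MANIFEST_REQUIRED_COLUMNS = ("image_path", "participant_id", "eye", "repeat_index")
MANIFEST_OPTIONAL_COLUMNS = ("vessel_mask_path", "disc_mask_path")

SCORE_COLUMNS = (
    "image_id",
    "participant_id",
    "eye",
    "repeat_index",
    "gradable",
    "reasons",
    "n_background",
    "dilation_iterations",
    "median_R",
    "median_G",
    "median_B",
    "L",
    "a",
    "b",
    "rps",
)

MIN_IMAGE_SIZE = 64


@dataclass
class FundusImage:
    """An sRGB fundus raster plus the identity metadata scoring needs.

    ``pixels`` is normally uint8; float arrays in [0, 255] are also accepted
    so that continuous-valued synthetic renders can flow through the same
    pipeline without quantisation.
    """

    pixels: np.ndarray
    image_id: str
    participant_id: str = ""
    eye: Literal["right", "left"] = "right"
    repeat_index: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < MIN_IMAGE_SIZE or px.shape[1] < MIN_IMAGE_SIZE:
            raise FormatError(
                f"degenerate raster {px.shape[0]}x{px.shape[1]}: "
                f"both sides must be >= {MIN_IMAGE_SIZE}"
            )
        if px.dtype != np.uint8:
            if float(px.min()) < 0 or float(px.max()) > 255:
                raise FormatError("pixel values must lie in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


MaskKind = Literal["vessel", "disc", "border", "combined", "retinal_background"]
MaskSource = Literal["ingested", "baseline_segmenter", "derived"]


@dataclass
class BinaryMask:
    """A strictly binary raster aligned with its parent image."""

    values: np.ndarray
    kind: MaskKind
    source: MaskSource = "derived"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {vals.shape}")
        self.values = vals.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def read_image(
    path: str | os.PathLike,
    *,
    image_id: str | None = None,
    participant_id: str = "",
    eye: str = "right",
    repeat_index: int = 1,
) -> FundusImage:
    """Read a 3-channel PNG/JPEG into a :class:`FundusImage`.

    Identity metadata comes from the caller (i.e. the manifest row), never
    from the filename. Grayscale or alpha-bearing inputs are rejected with
    a :class:`FormatError` naming the channel count.
    """
    try:
        with Image.open(path) as im:
            im.load()
            nchan = len(im.getbands())
            if im.mode != "RGB":
                raise FormatError(
                    f"{path}: expected a 3-channel RGB image, got mode "
                    f"{im.mode!r} ({nchan} channel(s))"
                )
            pixels = np.asarray(im, dtype=np.uint8)
    except (OSError, UnidentifiedImageError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise IOError(f"{path}: unreadable image file ({exc})") from exc
    return FundusImage(
        pixels=pixels,
        image_id=image_id if image_id is not None else os.fspath(path),
        participant_id=participant_id,
        eye=eye,  # type: ignore[arg-type]
        repeat_index=repeat_index,
    )


def read_mask(
    path: str | os.PathLike,
    expected_shape: tuple[int, int],
    kind: MaskKind,
    source: MaskSource = "ingested",
) -> BinaryMask:
    """Read a binary mask PNG; any nonzero pixel is foreground."""
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"{path}: unreadable mask file ({exc})") from exc
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    if arr.shape != tuple(expected_shape):
        raise AlignmentError(
            f"{path}: mask shape {arr.shape} does not match image shape "
            f"{tuple(expected_shape)}"
        )
    return BinaryMask(values=arr > 0, kind=kind, source=source)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit PNG with 0/255 semantics."""
    Image.fromarray(np.where(mask.values, 255, 0).astype(np.uint8)).save(path)


def write_image(image: FundusImage, path: str | os.PathLike) -> None:
    px = image.pixels
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="RGB").save(path)


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate the cohort manifest CSV.

    Order-preserving and deterministic; (participant_id, eye, repeat_index)
    must be unique and every referenced path must exist.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if df.empty:
        return df
    bad_eye = set(df["eye"].unique()) - {"right", "left"}
    if bad_eye:
        raise FormatError(f"{path}: invalid eye values {sorted(bad_eye)}")
    key = df[["participant_id", "eye", "repeat_index"]].apply(tuple, axis=1)
    dups = key[key.duplicated()]
    if len(dups):
        raise FormatError(
            f"{path}: duplicate (participant_id, eye, repeat_index) rows: "
            f"{sorted(set(dups))[:5]}"
        )
    base = os.path.dirname(os.fspath(path))
    path_cols = ["image_path"] + [
        c for c in MANIFEST_OPTIONAL_COLUMNS if c in df.columns
    ]
    for col in path_cols:
        for p in df[col].dropna():
            full = p if os.path.isabs(p) else os.path.join(base, p)
            if not os.path.exists(full):
                raise FormatError(f"{path}: referenced file does not exist: {p}")
    return df


def manifest_path(manifest_file: str | os.PathLike, relative: str) -> str:
    """Resolve a manifest-relative path against the manifest's directory."""
    if os.path.isabs(relative):
        return relative
    return os.path.join(os.path.dirname(os.fspath(manifest_file)), relative)


def write_scores(records: list[dict], path: str | os.PathLike) -> None:
    """Write per-image score records to a header-stable CSV.

    Non-finite score cells (ungradable images) are written empty; the
    ``gradable`` flag carries the exclusion. Round-trips losslessly through
    :func:`read_scores` for all finite values (floats serialised via repr).
    """
    df = pd.DataFrame(records, columns=list(SCORE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "reasons": str},
        float_precision="round_trip",
    )
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: scores file missing columns {missing}")
    df["reasons"] = df["reasons"].fillna("")
    return df


def save_model(model: RPSModel, path: str | os.PathLike) -> None:
    """Persist a fitted scale as versioned JSON.

    Floats are serialised with full repr precision, so a reloaded model
    reproduces projections bit-identically.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "mean": [float(x) for x in model.mean],
        "eigenvectors": [[float(x) for x in row] for row in model.eigenvectors],
        "eigenvalues": [float(x) for x in model.eigenvalues],
        "proportional_eigenvalues": [
            float(x) for x in model.proportional_eigenvalues
        ],
        "orientation": int(model.orientation),
        "n_fit": int(model.n_fit),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path: str | os.PathLike) -> RPSModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: unsupported model format_version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    required = ("mean", "eigenvectors", "eigenvalues", "orientation", "n_fit")
    missing = [k for k in required if k not in payload]
    if missing:
        raise ModelSchemaError(f"{path}: model file missing fields {missing}")
    eigenvalues = np.asarray(payload["eigenvalues"], dtype=float)
    total = eigenvalues.sum()
    prop = payload.get(
        "proportional_eigenvalues",
        (eigenvalues / total).tolist() if total > 0 else [math.nan, math.nan],
    )
    model = RPSModel(
        mean=np.asarray(payload["mean"], dtype=float),
        eigenvectors=np.asarray(payload["eigenvectors"], dtype=float),
        eigenvalues=eigenvalues,
        proportional_eigenvalues=np.asarray(prop, dtype=float),
        orientation=int(payload["orientation"]),
        n_fit=int(payload["n_fit"]),
    )
    return model


def record_to_row(record) -> dict:
    """Flatten a pipeline ScoreRecord into a scores-CSV row dict."""
    d = dataclasses.asdict(record)
    row = {
        "image_id": d["image_id"],
        "participant_id": d["participant_id"],
        "eye": d["eye"],
        "repeat_index": d["repeat_index"],
        "gradable": bool(d["gradable"]),
        "reasons": ";".join(d["reasons"]),
        "n_background": d["n_background"],
        "dilation_iterations": d["dilation_iterations"],
    }
    for key, src in (
        ("median_R", 0), ("median_G", 1), ("median_B", 2),
    ):
        med = d["median_rgb"]
        row[key] = med[src] if med is not None else math.nan
    lab = d["lab"]
    row["L"] = lab[0] if lab is not None else math.nan
    row["a"] = lab[1] if lab is not None else math.nan
    row["b"] = lab[2] if lab is not None else math.nan
    rps = d.get("rps")
    row["rps"] = rps if rps is not None else math.nan
    return row
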