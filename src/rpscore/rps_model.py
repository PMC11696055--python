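"""The pigment scale: a two-component PCA over cohort chromaticity.

A cohort's (a*, b*) background chromaticities are mean-centred and
eigendecomposed (unbiased covariance, divisor n-1); each eye's score is the
signed projection of its chromaticity onto the eigenvector with the largest
eigenvalue. The eigenvector sign is fixed so that scores correlate
positively with a* — redder/browner backgrounds score higher, matching the
convention that a greater score means a more pigmented retina; when the
projection is uncorrelated with a* the rule falls back to positive-b*
correlation. The fitted scale (mean, eigenvectors, orientation) transfers
unchanged to new cohorts, producing scores on a unified scale without
refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateModelError, FittingError, StandardisationError

_ORIENT_TOL = 1e-12


@dataclass
class RPSModel:
    """A fitted 2-D PCA scale, persistable and transferable across cohorts."""

    mean: np.ndarray                      # (2,) in (a, b) space
    eigenvectors: np.ndarray              # rows = components, descending eigenvalue
    eigenvalues: np.ndarray               # (2,) non-negative, descending
    proportional_eigenvalues: np.ndarray  # sums to 1
    orientation: int                      # +1 or -1
    n_fit: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.proportional_eigenvalues = np.asarray(
            self.proportional_eigenvalues, dtype=float
        )

    @property
    def first_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[0]


def _as_points(points: Iterable) -> np.ndarray:
    rows = []
    for p in points:
        if hasattr(p, "as_array"):  # ChromaPoint
            rows.append(tuple(p.as_array()))
        else:
            rows.append(tuple(p))
    return np.asarray(rows, dtype=float)


def _pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, eigenvectors (rows, descending) and eigenvalues of a point cloud."""
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order].T
    return mean, eigenvectors, eigenvalues


def _orient(X: np.ndarray, mean: np.ndarray, axis: np.ndarray) -> int:
    """Sign such that projections correlate positively with a* (fallback b*)."""
    proj = (X - mean) @ axis
    if proj.std() == 0:
        return 1
    for coord in range(X.shape[1]):
        col = X[:, coord]
        if col.std() == 0:
            continue
        r = np.corrcoef(proj, col)[0, 1]
        if abs(r) >= _ORIENT_TOL:
            return 1 if r >= 0 else -1
    return 1


def fit(points: Iterable) -> RPSModel:
    """Fit the two-component PCA scale to cohort chromaticity points.

    Collinear clouds are legal (second eigenvalue 0); a zero-variance cloud
    raises :class:`DegenerateModelError`, and fewer than 3 points raises
    :class:`FittingError`.
    """
    X = _as_points(points)
    if X.ndim != 2 or X.shape[0] < 3:
        raise FittingError(
            f"need at least 3 chromaticity points to fit, got {0 if X.ndim != 2 else X.shape[0]}"
        )
    if not np.isfinite(X).all():
        raise FittingError("non-finite chromaticity points in fit input")
    mean, eigenvectors, eigenvalues = _pca(X)
    total = eigenvalues.sum()
    if total <= 0:
        raise DegenerateModelError(
            "zero-variance chromaticity cloud: no principal axis exists"
        )
    orientation = _orient(X, mean, eigenvectors[0])
    return RPSModel(
        mean=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        proportional_eigenvalues=eigenvalues / total,
        orientation=orientation,
        n_fit=X.shape[0],
    )


def project(model: RPSModel, point) -> float:
    """Score one chromaticity point: orientation * <point - mean, v1>."""
    p = point.as_array() if hasattr(point, "as_array") else np.asarray(point, float)
    if not np.isfinite(p).all():
        raise ValueError(f"non-finite chromaticity point {p}")
    return float(model.orientation * np.dot(p - model.mean, model.first_eigenvector))


def project_many(model: RPSModel, points: Iterable) -> np.ndarray:
    X = _as_points(points)
    if not np.isfinite(X).all():
        raise ValueError("non-finite chromaticity points")
    return model.orientation * ((X - model.mean) @ model.first_eigenvector)


def apply_transfer(model: RPSModel, points: Iterable) -> np.ndarray:
    """Score a new cohort on a previously fitted scale.

    Uses the reference cohort's mean, eigenvector and orientation unchanged —
    no refit, no recentring — so scores are directly comparable across
    cohorts.
    """
    return project_many(model, points)


def mean_rps_per_participant(scores: pd.DataFrame) -> pd.DataFrame:
    """Average score over a participant's available (gradable) eyes.

    Expects columns ``participant_id``, ``eye`` and ``rps``. Rows with
    non-finite scores are dropped; participants with no gradable eye are
    excluded from the output.
    """
    valid = scores[np.isfinite(scores["rps"].to_numpy(dtype=float))]
    per_eye = (
        valid.groupby(["participant_id", "eye"], sort=False)["rps"]
        .mean()
        .reset_index()
    )
    out = (
        per_eye.groupby("participant_id", sort=False)["rps"]
        .agg(rps_mean="mean", n_eyes="size")
        .reset_index()
    )
    return out


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardise to mean 0, SD 1 (sample SD, divisor n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StandardisationError("z-scoring needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StandardisationError("z-scoring undefined for zero spread")
    return (x - x.mean()) / sd
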