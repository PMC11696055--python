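"""Reliability of the pigment score: one-way ICC and paired summaries.

Repeatability (two captures of the same eye) and inter-eye agreement are
quantified with the one-way single-rater intraclass correlation ICC(1,1)
from one-way random-effects ANOVA:

    ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

with exact F-distribution confidence bounds. Also provided: right-minus-left
paired difference summaries, and a harness that scores the same cohort with
the standard (a*, b*)-only scale and with a 3-component (L*, a*, b*) variant,
so the chromaticity-only design can be stress-tested under illumination
jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import rps_model
from .errors import DegenerateStatisticsError


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f: float
    p: float
    df1: int
    df2: int
    n_subjects: int
    k: int


def as_ratings_table(values, min_subjects: int = 3) -> np.ndarray:
    """Validate an n-subjects x k-measurements ratings table.

    Subjects with any missing measurement are dropped listwise.
    """
    table = np.asarray(values, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError(
            f"ratings table must be 2-D with >= 2 measurement columns, got {table.shape}"
        )
    complete = np.isfinite(table).all(axis=1)
    table = table[complete]
    if table.shape[0] < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} complete subjects, got {table.shape[0]}"
        )
    return table


def icc_oneway(values, conf: float = 0.95) -> ICCResult:
    """ICC(1,1) with exact F-based confidence bounds.

    The p-value is the upper-tail probability of the one-way ANOVA F
    statistic (MSB/MSW) under the no-subject-effect null.
    """
    table = as_ratings_table(values)
    n, k = table.shape
    subject_means = table.mean(axis=1)
    grand = table.mean()
    ssb = k * np.sum((subject_means - grand) ** 2)
    ssw = np.sum((table - subject_means[:, None]) ** 2)
    df1 = n - 1
    df2 = n * (k - 1)
    msb = ssb / df1
    msw = ssw / df2
    if msb == 0 and msw == 0:
        raise DegenerateStatisticsError(
            "zero within- and between-subject variance: ICC undefined"
        )
    alpha = 1.0 - conf
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, np.inf, 0.0, df1, df2, n, k)
    f = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_low = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_up = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_up - 1) / (f_up + k - 1)
    p = float(stats.f.sf(f, df1, df2))
    return ICCResult(float(icc), float(ci_low), float(ci_high), float(f), p,
                     df1, df2, n, k)


def paired_stats(right, left) -> tuple[float, float]:
    """Mean and sample SD of the right-minus-left score difference."""
    r = np.asarray(right, dtype=float)
    l = np.asarray(left, dtype=float)
    if r.shape != l.shape:
        raise ValueError("right and left score vectors must be paired")
    keep = np.isfinite(r) & np.isfinite(l)
    d = r[keep] - l[keep]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    return float(d.mean()), float(d.std(ddof=1))


def eye_pair_table(scores: pd.DataFrame, value_col: str = "rps") -> np.ndarray:
    """Build an n x 2 (right, left) ratings table from a per-image score frame.

    Multiple repeats per eye are averaged first; participants lacking either
    eye are dropped.
    """
    valid = scores[np.isfinite(scores[value_col].to_numpy(dtype=float))]
    per_eye = (
        valid.groupby(["participant_id", "eye"], sort=False)[value_col]
        .mean()
        .unstack("eye")
    )
    if not {"right", "left"} <= set(per_eye.columns):
        raise ValueError("need both right and left eyes to pair")
    return per_eye[["right", "left"]].dropna().to_numpy()


def repeat_pair_table(scores: pd.DataFrame, value_col: str = "rps") -> np.ndarray:
    """Build an n x k ratings table of repeat captures of the same eye."""
    valid = scores[np.isfinite(scores[value_col].to_numpy(dtype=float))]
    wide = (
        valid.groupby(["participant_id", "eye", "repeat_index"], sort=False)[value_col]
        .mean()
        .unstack("repeat_index")
    )
    return wide.dropna().to_numpy()


def _lab_variant_scores(lab: np.ndarray) -> np.ndarray:
    """First-PC projection of a 3-component PCA on (L, a, b).

    The comparison variant: identical construction to the standard scale but
    keeping lightness, so illumination leaks into the score.
    """
    mean, vecs, vals = rps_model._pca(lab)
    if vals.sum() <= 0:
        raise DegenerateStatisticsError("zero-variance (L,a,b) cloud")
    # orient on a* (column 1 of the Lab triple), falling back through columns
    axis = vecs[0]
    proj = (lab - mean) @ axis
    sign = 1
    for coord in (1, 2, 0):
        col = lab[:, coord]
        if col.std() == 0 or proj.std() == 0:
            continue
        r = np.corrcoef(proj, col)[0, 1]
        if abs(r) >= 1e-12:
            sign = 1 if r >= 0 else -1
            break
    return sign * proj


def compare_lab_vs_ab(lab_scores: pd.DataFrame) -> dict:
    """Inter-eye reliability of the (a,b)-only scale vs an (L,a,b) variant.

    ``lab_scores`` needs columns participant_id, eye and the per-image
    background L, a, b. Both scales are fitted on all rows (pooled eyes),
    then inter-eye ICC(1,1) and right-minus-left difference summaries are
    computed for each.
    """
    df = lab_scores.copy()
    if df["participant_id"].nunique() < 3:
        raise ValueError("need at least 3 participants to compare reliabilities")
    lab = df[["L", "a", "b"]].to_numpy(dtype=float)
    model_ab = rps_model.fit(lab[:, 1:])
    df["rps_ab"] = rps_model.project_many(model_ab, lab[:, 1:])
    df["rps_lab"] = _lab_variant_scores(lab)

    report: dict = {"n_images": int(len(df))}
    for tag in ("ab", "lab"):
        table = eye_pair_table(df, value_col=f"rps_{tag}")
        res = icc_oneway(table)
        mean_d, sd_d = paired_stats(table[:, 0], table[:, 1])
        report[f"icc_{tag}"] = res.icc
        report[f"icc_{tag}_ci"] = (res.ci_low, res.ci_high)
        report[f"mean_diff_{tag}"] = mean_d
        report[f"sd_diff_{tag}"] = sd_d
        report["n_pairs"] = table.shape[0]
    return report
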