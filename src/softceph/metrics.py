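"""Landmark-detection accuracy and reliability metrics.

Errors are interocular-normalized: each landmark's Euclidean error is
divided by the outer-canthal distance d_IOD of the ground truth, making
the measure invariant to face scale.  The mean normalized error (MNE) is
the average of these fractions (reported in percent); the failure rate
FR10% is the share of images whose MNE exceeds 10%.  Annotator stability
uses the intraclass correlation coefficient, ICC(2,1): two-way random
effects, absolute agreement, single measure.  Rule-based diagnoses are
scored by confusion-matrix accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

from .schema import LandmarkSchema, LandmarkSet

__all__ = ["ErrorReport", "interocular_distance", "mne", "failure_rate",
           "icc", "confusion_accuracy"]


@dataclass
class ErrorReport:
    """Per-image normalized errors.

    ``per_point_e`` holds the dimensionless fractions e_i for the points
    entering the average; ``mne_percent`` is their mean times 100.
    """

    per_point_e: np.ndarray
    mne_percent: float
    d_iod: float


def interocular_distance(gt: LandmarkSet, schema: LandmarkSchema) -> float:
    """Euclidean distance between the ground-truth outer canthi (pixels)."""
    i, j = schema.ion_pair
    if not (gt.visible[i] and gt.visible[j]):
        raise ValueError("interocular normalization unavailable: "
                         "an outer canthus is not visible")
    d = float(np.linalg.norm(gt.points[i] - gt.points[j]))
    if d == 0.0:
        raise ValueError("interocular distance is zero")
    return d


def mne(pred: LandmarkSet, gt: LandmarkSet,
        schema: LandmarkSchema) -> ErrorReport:
    """Mean normalized error of one image.

    Points invisible in either set are excluded from the average.
    """
    if len(pred) != len(gt):
        raise ValueError("point count mismatch")
    d_iod = interocular_distance(gt, schema)
    mask = pred.visible & gt.visible
    if not mask.any():
        raise ValueError("no common visible landmarks")
    errs = np.linalg.norm(pred.points[mask] - gt.points[mask], axis=1)
    e = errs / d_iod
    return ErrorReport(e, float(e.mean() * 100.0), d_iod)


def failure_rate(per_image_mne: np.ndarray | list,
                 threshold: float = 10.0) -> float:
    """Percent of images whose MNE is strictly greater than ``threshold``."""
    vals = np.asarray(per_image_mne, dtype=float)
    if vals.size == 0:
        raise ValueError("empty MNE list")
    return float(100.0 * np.count_nonzero(vals > threshold) / vals.size)


def icc(ratings: pd.DataFrame,
        targets: str = "target", raters: str = "rater",
        scores: str = "score") -> float:
    """ICC(2,1) of a long-form balanced ratings table.

    ``ratings`` has one row per (target, rater) observation.  Repeated
    measurements by a single observer are treated by passing the repeat
    index as the rater column.  Requires >= 2 raters and >= 2 targets.
    """
    df = ratings.rename(columns={targets: "target", raters: "rater",
                                 scores: "score"})
    if df["rater"].nunique() < 2:
        raise ValueError("need at least two raters/repeats")
    if df["target"].nunique() < 2:
        raise ValueError("need at least two targets")
    res = pg.intraclass_corr(data=df, targets="target", raters="rater",
                             ratings="score").set_index("Type")
    for label in ("ICC(A,1)", "ICC2"):  # pingouin renamed the row
        if label in res.index:
            return float(res.loc[label, "ICC"])
    raise RuntimeError("two-way absolute-agreement ICC row not found")


def confusion_accuracy(matrix: np.ndarray | list) -> float:
    """Percent accuracy of a square confusion matrix: 100 * trace / total."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.size == 0:
        raise ValueError("matrix must be square and nonempty")
    if (m < 0).any():
        raise ValueError("matrix entries must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise ValueError("matrix total must be positive")
    return float(100.0 * np.trace(m) / total)
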