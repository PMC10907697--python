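"""Rule-based dentofacial-deformity screening from cephalometric reports.

Three independent rules:

* **Skeletal class** from the facial angle N-Sn-Pog: ≤ 157° is Class II
  (retrusive mandible), ≥ 165° is Class III (protrusive mandible),
  angles strictly between are labeled neither.
* **Occlusal-plane tilt** from the cheilion slope k: positive slopes tilt
  up (patient-left commissure superior), negative down, |k| within a
  small tolerance is level (measured slopes are never exactly zero).
* **Mandibular asymmetry (MAD)** from the cheilion–chin distances:
  when the patient-left distance D6 exceeds the right distance D7 by more
  than a threshold the chin deviates toward the patient's right, and
  vice versa.

Predicted label lists are scored against expert labels with one
confusion matrix and accuracy per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cephalometry import CephalometricReport
from .metrics import confusion_accuracy

__all__ = ["Diagnosis", "classify_skeletal", "classify_occlusal",
           "classify_mad", "diagnose", "evaluate_against_labels",
           "SKELETAL_CLASS_II_MAX_DEG", "SKELETAL_CLASS_III_MIN_DEG"]

SKELETAL_CLASS_II_MAX_DEG = 157.0
SKELETAL_CLASS_III_MIN_DEG = 165.0


@dataclass
class Diagnosis:
    """Labels plus the thresholds that produced them (for audit)."""

    skeletal_class: str | None = None   # "II" | "III" | "neither"
    occlusal_tilt: str | None = None    # "down" | "level" | "up"
    mad_skew: str | None = None         # "left" | "right" | "none"
    thresholds: dict = field(default_factory=dict)


def classify_skeletal(facial_angle: float) -> str:
    """Class II / III / neither from the facial angle (degrees)."""
    if not 0.0 <= facial_angle <= 180.0:
        raise ValueError("facial angle must be in [0, 180] degrees")
    if facial_angle <= SKELETAL_CLASS_II_MAX_DEG:
        return "II"
    if facial_angle >= SKELETAL_CLASS_III_MIN_DEG:
        return "III"
    return "neither"


def classify_occlusal(k: float, tol: float = 0.01) -> str:
    """Occlusal-plane tilt from the cheilion slope k."""
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    if abs(k) <= tol:
        return "level"
    return "up" if k > 0 else "down"


def classify_mad(d6_mm: float, d7_mm: float, threshold_mm: float = 3.0) -> str:
    """Chin skew from the left/right cheilion–chin distances (mm).

    A longer patient-left distance (D6) means the chin sits toward the
    patient's right.
    """
    if d6_mm < 0 or d7_mm < 0:
        raise ValueError("distances must be nonnegative")
    delta = d6_mm - d7_mm
    if abs(delta) <= threshold_mm:
        return "none"
    return "right" if delta > 0 else "left"


def diagnose(reports: list[CephalometricReport],
             occlusal_tol: float = 0.01,
             mad_threshold_mm: float = 3.0) -> Diagnosis:
    """Combine one subject's per-pose reports into a diagnosis.

    Uses the first report that defines each quantity (facial angle from
    the lateral view, k and D6/D7 from a frontal view).  A quantity no
    supplied pose measures yields the normal label for its task —
    screening semantics: no evidence of deformity.  ``thresholds``
    records which tasks were actually measured.
    """
    diag = Diagnosis(thresholds={
        "skeletal_ii_max_deg": SKELETAL_CLASS_II_MAX_DEG,
        "skeletal_iii_min_deg": SKELETAL_CLASS_III_MIN_DEG,
        "occlusal_tol": occlusal_tol,
        "mad_threshold_mm": mad_threshold_mm,
    })
    for rep in reports:
        if diag.skeletal_class is None and rep.facial_angle is not None:
            diag.skeletal_class = classify_skeletal(rep.facial_angle)
        if diag.occlusal_tilt is None and rep.k is not None:
            diag.occlusal_tilt = classify_occlusal(rep.k, occlusal_tol)
        if diag.mad_skew is None and rep.d6 is not None and rep.d7 is not None:
            diag.mad_skew = classify_mad(rep.d6, rep.d7, mad_threshold_mm)
    diag.thresholds["measured"] = {
        "skeletal": diag.skeletal_class is not None,
        "occlusal": diag.occlusal_tilt is not None,
        "mad": diag.mad_skew is not None,
    }
    if diag.skeletal_class is None:
        diag.skeletal_class = "neither"
    if diag.occlusal_tilt is None:
        diag.occlusal_tilt = "level"
    if diag.mad_skew is None:
        diag.mad_skew = "none"
    return diag


def evaluate_against_labels(predictions: list[str], truth: list[str],
                            labels: list[str] | None = None):
    """Confusion matrix (as a DataFrame) and percent accuracy for one task.

    Rows are actual labels, columns predicted.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    if labels is None:
        labels = sorted(set(truth) | set(predictions))
    cm = pd.crosstab(
        pd.Categorical(truth, categories=labels),
        pd.Categorical(predictions, categories=labels),
        dropna=False,
    )
    cm.index.name, cm.columns.name = "actual", "predicted"
    return cm, confusion_accuracy(cm.to_numpy())
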