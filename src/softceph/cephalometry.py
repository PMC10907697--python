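"""Calibrated soft-tissue measurements from a 34-point landmark set.

Every photograph carries a printed 1 cm scale bar, so pixel distances
convert to millimetres.  The measurement suite comprises:

* mouth opening D1 (large) / D2 (slight): the UI–LI distance;
* esthetic-line distances D3–D5: Ls, Li and Sl to the E-line (Prn→Pog);
* chin-deviation distances D6/D7: the left/right cheilion to Gn;
* midline distances D8–D10: Pog, Gn and Gna to the facial midline, the
  least-squares line through the midline points N, Prn, Sn, Ss, Ls, Sl;
* the occlusal slope k of the cheilion–cheilion line (y-up convention:
  k > 0 means the patient-left corner of the mouth sits higher);
* five angles: facial (N-Sn-Pog), nasofacial (Prn-N-Pog), nasomental
  (N-Prn-Pog), mentolabial (Li-Sl-Pog) and the soft-tissue ANB (Ss-N-Sl).

Frontal measures (D6–D10, k) apply to frontal poses, profile measures
(D3–D5, angles) to the lateral view, and the mouth-opening distances to
the open-mouth poses; fields a pose does not define are ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import FRONTAL_POSES, LandmarkSchema, LandmarkSet, Pose

__all__ = ["Line2D", "CephalometricReport", "mm_per_pixel",
           "point_to_line_distance", "fit_facial_midline", "occlusal_slope",
           "angle_at_vertex", "measure", "MIDLINE_NAMES"]

MIDLINE_NAMES = ("N", "Prn", "Sn", "Ss", "Ls", "Sl")


@dataclass(frozen=True)
class Line2D:
    """A line given by an anchor point and a unit direction vector."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        n = float(np.hypot(*self.direction))
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")


@dataclass
class CephalometricReport:
    """Distances in mm, slope k (dimensionless), angles in degrees.

    Fields undefined for the pose are None.  ``signed`` distances follow
    the optional convention noted in :func:`measure`.
    """

    pose: Pose
    mm_per_px: float
    d1: float | None = None
    d2: float | None = None
    d3: float | None = None
    d4: float | None = None
    d5: float | None = None
    d6: float | None = None
    d7: float | None = None
    d8: float | None = None
    d9: float | None = None
    d10: float | None = None
    k: float | None = None
    facial_angle: float | None = None
    nasofacial_angle: float | None = None
    nasomental_angle: float | None = None
    mentolabial_angle: float | None = None
    anb_angle: float | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "pose"}
        d["pose"] = self.pose.value
        return d


def mm_per_pixel(landmarks: LandmarkSet, schema: LandmarkSchema) -> float:
    """Physical calibration from the scale-bar endpoints."""
    i, j = schema.scale_pair
    if not (landmarks.visible[i] and landmarks.visible[j]):
        raise ValueError("scale-bar endpoints not annotated")
    d = float(np.linalg.norm(landmarks.points[i] - landmarks.points[j]))
    if d == 0.0:
        raise ValueError("scale-bar endpoints coincide")
    return schema.scale_length_mm / d


def point_to_line_distance(p, line: Line2D, signed: bool = False) -> float:
    """Perpendicular distance of a point to a line (pixels).

    With ``signed=True`` the sign is the side of the line given by the
    left normal of ``direction``.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(line.point, dtype=float)
    d = np.asarray(line.direction, dtype=float)
    normal = np.array([-d[1], d[0]])
    s = float(np.dot(p - a, normal))
    return s if signed else abs(s)


def fit_facial_midline(landmarks: LandmarkSet,
                       schema: LandmarkSchema | None = None,
                       indices=None) -> Line2D:
    """Least-squares facial midline through N, Prn, Sn, Ss, Ls, Sl.

    The midline is near-vertical, so x is regressed on y (x = a + b·y),
    which stays well-posed for a perfectly vertical configuration.
    """
    if indices is None:
        if schema is None:
            raise ValueError("pass a schema or explicit indices")
        indices = schema.indices(*MIDLINE_NAMES)
    idx = [i for i in indices if landmarks.visible[i]]
    if len(idx) < 2:
        raise ValueError("need at least two visible midline points")
    pts = landmarks.points[idx]
    if np.allclose(pts, pts[0]):
        raise ValueError("midline points are all coincident")
    y, x = pts[:, 1], pts[:, 0]
    if np.ptp(y) == 0:  # horizontal configuration: fall back to y on x
        b, a = np.polyfit(x, y, 1)
        d = np.array([1.0, b])
        p = (float(x.mean()), float(a + b * x.mean()))
    else:
        b, a = np.polyfit(y, x, 1)  # x = a + b*y
        d = np.array([b, 1.0])
        p = (float(a + b * y.mean()), float(y.mean()))
    d = d / np.linalg.norm(d)
    return Line2D(p, (float(d[0]), float(d[1])))


def occlusal_slope(cr, cl) -> float:
    """Slope k of the cheilion line in a y-up frame.

    ``cr``/``cl`` are the right/left cheilions in image coordinates
    (y down).  k > 0 when the patient-left commissure is superior.
    """
    cr = np.asarray(cr, dtype=float)
    cl = np.asarray(cl, dtype=float)
    dx = cl[0] - cr[0]
    if dx == 0.0:
        raise ValueError("cheilion line is vertical; slope undefined")
    return float(-(cl[1] - cr[1]) / dx)  # negate: image y points down


def angle_at_vertex(a, vertex, b) -> float:
    """Interior angle (degrees, in [0, 180]) between vertex→a and vertex→b."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    u, w = a - v, b - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise ValueError("angle undefined: point coincides with vertex")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# measurement -> poses where it is defined
_POSE_GATES = {
    "d1": (Pose.LMO,),
    "d2": (Pose.SMO,),
    "d3": (Pose.RLV,), "d4": (Pose.RLV,), "d5": (Pose.RLV,),
    "d6": FRONTAL_POSES, "d7": FRONTAL_POSES,
    "d8": FRONTAL_POSES, "d9": FRONTAL_POSES, "d10": FRONTAL_POSES,
    "k": FRONTAL_POSES,
    # sagittal angles are only geometrically meaningful on the profile view
    "facial_angle": (Pose.RLV,),
    "nasofacial_angle": (Pose.RLV,),
    "nasomental_angle": (Pose.RLV,),
    "mentolabial_angle": (Pose.RLV,),
    "anb_angle": (Pose.RLV,),
}


def measure(landmarks: LandmarkSet, pose: Pose | str,
            schema: LandmarkSchema,
            mad_reference: str = "Gn") -> CephalometricReport:
    """Compute every measurement the pose defines from one landmark set.

    A missing required landmark marks the individual measurement absent
    (with a warning in the report) rather than failing the whole report.
    ``mad_reference`` selects the chin point for D6/D7 ("Gn" per the
    marker numbering, or "Gna").
    """
    pose = Pose.coerce(pose)
    scale = mm_per_pixel(landmarks, schema)
    rep = CephalometricReport(pose=pose, mm_per_px=scale)

    def pt(name: str):
        i = schema.index(name)
        return landmarks.points[i] if landmarks.visible[i] else None

    def gated(field_name: str) -> bool:
        return pose in _POSE_GATES[field_name]

    def need(field_name: str, *names: str):
        """Return points if the pose defines the field and all are visible."""
        if not gated(field_name):
            return None
        pts = [pt(n) for n in names]
        if any(p is None for p in pts):
            rep.warnings.append(f"{field_name}: missing landmark among {names}")
            return None
        return pts

    def dist_mm(p, q) -> float:
        return float(np.linalg.norm(np.asarray(p) - np.asarray(q)) * scale)

    chin = mad_reference if mad_reference in ("Gn", "Gna") else "Gn"

    if (p := need("d1", "UI", "LI")) is not None:
        rep.d1 = dist_mm(*p)
    if (p := need("d2", "UI", "LI")) is not None:
        rep.d2 = dist_mm(*p)

    eline = None
    if pose is Pose.RLV:
        pe = [pt("Prn"), pt("Pog")]
        if all(q is not None for q in pe) and not np.allclose(pe[0], pe[1]):
            d = np.asarray(pe[1]) - np.asarray(pe[0])
            d = d / np.linalg.norm(d)
            eline = Line2D(tuple(map(float, pe[0])), (float(d[0]), float(d[1])))
        else:
            rep.warnings.append("E-line: Prn/Pog unavailable")
    for field_name, name in (("d3", "Ls"), ("d4", "Li"), ("d5", "Sl")):
        if (p := need(field_name, name)) is not None:
            if eline is None:
                rep.warnings.append(f"{field_name}: no E-line")
            else:
                setattr(rep, field_name,
                        point_to_line_distance(p[0], eline) * scale)

    if (p := need("d6", "CL", chin)) is not None:
        rep.d6 = dist_mm(*p)
    if (p := need("d7", "CR", chin)) is not None:
        rep.d7 = dist_mm(*p)

    midline = None
    if pose in FRONTAL_POSES:
        try:
            midline = fit_facial_midline(landmarks, schema)
        except ValueError as exc:
            rep.warnings.append(f"midline: {exc}")
    for field_name, name in (("d8", "Pog"), ("d9", "Gn"), ("d10", "Gna")):
        if (p := need(field_name, name)) is not None:
            if midline is None:
                rep.warnings.append(f"{field_name}: no midline")
            else:
                setattr(rep, field_name,
                        point_to_line_distance(p[0], midline) * scale)

    if (p := need("k", "CR", "CL")) is not None:
        try:
            rep.k = occlusal_slope(*p)
        except ValueError as exc:
            rep.warnings.append(f"k: {exc}")

    for field_name, (na, nv, nb) in (
            ("facial_angle", ("N", "Sn", "Pog")),
            ("nasofacial_angle", ("Prn", "N", "Pog")),
            ("nasomental_angle", ("N", "Prn", "Pog")),
            ("mentolabial_angle", ("Li", "Sl", "Pog")),
            ("anb_angle", ("Ss", "N", "Sl"))):
        if (p := need(field_name, na, nv, nb)) is not None:
            try:
                setattr(rep, field_name, angle_at_vertex(*p))
            except ValueError as exc:
                rep.warnings.append(f"{field_name}: {exc}")
    return rep
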