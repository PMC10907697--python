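"""Stylized multipose face generator with analytically known geometry.

Renders non-photorealistic but structurally consistent face images
(filled ellipses and polygons on a uniform white or blue background, as
in the acquisition protocol) whose 34-point landmark template is
*constructed* from the requested clinical parameters, so ground truth is
exact by design:

* the profile chin position is placed by inverse trigonometry so the
  measured facial angle N-Sn-Pog equals ``facial_angle_deg``;
* the commissures are sheared so the occlusal slope equals ``occlusal_k``;
* the chin block is translated laterally by ``chin_offset_mm`` while the
  midline points stay on the midline;
* the upper/lower incisor edges are separated by ``mouth_opening_mm``;
* a drawn scale bar spans exactly 10 mm at the requested ``mm_per_px``.

The lateral view duplicates bilateral labels onto the visible side, the
labeling rule used for lateral photographs.  ``jitter_px`` adds Gaussian
annotation noise to a *copy* of the landmarks (``noisy_landmarks``),
emulating observer imprecision; the exact template is always kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import draw as skdraw

from .schema import LandmarkSchema, LandmarkSet, Pose, load_schema

__all__ = ["FaceParams", "SyntheticSample", "generate_face",
           "generate_dataset", "dataset_labels"]

# default incisor separation per pose (mm)
_DEFAULT_OPENING = {Pose.RFV: 0.0, Pose.SMO: 15.0, Pose.LMO: 39.0,
                    Pose.PS: 2.0, Pose.RLV: 0.0}


@dataclass(frozen=True)
class FaceParams:
    """Controllable generation parameters (units in field names)."""

    pose: Pose = Pose.RFV
    facial_angle_deg: float = 165.0
    chin_offset_mm: float = 0.0
    occlusal_k: float = 0.0
    mm_per_px: float = 0.5
    mouth_opening_mm: float | None = None
    jitter_px: float = 0.0
    image_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if not 90.0 < self.facial_angle_deg < 180.0:
            raise ValueError("facial_angle_deg must be in (90, 180)")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be nonnegative")

    @property
    def opening_mm(self) -> float:
        if self.mouth_opening_mm is not None:
            return self.mouth_opening_mm
        return _DEFAULT_OPENING[Pose.coerce(self.pose)]


@dataclass
class SyntheticSample:
    """One rendered face with exact and (optionally) jittered landmarks."""

    image: np.ndarray
    landmarks: LandmarkSet
    noisy_landmarks: LandmarkSet
    params: FaceParams


def _frontal_template(p: FaceParams) -> tuple[dict, set]:
    """Landmark positions in mm (origin at nasion, x = patient-left)."""
    c = p.chin_offset_mm
    k = p.occlusal_k
    o = p.opening_mm
    half = 26.0 if p.pose is not Pose.PS else 30.0
    mouth_y = 55.0 if p.pose is not Pose.PS else 53.0
    t = {
        "TR": (-62, 8), "TL": (62, 8),
        "GoR": (-46, 72), "GoL": (46, 72),
        "Gna": (c, 102.0 + 0.6 * o), "Gn": (c, 97.0 + 0.6 * o),
        "Pog": (c, 90.0 + 0.6 * o),
        "N": (0, 0), "Prn": (0, 30), "Sn": (0, 38),
        "AcR": (-13, 32), "AcL": (13, 32),
        "ExR": (-44, 0), "ExL": (44, 0),
        "EnR": (-16, 0), "EnL": (16, 0),
        "UPmR": (-30, -6), "UPmL": (30, -6),
        "LPmR": (-30, 6), "LPmL": (30, 6),
        "PuR": (-30, 0), "PuL": (30, 0),
        "CR": (-half, mouth_y + k * half), "CL": (half, mouth_y - k * half),
        "Ls": (0, mouth_y - 7), "Ss": (0, 44),
        "Sts": (0, mouth_y), "Sti": (0, mouth_y + 3 + 0.9 * o),
        "UI": (0, mouth_y + 2), "LI": (0, mouth_y + 2 + o),
        "Li": (0, mouth_y + 7 + 0.9 * o), "Sl": (0, mouth_y + 23 + 0.7 * o),
    }
    hidden = set()
    if p.pose is Pose.RFV:
        hidden |= {"UI", "LI"}
    if p.pose is Pose.PS:
        hidden |= {"LI"}
    return t, hidden


def _profile_template(p: FaceParams) -> tuple[dict, set]:
    """Lateral-view template; the patient faces image-right.

    Pog is placed at 55 mm from Sn on the posterior-deviating ray that
    makes the N-Sn-Pog angle exactly ``facial_angle_deg``.
    """
    n = np.array([0.0, 0.0])
    sn = np.array([14.0, 38.0])
    u = (n - sn) / np.linalg.norm(n - sn)
    th = np.deg2rad(p.facial_angle_deg)

    def rot(v, a):
        ca, sa = np.cos(a), np.sin(a)
        return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1]])

    cands = [sn + 55.0 * rot(u, s * th) for s in (+1.0, -1.0)]
    pog = min(cands, key=lambda q: q[0])  # posterior of the straight ray
    gn = pog + np.array([-3.0, 8.0])
    gna = pog + np.array([-9.0, 13.0])
    t = {
        "N": tuple(n), "Sn": tuple(sn), "Pog": tuple(pog),
        "Gn": tuple(gn), "Gna": tuple(gna),
        "Prn": (32, 28), "Ss": (16, 45),
        "Ls": (20, 50), "Sts": (17, 55), "Sti": (16, 58),
        "Li": (18, 63), "Sl": (10, 76),
    }
    # bilateral structures collapse onto the visible side
    dup = {"Ex": (-6, 0), "En": (14, 3), "UPm": (4, -4), "LPm": (4, 6),
           "Pu": (4, 1), "Ac": (24, 33), "T": (-40, 10), "Go": (-28, 68)}
    for stem, xy in dup.items():
        t[stem + "R"] = xy
        t[stem + "L"] = xy
    t["CR"] = t["CL"] = (18, 55)
    t["UI"] = t["LI"] = (16, 56)
    hidden = {"CR", "CL", "UI", "LI"}
    return t, hidden


def _mm_to_px(template: dict, p: FaceParams,
              schema: LandmarkSchema) -> np.ndarray:
    """Place the mm template on the pixel canvas, centered."""
    names = [nm for nm in schema.names if nm not in ("Scale0", "Scale1")]
    mm = np.array([template[nm] for nm in names], dtype=float)
    px = mm / p.mm_per_px
    lo, hi = px.min(axis=0), px.max(axis=0)
    center = (lo + hi) / 2.0
    shift = np.array([p.image_size / 2.0, p.image_size / 2.0]) - center
    pts = np.zeros((schema.n_points, 2))
    for i, nm in enumerate(schema.names):
        if nm in ("Scale0", "Scale1"):
            continue
        pts[i] = np.array(template[nm]) / p.mm_per_px + shift
    s0, s1 = schema.scale_pair
    bar = 10.0 / p.mm_per_px
    pts[s0] = (14.0, 18.0)
    pts[s1] = (14.0, 18.0 + bar)
    return pts


def _poly(img, pts_xy, color):
    rr, cc = skdraw.polygon(pts_xy[:, 1], pts_xy[:, 0], shape=img.shape[:2])
    img[rr, cc] = color


def _ellipse(img, cx, cy, rx, ry, color):
    rr, cc = skdraw.ellipse(cy, cx, max(ry, 1), max(rx, 1),
                            shape=img.shape[:2])
    img[rr, cc] = color


def _disk(img, cx, cy, r, color):
    rr, cc = skdraw.disk((cy, cx), max(r, 1), shape=img.shape[:2])
    img[rr, cc] = color


def _render(pts: np.ndarray, p: FaceParams, schema: LandmarkSchema,
            rng: np.random.Generator) -> np.ndarray:
    """Draw the stylized face so that image structure follows the landmarks."""
    size = p.image_size
    bg = np.array([255, 255, 255] if rng.random() < 0.5 else [205, 220, 245],
                  dtype=np.uint8)
    img = np.tile(bg, (size, size, 1)).astype(np.uint8)
    skin = np.clip(np.array([224, 180, 150]) + rng.integers(-12, 13, 3),
                   0, 255).astype(np.uint8)
    dark = np.array([60, 45, 40], dtype=np.uint8)
    lip = np.array([190, 90, 90], dtype=np.uint8)

    def P(nm):
        return pts[schema.index(nm)]

    s = 1.0 / p.mm_per_px  # px per mm
    if Pose.coerce(p.pose) is Pose.RLV:
        outline = np.array([
            P("TR") + (-6 * s, -42 * s), P("N") + (18 * s, -40 * s),
            P("N") + (6 * s, -12 * s), P("N"), P("Prn") + (-4 * s, -8 * s),
            P("Prn"), P("Sn") + (4 * s, -2 * s), P("Sn"),
            P("Ls"), P("Sts") + (2 * s, 0), P("Li"), P("Sl"),
            P("Pog"), P("Gn"), P("Gna"), P("GoR"),
            P("TR") + (0, 30 * s), P("TR") + (-8 * s, 0),
        ])
        _poly(img, outline, skin)
        _ellipse(img, *P("TR"), 5 * s, 9 * s, dark)            # ear
        eye_c = (P("ExR") + P("EnR")) / 2
        _ellipse(img, *eye_c, 10 * s, 4 * s, np.array([250, 250, 250]))
        _disk(img, *P("PuR"), 2.5 * s, dark)
        _poly(img, np.array([P("Ls"), P("Sts") + (3 * s, 0), P("Li"),
                             P("Sts") + (-3 * s, 0)]), lip)
        _disk(img, *P("Prn"), 1.5 * s, (skin * 0.82).astype(np.uint8))
    else:
        face_c = (P("N") + P("Gna")) / 2 + np.array([0, -6 * s])
        _ellipse(img, face_c[0], face_c[1], 62 * s, 66 * s, skin)
        jaw = np.array([P("GoR"), P("GoR") + (6 * s, 18 * s), P("Gna"),
                        P("GoL") + (-6 * s, 18 * s), P("GoL"),
                        P("GoL") + (-8 * s, -10 * s),
                        P("GoR") + (8 * s, -10 * s)])
        _poly(img, jaw, skin)
        chin = (skin * 0.88).astype(np.uint8)
        _ellipse(img, *((P("Pog") + P("Gn")) / 2), 14 * s, 9 * s, chin)
        for side in "RL":
            ex, en = P("Ex" + side), P("En" + side)
            ec = (ex + en) / 2
            _ellipse(img, ec[0], ec[1], abs(ex[0] - en[0]) / 2, 5.5 * s,
                     np.array([250, 250, 250]))
            _disk(img, *P("Pu" + side), 3 * s, dark)
            _disk(img, *P("T" + side), 2 * s, dark)
            _disk(img, *P("Ac" + side), 1.5 * s, (skin * 0.7).astype(np.uint8))
        nose = np.array([P("N"), P("AcR"), P("Sn"), P("AcL")])
        _poly(img, nose, (skin * 0.92).astype(np.uint8))
        _disk(img, *P("Prn"), 2 * s, (skin * 0.8).astype(np.uint8))
        # mouth: lips around the stomion line, teeth when open
        _poly(img, np.array([P("CR"), P("Ls"), P("CL"), P("Sts")]), lip)
        _poly(img, np.array([P("CR"), P("Sti"), P("CL"), P("Li")]), lip)
        if p.opening_mm > 0.5:
            _poly(img, np.array([P("CR"), P("Sts"), P("CL"), P("Sti")]),
                  np.array([40, 20, 20], dtype=np.uint8))
            white = np.array([245, 245, 240], dtype=np.uint8)
            for top, bot in (("Sts", "UI"), ("LI", "Sti")):
                y0, y1 = P(top)[1], P(bot)[1]
                if y1 > y0:
                    _poly(img, np.array([[P("Sts")[0] - 12 * s, y0],
                                         [P("Sts")[0] + 12 * s, y0],
                                         [P("Sts")[0] + 12 * s, y1],
                                         [P("Sts")[0] - 12 * s, y1]]), white)
    # scale bar: exactly 10 mm between tick centers
    s0, s1 = (pts[i] for i in schema.scale_pair)
    rr, cc = skdraw.line(int(round(s0[1])), int(round(s0[0])),
                         int(round(s1[1])), int(round(s1[0])))
    keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
    img[rr[keep], cc[keep]] = (0, 0, 0)
    for end in (s0, s1):
        rr, cc = skdraw.line(int(round(end[1])), int(round(end[0])) - 3,
                             int(round(end[1])), int(round(end[0])) + 3)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[keep], cc[keep]] = (0, 0, 0)
    return img


def generate_face(params: FaceParams,
                  schema: LandmarkSchema | None = None) -> SyntheticSample:
    """Render one face; landmark geometry matches ``params`` exactly."""
    schema = schema or load_schema("custom34")
    pose = Pose.coerce(params.pose)
    rng = np.random.default_rng(params.seed)
    if pose is Pose.RLV:
        template, hidden = _profile_template(params)
    else:
        template, hidden = _frontal_template(params)
    pts = _mm_to_px(template, params, schema)
    visible = np.array([nm not in hidden for nm in schema.names])
    inside = (pts[visible] >= 2).all() and \
        (pts[visible] <= params.image_size - 3).all()
    if not inside:
        raise ValueError("parameters place landmarks outside the image; "
                         "increase image_size or mm_per_px")
    img = _render(pts, params, schema, rng)
    lm = LandmarkSet(pts, visible, schema.name, params.mm_per_px)
    noisy = lm.copy()
    if params.jitter_px > 0:
        noisy.points = noisy.points + rng.normal(0.0, params.jitter_px,
                                                 noisy.points.shape)
    return SyntheticSample(img, lm, noisy, params)


def _label_from_params(p: FaceParams, mad_threshold_mm: float = 3.0,
                       occlusal_tol: float = 0.01) -> dict:
    """Closed-form diagnosis labels from the drawn parameters.

    Uses the frontal template constants directly (not the measurement
    pipeline), so tests can cross-check the two routes.
    """
    from .diagnosis import (SKELETAL_CLASS_II_MAX_DEG,
                            SKELETAL_CLASS_III_MIN_DEG)
    a = p.facial_angle_deg
    skel = ("II" if a <= SKELETAL_CLASS_II_MAX_DEG
            else "III" if a >= SKELETAL_CLASS_III_MIN_DEG else "neither")
    k = p.occlusal_k
    occl = "level" if abs(k) <= occlusal_tol else ("up" if k > 0 else "down")
    half, mouth_y, chin_y = 26.0, 55.0, 97.0 + 0.6 * p.opening_mm
    c = p.chin_offset_mm
    d6 = np.hypot(half - c, chin_y - (mouth_y - k * half))
    d7 = np.hypot(half + c, chin_y - (mouth_y + k * half))
    delta = d6 - d7
    mad = ("none" if abs(delta) <= mad_threshold_mm
           else "right" if delta > 0 else "left")
    return {"skeletal_class": skel, "occlusal_tilt": occl, "mad_skew": mad}


def dataset_labels(samples: list[SyntheticSample]) -> "pd.DataFrame":
    import pandas as pd
    rows = []
    for i, s in enumerate(samples):
        row = {"index": i, "pose": Pose.coerce(s.params.pose).value}
        row.update(_label_from_params(s.params))
        rows.append(row)
    return pd.DataFrame(rows)


def generate_dataset(n: int, param_ranges: dict | None = None,
                     seed: int = 0, out_dir=None,
                     schema: LandmarkSchema | None = None
                     ) -> list[SyntheticSample]:
    """Draw ``n`` faces with parameters sampled from uniform ranges.

    ``param_ranges`` maps FaceParams field names to either a fixed value
    or a (low, high) range; ``pose`` may map to a list of poses sampled
    uniformly.  With ``out_dir`` set, writes ``face_####.png`` images, an
    ``annotations.csv`` (exact landmarks) and a ``labels.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    schema = schema or load_schema("custom34")
    ranges = dict(param_ranges or {})
    for key, val in ranges.items():
        if isinstance(val, (tuple, list)) and len(val) == 0:
            raise ValueError(f"empty range for {key!r}")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        kwargs = {}
        for key, val in ranges.items():
            if key == "pose":
                opts = val if isinstance(val, (tuple, list)) else [val]
                kwargs[key] = Pose.coerce(opts[rng.integers(len(opts))])
            elif isinstance(val, (tuple, list)):
                kwargs[key] = float(rng.uniform(val[0], val[1]))
            else:
                kwargs[key] = val
        kwargs["seed"] = int(rng.integers(0, 2 ** 31 - 1))
        samples.append(generate_face(FaceParams(**kwargs), schema))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .annotations_io import AnnotationRecord, write_annotations
        records = []
        for i, s in enumerate(samples):
            name = f"face_{i:04d}.png"
            Image.fromarray(s.image).save(out / name)
            records.append(AnnotationRecord(
                image=name, pose=Pose.coerce(s.params.pose),
                schema_name=schema.name, points=s.landmarks.points,
                visible=s.landmarks.visible))
        write_annotations(records, out / "annotations.csv")
        dataset_labels(samples).to_csv(out / "labels.csv", index=False)
    return samples
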