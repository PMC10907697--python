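"""Landmark taxonomy: the 34-point soft-tissue schema, poses, mirror pairs.

The schema describes *what* the coordinates mean: landmark names in clinical
order, which index pairs swap under a horizontal flip, which landmarks are
annotated in which photographic pose, which pair normalizes errors
(the exocanthions) and which pair spans the printed 1 cm scale bar.

All indices are 0-based in code; the bundled YAML and any user-facing
numbering are 1-based (clinical convention).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Pose",
    "LandmarkSchema",
    "LandmarkSet",
    "load_schema",
    "mirror_permutation",
]


class Pose(str, enum.Enum):
    """The five photographic poses of the acquisition protocol."""

    RFV = "RFV"  # resting frontal view
    SMO = "SMO"  # slight mouth opening
    LMO = "LMO"  # large mouth opening
    PS = "PS"    # postural smile
    RLV = "RLV"  # resting lateral view

    @classmethod
    def coerce(cls, value: "Pose | str") -> "Pose":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(f"unknown pose {value!r}; expected one of "
                             f"{[p.value for p in cls]}") from None


FRONTAL_POSES = (Pose.RFV, Pose.SMO, Pose.LMO, Pose.PS)


@dataclass(frozen=True)
class LandmarkSchema:
    """Immutable description of a landmark layout.

    Attributes
    ----------
    name : str
        Schema identifier (``"custom34"`` for the 34-point layout).
    names : tuple of str
        Landmark abbreviations in index order.
    mirror_pairs : tuple of (int, int)
        0-based index pairs swapped by a horizontal flip.
    pose_visibility : dict
        ``Pose -> frozenset`` of 0-based indices annotated in that pose.
    ion_pair : (int, int)
        Outer-canthus pair used for interocular normalization.
    scale_pair : (int, int)
        Endpoints of the physical scale bar.
    scale_length_mm : float
        Physical length of the scale bar (10 mm).
    """

    name: str
    names: tuple[str, ...]
    mirror_pairs: tuple[tuple[int, int], ...]
    pose_visibility: dict[Pose, frozenset[int]]
    ion_pair: tuple[int, int]
    scale_pair: tuple[int, int]
    scale_length_mm: float

    @property
    def n_points(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """0-based index of a landmark abbreviation."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no landmark named {name!r} in schema "
                           f"{self.name!r}") from None

    def indices(self, *names: str) -> tuple[int, ...]:
        return tuple(self.index(n) for n in names)

    def visible_in(self, pose: Pose | str) -> frozenset[int]:
        return self.pose_visibility[Pose.coerce(pose)]

    def __post_init__(self) -> None:
        n = self.n_points
        seen: set[frozenset[int]] = set()
        for i, j in self.mirror_pairs:
            if i == j:
                raise ValueError(f"mirror pair ({i}, {j}) is degenerate")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"mirror pair ({i}, {j}) out of range")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"mirror pair ({i}, {j}) listed twice")
            seen.add(key)
        for pair, label in ((self.ion_pair, "ion_pair"),
                            (self.scale_pair, "scale_pair")):
            if not all(0 <= k < n for k in pair):
                raise ValueError(f"{label} {pair} out of range")


@dataclass
class LandmarkSet:
    """Ordered 2-D pixel coordinates for one image.

    ``points`` is an (n, 2) float array of (x, y) with origin at the top-left
    corner, x rightward, y downward, 0-based.  ``visible`` marks landmarks
    that are defined/annotated; invisible rows are ignored by geometry code.
    ``mm_per_px`` carries the physical calibration when known.
    """

    points: np.ndarray
    visible: np.ndarray | None = None
    schema_name: str = "custom34"
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.visible is None:
            self.visible = np.ones(len(self.points), dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
            if self.visible.shape != (len(self.points),):
                raise ValueError("visible mask length mismatch")
        if not np.all(np.isfinite(self.points[self.visible])):
            raise ValueError("visible landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.points.copy(), self.visible.copy(),
                           self.schema_name, self.mm_per_px)

    def visible_points(self) -> np.ndarray:
        return self.points[self.visible]


_SCHEMA_CACHE: dict[str, LandmarkSchema] = {}


def load_schema(name: str = "custom34") -> LandmarkSchema:
    """Load a bundled landmark schema by identifier.

    Raises
    ------
    KeyError
        If no bundled schema has that name.
    """
    if name in _SCHEMA_CACHE:
        return _SCHEMA_CACHE[name]
    try:
        text = (resources.files("softceph.data") / f"{name}.yaml").read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown schema {name!r}") from None
    raw = yaml.safe_load(text)
    n = int(raw["n_points"])
    names = tuple(str(s) for s in raw["names"])
    if len(names) != n:
        raise ValueError(f"schema {name!r}: {len(names)} names for "
                         f"n_points={n}")
    pairs = tuple((int(i) - 1, int(j) - 1) for i, j in raw["mirror_pairs"])
    hidden = {Pose.coerce(p): {int(k) - 1 for k in idxs}
              for p, idxs in raw["pose_hidden"].items()}
    visibility = {
        pose: frozenset(set(range(n)) - hidden.get(pose, set()))
        for pose in Pose
    }
    schema = LandmarkSchema(
        name=str(raw["name"]),
        names=names,
        mirror_pairs=pairs,
        pose_visibility=visibility,
        ion_pair=tuple(int(k) - 1 for k in raw["ion_pair"]),
        scale_pair=tuple(int(k) - 1 for k in raw["scale_pair"]),
        scale_length_mm=float(raw["scale_length_mm"]),
    )
    _SCHEMA_CACHE[name] = schema
    return schema


def mirror_permutation(schema: LandmarkSchema) -> np.ndarray:
    """Index permutation applied to landmark order under a horizontal flip.

    Swaps each mirror pair and fixes midline points.  The permutation is an
    involution: applying it twice is the identity.
    """
    perm = np.arange(schema.n_points)
    for i, j in schema.mirror_pairs:
        perm[i], perm[j] = j, i
    return perm
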