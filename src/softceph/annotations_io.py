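"""Annotation file reading/writing and multi-observer consensus.

The canonical format is one CSV per dataset with columns
``image, pose, schema, observer, repeat, x1, y1, …, x34, y34`` (header
numbering is 1-based, clinical convention; coordinate *values* are
0-based original-image pixels).  Invisible landmarks are stored as empty
cells.  A JSON-lines dialect with the same fields is also supported.
Training uses the per-landmark mean of repeated annotations (consensus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import LandmarkSet, Pose, load_schema

__all__ = ["AnnotationRecord", "read_annotations", "write_annotations",
           "consensus"]


@dataclass
class AnnotationRecord:
    """One observer's annotation of one image."""

    image: str
    pose: Pose
    points: np.ndarray
    visible: np.ndarray | None = None
    schema_name: str = "custom34"
    observer: str = ""
    repeat: int = 0

    def __post_init__(self) -> None:
        self.pose = Pose.coerce(self.pose)
        self.points = np.asarray(self.points, dtype=float)
        n = load_schema(self.schema_name).n_points
        if self.points.shape != (n, 2):
            raise ValueError(
                f"record {self.image!r}: expected {n} points, "
                f"got shape {self.points.shape}")
        if self.visible is None:
            self.visible = ~np.isnan(self.points).any(axis=1)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
        if np.isnan(self.points[self.visible]).any():
            raise ValueError(f"record {self.image!r}: NaN coordinate on a "
                             "visible landmark")

    def landmark_set(self) -> LandmarkSet:
        pts = self.points.copy()
        pts[~self.visible] = 0.0
        return LandmarkSet(pts, self.visible, self.schema_name)


def _columns(n: int) -> list[str]:
    cols = ["image", "pose", "schema", "observer", "repeat"]
    for i in range(1, n + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def write_annotations(records: list[AnnotationRecord], path) -> None:
    """Write records to CSV (or ``.jsonl``), sorted for stable diffs."""
    path = Path(path)
    ordered = sorted(records, key=lambda r: (r.image, r.observer, r.repeat))
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for r in ordered:
                pts = [[None, None] if not v else [float(x), float(y)]
                       for (x, y), v in zip(r.points, r.visible)]
                fh.write(json.dumps({
                    "image": r.image, "pose": r.pose.value,
                    "schema": r.schema_name, "observer": r.observer,
                    "repeat": r.repeat, "points": pts}) + "\n")
        return
    n = load_schema(records[0].schema_name).n_points if records else 34
    rows = []
    for r in ordered:
        row = {"image": r.image, "pose": r.pose.value, "schema": r.schema_name,
               "observer": r.observer, "repeat": r.repeat}
        for i, ((x, y), v) in enumerate(zip(r.points, r.visible), start=1):
            row[f"x{i}"] = repr(float(x)) if v else ""
            row[f"y{i}"] = repr(float(y)) if v else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=_columns(n))
    df.to_csv(path, index=False)


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a CSV or JSON-lines annotation file.

    Malformed rows raise a ``ValueError`` naming the record and line.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    if path.suffix == ".jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    d = json.loads(line)
                    pts = np.array(
                        [[np.nan, np.nan] if p[0] is None else p
                         for p in d["points"]], dtype=float)
                    records.append(AnnotationRecord(
                        image=d["image"], pose=d["pose"], points=pts,
                        schema_name=d.get("schema", "custom34"),
                        observer=d.get("observer", ""),
                        repeat=int(d.get("repeat", 0))))
                except (KeyError, ValueError, json.JSONDecodeError) as exc:
                    raise ValueError(f"{path}:{lineno}: bad record: {exc}") \
                        from None
        return records
    df = pd.read_csv(path, dtype={"image": str, "observer": str},
                     float_precision="round_trip")
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        schema_name = str(row.get("schema", "custom34"))
        n = load_schema(schema_name).n_points
        try:
            pts = np.array([[row.get(f"x{i}", np.nan), row.get(f"y{i}", np.nan)]
                            for i in range(1, n + 1)], dtype=float)
            records.append(AnnotationRecord(
                image=str(row["image"]), pose=row["pose"], points=pts,
                schema_name=schema_name,
                observer="" if pd.isna(row.get("observer")) else str(row["observer"]),
                repeat=int(row.get("repeat", 0))))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad record: {exc}") from None
    return records


def consensus(records: list[AnnotationRecord]) -> AnnotationRecord:
    """Per-landmark mean across observers/repeats of one image.

    A landmark is visible in the consensus if it is visible in every
    contributing record.
    """
    if not records:
        raise ValueError("no records to average")
    schemas = {r.schema_name for r in records}
    if len(schemas) > 1:
        raise ValueError(f"mixed schemas: {sorted(schemas)}")
    images = {r.image for r in records}
    if len(images) > 1:
        raise ValueError(f"records span multiple images: {sorted(images)}")
    pts = np.mean([r.points for r in records], axis=0)
    vis = np.logical_and.reduce([r.visible for r in records])
    pts[~vis] = np.nan
    return AnnotationRecord(
        image=records[0].image, pose=records[0].pose, points=pts,
        visible=vis, schema_name=records[0].schema_name,
        observer="consensus", repeat=0)
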