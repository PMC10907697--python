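"""Shared fixtures: schemas, synthetic samples, and the scaled-down
landmark-subset pipeline used by the learning checks."""

from __future__ import annotations

import numpy as np
import pytest

from softceph.preprocess import bbox_from_landmarks, crop_resize, expand_box, \
    map_coords
from softceph.schema import LandmarkSchema, LandmarkSet, Pose, load_schema
from softceph.synthetic_faces import FaceParams, generate_dataset, generate_face

# 8 high-contrast landmarks used for scaled-down training checks
TINY_NAMES = ("ExR", "ExL", "PuR", "PuL", "Prn", "CR", "CL", "Gna")

TINY_SCHEMA = LandmarkSchema(
    name="tiny8", names=TINY_NAMES,
    mirror_pairs=((0, 1), (2, 3), (5, 6)),
    pose_visibility={p: frozenset(range(8)) for p in Pose},
    ion_pair=(0, 1), scale_pair=(0, 1), scale_length_mm=10.0)

# generator ranges for frontal training faces
FRONTAL_RANGES = dict(pose=Pose.RFV, chin_offset_mm=(-8.0, 8.0),
                      occlusal_k=(-0.08, 0.08), mm_per_px=(0.35, 0.6))


@pytest.fixture(scope="session")
def schema():
    return load_schema("custom34")


@pytest.fixture(scope="session")
def frontal_sample():
    return generate_face(FaceParams(pose=Pose.RFV, chin_offset_mm=4.0,
                                    occlusal_k=0.04, seed=11))


@pytest.fixture(scope="session")
def lateral_sample():
    return generate_face(FaceParams(pose=Pose.RLV, facial_angle_deg=162.0,
                                    seed=12))


def subset_crop(samples, size=128, names=TINY_NAMES):
    """Crop faces to network inputs with subsetted landmark ground truth."""
    full = load_schema("custom34")
    idx = list(full.indices(*names))
    out = []
    for s in samples:
        box = expand_box(bbox_from_landmarks(s.landmarks))
        crop, tf = crop_resize(s.image, box, size)
        pts = map_coords(tf, s.landmarks.points[idx], "to_network")
        out.append((crop.astype(np.uint8),
                    LandmarkSet(pts, schema_name="tiny8")))
    return out


@pytest.fixture(scope="session")
def tiny_train_set():
    """300 frontal faces prepared for the scaled-down learning check."""
    return subset_crop(generate_dataset(300, FRONTAL_RANGES, seed=101))


@pytest.fixture(scope="session")
def tiny_test_set():
    """48 held-out frontal faces from a disjoint seed."""
    return subset_crop(generate_dataset(48, FRONTAL_RANGES, seed=202))
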