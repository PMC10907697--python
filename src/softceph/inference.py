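"""End-to-end landmark detection on original-resolution images.

Composes the crop pipeline, the network and the heatmap decoder:
expand a face box to the square crop, resize to the network input,
predict heatmaps, read the peaks and map the coordinates back to the
original image.  The face box comes from annotations (training/eval) or
from any external detector callable returning a ``FaceBox``.
"""

from __future__ import annotations

import numpy as np

from .heatmap_codec import decode
from .model import BHRNet, predict
from .preprocess import FaceBox, bbox_from_landmarks, crop_resize, expand_box, \
    map_coords
from .schema import LandmarkSet

__all__ = ["detect_landmarks"]


def detect_landmarks(model: BHRNet, image: np.ndarray,
                     face_box: FaceBox | None = None,
                     landmarks_for_box: LandmarkSet | None = None,
                     k_top: float = 0.3, k_bottom: float = 0.1
                     ) -> tuple[LandmarkSet, np.ndarray]:
    """Detect landmarks on one image; returns (landmarks, confidences).

    Exactly one of ``face_box`` (from a detector) or ``landmarks_for_box``
    (annotation-derived, as for training images) must locate the face.
    """
    if face_box is None:
        if landmarks_for_box is None:
            raise ValueError("need a face_box or landmarks to derive one")
        face_box = bbox_from_landmarks(landmarks_for_box)
    square = expand_box(face_box, k_top=k_top, k_bottom=k_bottom)
    crop, transform = crop_resize(image, square, model.config.input_size)
    out = predict(model, crop)
    lm_net, conf = decode(out.stack(0))
    pts = map_coords(transform, lm_net.points, "to_original")
    return LandmarkSet(pts, lm_net.visible), conf
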