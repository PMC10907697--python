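"""Face-box expansion, square cropping and coordinate mapping.

The network consumes fixed-size square inputs.  A face box (from annotations
or any external detector) is expanded asymmetrically — 0.3·h above to keep
the forehead, 0.1·h below to keep the chin — then padded symmetrically on the
short axis to a 1:1 square, cropped with zero fill where the square leaves
the source image, and resized to the network resolution.  The resulting
affine ``CropTransform`` maps coordinates losslessly in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

from .schema import LandmarkSet

__all__ = [
    "FaceBox",
    "CropTransform",
    "bbox_from_landmarks",
    "expand_box",
    "crop_resize",
    "map_coords",
]


class DegenerateBoxError(ValueError):
    """Landmarks collapse onto a line or point along an axis."""


class EmptyCropError(ValueError):
    """The requested crop square does not intersect the image."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned pixel box, origin top-left, x rightward, y downward."""

    left: float
    top: float
    right: float
    bottom: float

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise ValueError(f"invalid box {self}")

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top


@dataclass(frozen=True)
class CropTransform:
    """Invertible affine map between original and network-input pixels.

    network = (original − offset) · scale;  original = network / scale + offset.
    """

    square_box: FaceBox
    out_size: int

    @property
    def scale(self) -> float:
        return self.out_size / self.square_box.width

    @property
    def offset(self) -> tuple[float, float]:
        return (self.square_box.left, self.square_box.top)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["square_box"] = asdict(self.square_box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CropTransform":
        return cls(FaceBox(**d["square_box"]), int(d["out_size"]))


def bbox_from_landmarks(landmarks: LandmarkSet) -> FaceBox:
    """Tight bounding box of the visible landmarks.

    Raises
    ------
    DegenerateBoxError
        Fewer than two visible points, or zero extent along an axis.
    """
    pts = landmarks.visible_points()
    if len(pts) < 2:
        raise DegenerateBoxError("need at least two visible landmarks")
    (x1, y1), (x2, y2) = pts.min(axis=0), pts.max(axis=0)
    if x1 == x2 or y1 == y2:
        raise DegenerateBoxError("landmarks are collinear along an axis")
    return FaceBox(float(x1), float(y1), float(x2), float(y2))


def expand_box(box: FaceBox,
               image_size: tuple[int, int] | None = None,
               k_top: float = 0.3,
               k_bottom: float = 0.1) -> FaceBox:
    """Expand a face box to a square crop region.

    The top margin grows by ``k_top * h`` and the bottom by ``k_bottom * h``
    (h = face height), then the short axis is padded symmetrically until the
    region is square.  Coordinates may extend beyond the image (``image_size``
    is accepted for interface symmetry; out-of-image area is zero-filled
    later by :func:`crop_resize`).
    """
    h, w = box.height, box.width
    top = box.top - k_top * h
    bottom = box.bottom + k_bottom * h
    left, right = box.left, box.right
    h_exp = bottom - top
    if h_exp > w:
        pad = (h_exp - w) / 2.0
        left -= pad
        right += pad
    elif h_exp < w:
        pad = (w - h_exp) / 2.0
        top -= pad
        bottom += pad
    return FaceBox(left, top, right, bottom)


def crop_resize(image: np.ndarray,
                square_box: FaceBox,
                out_size: int = 256) -> tuple[np.ndarray, CropTransform]:
    """Crop ``square_box`` (zero-filling outside the image) and resize.

    Parameters
    ----------
    image : (H, W) or (H, W, C) array
        Source raster; uint8 or float.
    square_box : FaceBox
        Square region (1:1 within one pixel) in source coordinates.
    out_size : int
        Edge length of the network input, default 256.

    Returns
    -------
    (out_size, out_size[, C]) float32 array and the CropTransform.
    """
    if out_size < 32:
        raise ValueError("out_size must be >= 32")
    if abs(square_box.width - square_box.height) > 1.0:
        raise ValueError("square_box must be square to within 1 px")
    H, W = image.shape[:2]
    li, ti = int(np.floor(square_box.left)), int(np.floor(square_box.top))
    side = int(round(square_box.width))
    if li >= W or ti >= H or li + side <= 0 or ti + side <= 0:
        raise EmptyCropError("crop square lies entirely outside the image")
    shape = (side, side) + image.shape[2:]
    canvas = np.zeros(shape, dtype=np.float32)
    sy0, sy1 = max(ti, 0), min(ti + side, H)
    sx0, sx1 = max(li, 0), min(li + side, W)
    canvas[sy0 - ti:sy1 - ti, sx0 - li:sx1 - li] = image[sy0:sy1, sx0:sx1]
    out = _sk_resize(canvas, (out_size, out_size), order=1,
                     anti_aliasing=False, preserve_range=True).astype(np.float32)
    # The transform uses the exact (float) box so coordinate round trips are
    # lossless regardless of the integer pixel grid used for sampling.
    return out, CropTransform(square_box, out_size)


def map_coords(transform: CropTransform,
               points: np.ndarray,
               direction: str = "to_network") -> np.ndarray:
    """Map (n, 2) coordinates through the crop transform.

    ``direction`` is ``"to_network"`` (original → network input) or
    ``"to_original"``.  The two directions compose to the identity.
    """
    pts = np.asarray(points, dtype=float)
    ox, oy = transform.offset
    s = transform.scale
    if direction == "to_network":
        return (pts - [ox, oy]) * s
    if direction == "to_original":
        return pts / s + [ox, oy]
    raise ValueError("direction must be 'to_network' or 'to_original'")
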