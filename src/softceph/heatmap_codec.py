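"""Gaussian heatmap encoding and argmax decoding.

Each landmark becomes one response map: value 1 at the landmark cell,
falling off as exp(−((x−x0)² + (y−y0)²) / 2σ²) with distance in heatmap
cells.  The coordinate convention is the single one used throughout the
package: heatmap cell (u, v) covers input pixel (u·stride, v·stride);
encoding quantizes by rounding, so an encode→decode round trip moves a
landmark by at most stride/2 per axis for positions up to
``input_size − stride/2`` (the final half-stride sliver at the far
border clamps to the last cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import LandmarkSet

__all__ = ["GaussianConfig", "HeatmapStack", "encode", "decode"]


@dataclass(frozen=True)
class GaussianConfig:
    """Geometry of the heatmap stack.

    sigma is the Gaussian kernel radius in heatmap pixels (default 2, the
    customary value for 64–128 px maps); ``stride = input_size /
    heatmap_size`` must be an exact integer.
    """

    heatmap_size: int = 64
    input_size: int = 256
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.input_size % self.heatmap_size:
            raise ValueError("heatmap_size must divide input_size exactly")

    @property
    def stride(self) -> int:
        return self.input_size // self.heatmap_size


@dataclass
class HeatmapStack:
    """One response map per landmark at a fixed stride.

    ``values`` is (n_landmarks, H, H) float32 with entries in [0, 1].
    """

    values: np.ndarray
    stride: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (n, H, H)")

    @property
    def n_landmarks(self) -> int:
        return self.values.shape[0]

    @property
    def heatmap_size(self) -> int:
        return self.values.shape[1]


def encode(landmarks: LandmarkSet, config: GaussianConfig) -> HeatmapStack:
    """Encode network-coordinate landmarks as a Gaussian heatmap stack.

    Landmarks outside the input bounds (or flagged invisible) produce an
    all-zero channel.  The peak value is exactly 1 at the quantized landmark
    cell (unit-peak, not unit-mass, normalization).
    """
    H = config.heatmap_size
    stride = config.stride
    n = len(landmarks)
    maps = np.zeros((n, H, H), dtype=np.float32)
    grid = np.arange(H, dtype=np.float64)
    for c in range(n):
        if not landmarks.visible[c]:
            continue
        x, y = landmarks.points[c]
        if not (0 <= x < config.input_size and 0 <= y < config.input_size):
            continue
        u = int(round(x / stride))
        v = int(round(y / stride))
        u, v = min(u, H - 1), min(v, H - 1)
        gx = np.exp(-((grid - u) ** 2) / (2 * config.sigma ** 2))
        gy = np.exp(-((grid - v) ** 2) / (2 * config.sigma ** 2))
        maps[c] = np.outer(gy, gx)  # rows are y
    return HeatmapStack(maps, stride)


def decode(heatmaps: HeatmapStack,
           quarter_offset: bool = False) -> tuple[LandmarkSet, np.ndarray]:
    """Read landmark coordinates and confidences from a heatmap stack.

    Per channel the landmark is the argmax cell times the stride and the
    confidence its peak value; ties break to the smallest row-major index.
    An all-zero channel yields an invisible landmark with confidence 0.
    ``quarter_offset`` optionally shifts a quarter cell toward the larger
    of the two axis neighbors (off by default for determinism).
    """
    vals = heatmaps.values
    if vals.shape[0] < 1:
        raise ValueError("empty heatmap stack")
    n, H, _ = vals.shape
    pts = np.zeros((n, 2), dtype=float)
    vis = np.zeros(n, dtype=bool)
    conf = np.zeros(n, dtype=float)
    for c in range(n):
        flat = int(np.argmax(vals[c]))
        v, u = divmod(flat, H)
        peak = float(vals[c, v, u])
        conf[c] = peak
        if peak <= 0:
            continue
        uu, vv = float(u), float(v)
        if quarter_offset:
            if 0 < u < H - 1:
                uu += 0.25 * np.sign(vals[c, v, u + 1] - vals[c, v, u - 1])
            if 0 < v < H - 1:
                vv += 0.25 * np.sign(vals[c, v + 1, u] - vals[c, v - 1, u])
        pts[c] = (uu * heatmaps.stride, vv * heatmaps.stride)
        vis[c] = True
    return LandmarkSet(pts, vis), conf
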