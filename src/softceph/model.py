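"""The heatmap-regression network (BHR-Net).

A U-Net-style encoder downsamples the input with stride-2 convolutions
(no max pooling), saving each scale's feature map; a reversed
high-resolution decoder then fuses all scales and *drops the
lowest-resolution branch at each stage* — the opposite of HR-Net, which
keeps adding low-resolution branches.  Stage 2 runs on every encoder
scale (repeated twice by default), Stage 3 on all but the lowest
(repeated four times), Stage 4 on the remainder.  The final head
upsamples the lowest-resolution output of Stages 2, 3 and 4, fuses them
with the Stage-4 full-resolution map, and projects to one heatmap
channel per landmark.  The full-resolution stream runs at 1/4 of the
input (a stride-4 stem), so a 256 px input yields 64 px heatmaps; a 2×
upsampling head option produces 128 px maps for the 34-point schema.

Everything is NCHW float32 on the package's own NumPy autodiff
(:mod:`softceph.nn`); weights are He-initialized from a seeded generator,
so builds are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .heatmap_codec import HeatmapStack

__all__ = ["ModelConfig", "NetworkOutput", "BHRNet", "build_bhrnet",
           "predict", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``heatmap_size`` must be input_size/4 (generic) or input_size/2
    (the high-resolution option used with the 34-point schema).
    ``base_width`` is the channel count of the full-resolution branch;
    each downsample doubles it.
    """

    input_size: int = 256
    heatmap_size: int = 64
    n_landmarks: int = 34
    in_channels: int = 3
    base_width: int = 32
    n_downsamples: int = 3
    stage2_repeats: int = 2
    stage3_repeats: int = 4

    def __post_init__(self) -> None:
        if self.input_size // self.heatmap_size not in (2, 4) or \
                self.input_size % self.heatmap_size:
            raise ValueError("input_size / heatmap_size must be 2 or 4")
        if self.n_downsamples < 2:
            raise ValueError("need at least two downsamples")
        if min(self.stage2_repeats, self.stage3_repeats) < 1:
            raise ValueError("stage repeats must be >= 1")
        if self.input_size % (4 * 2 ** self.n_downsamples):
            raise ValueError("input_size too small for n_downsamples")

    @property
    def stride(self) -> int:
        return self.input_size // self.heatmap_size


@dataclass
class NetworkOutput:
    """Batched network prediction: (N, n_landmarks, H, H) heatmaps."""

    heatmaps: np.ndarray
    stride: int

    def stack(self, i: int = 0) -> HeatmapStack:
        """Heatmap stack of sample ``i``, clipped to [0, 1] for decoding."""
        return HeatmapStack(np.clip(self.heatmaps[i], 0.0, 1.0), self.stride)


class _ConvBlock(nn.Module):
    """conv3x3 (optionally strided) + batchnorm + relu."""

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv = self.add_child("conv", nn.Conv2d(cin, cout, 3, stride, rng))
        self.bn = self.add_child("bn", nn.BatchNorm2d(cout))

    def __call__(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _Fuse(nn.Module):
    """One multi-scale exchange: every output branch sums resampled inputs.

    Higher-resolution inputs reach lower branches through chained stride-2
    convolutions; lower-resolution inputs reach higher branches through a
    1x1 projection and nearest upsampling.  Each fused branch then passes
    through one conv block.
    """

    def __init__(self, widths_in, widths_out, rng):
        super().__init__()
        self.n_in = len(widths_in)
        self.n_out = len(widths_out)
        for i in range(self.n_out):
            for j in range(self.n_in):
                if j < i:          # downsample j -> i
                    chain = []
                    cin = widths_in[j]
                    for s in range(i - j):
                        cout = widths_out[i] if s == i - j - 1 else cin * 2
                        chain.append(self.add_child(
                            f"down{i}_{j}_{s}", nn.Conv2d(cin, cout, 3, 2, rng)))
                        cin = cout
                elif j > i:        # project + upsample j -> i
                    self.add_child(f"up{i}_{j}",
                                   nn.Conv2d(widths_in[j], widths_out[i], 1, 1, rng))
                elif widths_in[j] != widths_out[i]:
                    self.add_child(f"id{i}",
                                   nn.Conv2d(widths_in[j], widths_out[i], 1, 1, rng))
            self.add_child(f"block{i}",
                           _ConvBlock(widths_out[i], widths_out[i], 1, rng))

    def __call__(self, branches):
        outs = []
        for i in range(self.n_out):
            acc = None
            for j in range(self.n_in):
                if j < i:
                    t = branches[j]
                    for s in range(i - j):
                        t = self._children[f"down{i}_{j}_{s}"](t)
                elif j > i:
                    t = self._children[f"up{i}_{j}"](branches[j])
                    t = nn.upsample_nearest(t, 2 ** (j - i))
                else:
                    t = branches[j]
                    if f"id{i}" in self._children:
                        t = self._children[f"id{i}"](t)
                acc = t if acc is None else nn.add(acc, t)
            outs.append(self._children[f"block{i}"](nn.relu(acc)))
        return outs


class BHRNet(nn.Module):
    """Four-stage encoder/decoder heatmap regressor (see module docstring)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.base_width
        # stem: two stride-2 convs bring the input to 1/4 resolution
        self.stem1 = self.add_child(
            "stem1", _ConvBlock(config.in_channels, max(w // 2, 4), 2, rng))
        self.stem2 = self.add_child(
            "stem2", _ConvBlock(max(w // 2, 4), w, 2, rng))
        # Stage 1: encoder — save every scale for the decoder skip path
        self.widths = [w * 2 ** d for d in range(config.n_downsamples + 1)]
        for d in range(config.n_downsamples):
            self.add_child(f"enc{d}",
                           _ConvBlock(self.widths[d], self.widths[d + 1], 2, rng))
        # Stages 2-4: fusion modules with progressive branch dropping
        n_br = config.n_downsamples + 1
        for r in range(config.stage2_repeats):
            self.add_child(f"s2_{r}",
                           _Fuse(self.widths[:n_br], self.widths[:n_br], rng))
        for r in range(config.stage3_repeats):
            self.add_child(f"s3_{r}",
                           _Fuse(self.widths[:n_br - 1], self.widths[:n_br - 1], rng))
        self.add_child("s4_0",
                       _Fuse(self.widths[:n_br - 2], self.widths[:n_br - 2], rng))
        # head: project each stage's lowest-resolution output to base width
        self.add_child("head_s2", nn.Conv2d(self.widths[n_br - 1], w, 1, 1, rng))
        self.add_child("head_s3", nn.Conv2d(self.widths[n_br - 2], w, 1, 1, rng))
        if n_br - 2 >= 2:
            self.add_child("head_s4", nn.Conv2d(self.widths[n_br - 3], w, 1, 1, rng))
        self.add_child("head_block", _ConvBlock(w, w, 1, rng))
        if config.stride == 2:
            self.add_child("head_up_block", _ConvBlock(w, w, 1, rng))
        self.add_child("head_out", nn.Conv2d(w, config.n_landmarks, 1, 1, rng))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.config
        b0 = self.stem2(self.stem1(x))
        branches = [b0]
        for d in range(cfg.n_downsamples):
            branches.append(self._children[f"enc{d}"](branches[-1]))
        n_br = len(branches)
        # Stage 2 on all scales
        for r in range(cfg.stage2_repeats):
            branches = self._children[f"s2_{r}"](branches)
        s2_low = branches[-1]
        branches = branches[:-1]
        # Stage 3 without the lowest branch
        for r in range(cfg.stage3_repeats):
            branches = self._children[f"s3_{r}"](branches)
        s3_low = branches[-1]
        branches = branches[:-1]
        # Stage 4 on what remains
        branches = self._children["s4_0"](branches)
        s4_low = branches[-1] if len(branches) >= 2 else branches[0]
        fused = branches[0]
        # head: lift every stage's lowest-resolution map to full resolution
        t = nn.upsample_nearest(self._children["head_s2"](s2_low), 2 ** (n_br - 1))
        fused = nn.add(fused, t)
        t = nn.upsample_nearest(self._children["head_s3"](s3_low), 2 ** (n_br - 2))
        fused = nn.add(fused, t)
        if "head_s4" in self._children:
            t = nn.upsample_nearest(self._children["head_s4"](s4_low), 2 ** (n_br - 3))
            fused = nn.add(fused, t)
        fused = self._children["head_block"](fused)
        if cfg.stride == 2:
            fused = self._children["head_up_block"](nn.upsample_nearest(fused, 2))
        return self._children["head_out"](fused)


def build_bhrnet(config: ModelConfig, seed: int = 0) -> BHRNet:
    """Construct a randomly initialized network from a config."""
    return BHRNet(config, seed=seed)


def _as_batch(images: np.ndarray, input_size: int) -> np.ndarray:
    """HWC/NHWC uint8-or-float rasters -> normalized NCHW float32."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("expected (H,W,C) or (N,H,W,C) images")
    if arr.shape[1] != input_size or arr.shape[2] != input_size:
        raise ValueError(f"input must be {input_size}x{input_size}, "
                         f"got {arr.shape[1]}x{arr.shape[2]}")
    arr = arr.astype(np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def predict(model: BHRNet, images: np.ndarray) -> NetworkOutput:
    """Run inference (batch-norm in running-stats mode) on raster input."""
    model.set_training(False)
    x = nn.Tensor(_as_batch(images, model.config.input_size))
    out = model(x)
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError("non-finite network output")
    return NetworkOutput(out.data, model.config.stride)


def save_checkpoint(model: BHRNet, path) -> None:
    """Serialize weights, batch-norm buffers and config to an .npz file."""
    arrays = {f"param:{k}": p.data for k, p in model.parameters().items()}
    arrays.update({f"buffer:{k}": v for k, v in model.buffers().items()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> BHRNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = BHRNet(cfg)
        params = model.parameters()
        buffers = model.buffers()
        for key in data.files:
            if key.startswith("param:"):
                params[key[6:]].data = data[key].astype(np.float32)
            elif key.startswith("buffer:"):
                buffers[key[7:]][...] = data[key]
    return model
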