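"""Loss, augmentation and the Adam/plateau training loop.

Training minimizes the pixelwise L2 (MSE) distance between predicted and
target Gaussian heatmaps.  The four augmentations of the acquisition
protocol — rotation, horizontal mirroring (with left/right landmark
relabeling), graying and HSV jitter — expand the dataset fourfold, either
materialized offline (default, deterministic) or sampled on the fly.
The learning rate starts at 1e-3 and drops tenfold whenever the loss has
not improved for 20 consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv, hsv2rgb

from . import nn
from .heatmap_codec import GaussianConfig, HeatmapStack, encode
from .model import BHRNet, _as_batch
from .schema import LandmarkSchema, LandmarkSet, mirror_permutation

__all__ = ["TrainConfig", "AugmentConfig", "PlateauScheduler",
           "heatmap_mse_loss", "augment", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (clinical-protocol defaults)."""

    initial_lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 300
    plateau_patience: int = 20
    lr_decay_factor: float = 0.1
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.batch_size, self.max_epochs,
               self.plateau_patience, self.sigma) <= 0:
            raise ValueError("all training parameters must be positive")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must be in (0, 1)")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation magnitudes; the operations themselves are fixed."""

    rotation_range: float = 30.0     # degrees, uniform in +/- range
    mirror_prob: float = 0.5
    grayscale_prob: float = 0.25
    hsv_jitter: tuple[float, float, float] = (0.02, 0.2, 0.2)
    expansion_factor: int = 4
    offline: bool = True

    def __post_init__(self) -> None:
        for p in (self.mirror_prob, self.grayscale_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")


class PlateauScheduler:
    """Reduce-on-plateau: decay the LR after ``patience`` stale epochs."""

    def __init__(self, initial_lr: float, patience: int = 20,
                 factor: float = 0.1, min_delta: float = 0.0):
        self.lr = initial_lr
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    def step(self, loss: float) -> float:
        """Record an epoch loss; return the LR to use next."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.lr *= self.factor
                self.num_bad = 0
        return self.lr


def heatmap_mse_loss(predicted: HeatmapStack, target: HeatmapStack) -> float:
    """Mean over all channels and cells of squared differences."""
    if predicted.values.shape != target.values.shape:
        raise ValueError("heatmap shape mismatch")
    d = predicted.values.astype(np.float64) - target.values
    return float(np.mean(d * d))


def _rotate(image: np.ndarray, landmarks: LandmarkSet,
            angle_deg: float) -> tuple[np.ndarray, LandmarkSet]:
    """Rotate image and landmarks together about the image center."""
    h, w = image.shape[:2]
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)],
                    [np.sin(th), np.cos(th)]])
    # image warp needs the inverse map (output pixel -> source pixel)
    inv = rot.T
    # ndimage works in (row, col) = (y, x); swap axes of the matrix
    m = inv[::-1, ::-1]
    off = c[::-1] - m @ c[::-1]
    if image.ndim == 3:
        out = np.stack([ndi.affine_transform(image[..., ch].astype(np.float32),
                                             m, off, order=1)
                        for ch in range(image.shape[2])], axis=-1)
    else:
        out = ndi.affine_transform(image.astype(np.float32), m, off, order=1)
    pts = (landmarks.points - c) @ rot.T + c
    lm = landmarks.copy()
    lm.points = pts
    return out.astype(image.dtype), lm


def augment(image: np.ndarray, landmarks: LandmarkSet,
            config: AugmentConfig, rng: np.random.Generator,
            schema: LandmarkSchema | None = None
            ) -> tuple[np.ndarray, LandmarkSet]:
    """One random augmented variant of (image, landmarks).

    Geometric transforms move image and coordinates identically; mirroring
    additionally relabels left/right landmark pairs through the schema's
    mirror permutation; photometric transforms (graying, HSV jitter) leave
    coordinates untouched.  Deterministic given the generator state.
    """
    img = image
    lm = landmarks.copy()
    angle = float(rng.uniform(-config.rotation_range, config.rotation_range))
    if angle != 0.0:
        img, lm = _rotate(img, lm, angle)
    if rng.random() < config.mirror_prob:
        w = img.shape[1]
        img = img[:, ::-1].copy()
        lm.points[:, 0] = (w - 1) - lm.points[:, 0]
        if schema is not None:
            perm = mirror_permutation(schema)
            lm.points = lm.points[perm]
            lm.visible = lm.visible[perm]
    if img.ndim == 3 and rng.random() < config.grayscale_prob:
        lum = img.astype(np.float32) @ np.array([0.299, 0.587, 0.114],
                                                dtype=np.float32)
        img = np.repeat(lum[..., None], img.shape[2], axis=2).astype(image.dtype)
    elif img.ndim == 3:
        jh, js, jv = config.hsv_jitter
        hsv = rgb2hsv(np.clip(img, 0, 255).astype(np.float32) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-jh, jh)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-js, js)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-jv, jv)), 0, 1)
        img = (hsv2rgb(hsv) * 255).astype(image.dtype)
    return img, lm


def _encode_targets(samples, gcfg: GaussianConfig) -> np.ndarray:
    return np.stack([encode(lm, gcfg).values for _, lm in samples])


def train(model: BHRNet, dataset, tcfg: TrainConfig | None = None,
          acfg: AugmentConfig | None = None,
          schema: LandmarkSchema | None = None):
    """Fit the network on (image, LandmarkSet) pairs in network coordinates.

    Parameters
    ----------
    dataset : sequence of (raster, LandmarkSet)
        Images already cropped/resized to ``model.config.input_size``;
        landmark coordinates in network-input pixels.
    tcfg, acfg : configs
        ``acfg=None`` disables augmentation entirely.

    Returns
    -------
    (model, history) where history is a list of
    ``{"epoch", "loss", "lr"}`` dicts, one per epoch.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    tcfg = tcfg or TrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    gcfg = GaussianConfig(model.config.heatmap_size, model.config.input_size,
                          tcfg.sigma)

    samples = list(dataset)
    if acfg is not None and acfg.offline and acfg.expansion_factor > 1:
        expanded = list(samples)
        for img, lm in samples:
            for _ in range(acfg.expansion_factor - 1):
                expanded.append(augment(img, lm, acfg, rng, schema))
        samples = expanded

    images = np.stack([s[0] for s in samples])
    targets = _encode_targets(samples, gcfg)
    x_all = _as_batch(images, model.config.input_size)

    params = model.parameters()
    opt = nn.Adam(params, lr=tcfg.initial_lr)
    sched = PlateauScheduler(tcfg.initial_lr, tcfg.plateau_patience,
                             tcfg.lr_decay_factor)
    history = []
    n = len(samples)
    model.set_training(True)
    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            if acfg is not None and not acfg.offline:
                batch_imgs, batch_lms = [], []
                for i in idx:
                    img, lm = augment(*dataset[i % len(dataset)], acfg, rng,
                                      schema)
                    batch_imgs.append(img)
                    batch_lms.append(lm)
                xb = _as_batch(np.stack(batch_imgs), model.config.input_size)
                tb = _encode_targets(list(zip(batch_imgs, batch_lms)), gcfg)
            else:
                xb, tb = x_all[idx], targets[idx]
            opt.zero_grad()
            out = model(nn.Tensor(xb))
            loss = nn.mse_loss(out, tb)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += lval * len(idx)
        epoch_loss /= n
        opt.lr = sched.step(epoch_loss)
        history.append({"epoch": epoch, "loss": epoch_loss, "lr": opt.lr})
    return model, history
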