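"""U-Net chamber segmentation: build, augment, train, predict.

The network follows the classic encoder/decoder layout: a contracting path of
two 3x3 convolutions + ReLU per level followed by 2x2 max pooling, channel
count doubling at every contraction step; an expanding path of 2x2
up-convolutions whose feature maps are concatenated with the matching encoder
level; and a final 1x1 convolution to one logit map per class (background plus
chambers).  Same-padding keeps the segmentation maps at the input resolution.

Training pairs are grayscale frames with per-chamber binary masks; the
augmentation recipe (rotations, small shifts, shear, zoom, no flips) is
applied identically to frame (bilinear) and mask (nearest-neighbor).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import affine_transform

from . import nn
from .errors import ConfigError, EmptyDatasetError, ShapeMismatchError
from .io import CHAMBER_LABELS, ImageFrame, label_image_to_masks, masks_to_label_image
from .nn import DTYPE
from .pggan import ArchitectureSpec, LayerDescriptor
from .phantom import VIEW_CHAMBERS


# ---------------------------------------------------------------------------
# configuration


@dataclass
class UNetConfig:
    input_resolution: int = 128
    input_channels: int = 1
    n_classes: int = 3              # background + LV + RV (4 with RA)
    depth: int = 4
    base_channels: int = 64
    growth_factor: int = 2          # channels double at each contraction step

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.input_resolution % (2 ** self.depth) != 0:
            raise ConfigError(
                f"input_resolution {self.input_resolution} not divisible by "
                f"2^depth = {2 ** self.depth}")

    @classmethod
    def for_view(cls, view: str, **kwargs) -> "UNetConfig":
        n_classes = 1 + len(VIEW_CHAMBERS[view])
        return cls(n_classes=n_classes, **kwargs)


@dataclass
class AugmentationSpec:
    """Geometric augmentation limits; flips stay disabled."""

    rotation_limit: float = 20.0     # degrees
    width_shift: float = 0.05        # fraction of the frame side
    height_shift: float = 0.05
    shear_limit: float = 0.20        # shear factor
    zoom_limit: float = 0.10         # fractional zoom range
    flips: bool = False

    def __post_init__(self):
        for name in ("rotation_limit", "width_shift", "height_shift",
                     "shear_limit", "zoom_limit"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.flips:
            raise ConfigError("flips are disabled in this augmentation recipe")

    def is_identity(self) -> bool:
        return all(getattr(self, n) == 0 for n in
                   ("rotation_limit", "width_shift", "height_shift",
                    "shear_limit", "zoom_limit"))


@dataclass
class SegTrainConfig:
    validation_split: float = 0.05
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-4
    loss: str = "cross_entropy"      # "cross_entropy" | "soft_dice"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_split < 1.0:
            raise ConfigError("validation_split must be in (0, 1)")
        if self.loss not in ("cross_entropy", "soft_dice"):
            raise ConfigError(f"unknown loss {self.loss!r}")


def build_unet_spec(config: UNetConfig) -> ArchitectureSpec:
    """Declarative blueprint of the symmetric encoder/decoder."""
    c = config.base_channels
    g = config.growth_factor
    blocks: list[list[LayerDescriptor]] = []
    cin = config.input_channels
    enc_channels = [c * g ** i for i in range(config.depth)]
    for ch in enc_channels:
        blocks.append([
            LayerDescriptor("conv3x3", cin, ch, "relu"),
            LayerDescriptor("conv3x3", ch, ch, "relu"),
            LayerDescriptor("maxpool2x", ch, ch),
        ])
        cin = ch
    bott = c * g ** config.depth
    blocks.append([
        LayerDescriptor("conv3x3", cin, bott, "relu"),
        LayerDescriptor("conv3x3", bott, bott, "relu"),
    ])
    cin = bott
    for ch in reversed(enc_channels):
        blocks.append([
            LayerDescriptor("upconv2x2", cin, ch, "relu"),
            LayerDescriptor("concat", ch * 2, ch * 2),
            LayerDescriptor("conv3x3", ch * 2, ch, "relu"),
            LayerDescriptor("conv3x3", ch, ch, "relu"),
        ])
        cin = ch
    tail = [LayerDescriptor("to_image", cin, config.n_classes)]
    return ArchitectureSpec("unet", 0, config.input_resolution, blocks,
                            tail=tail)


# ---------------------------------------------------------------------------
# model


class UNet:
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        c, g = config.base_channels, config.growth_factor
        enc_channels = [c * g ** i for i in range(config.depth)]
        self.enc = []
        cin = config.input_channels
        for ch in enc_channels:
            self.enc.append((nn.Conv2d(cin, ch, 3, rng), nn.ReLU(),
                             nn.Conv2d(ch, ch, 3, rng), nn.ReLU(),
                             nn.MaxPool2x()))
            cin = ch
        bott = c * g ** config.depth
        self.bottleneck = (nn.Conv2d(cin, bott, 3, rng), nn.ReLU(),
                           nn.Conv2d(bott, bott, 3, rng), nn.ReLU())
        self.dec = []
        cin = bott
        for ch in reversed(enc_channels):
            self.dec.append((nn.Upsample2x(), nn.Conv2d(cin, ch, 2, rng),
                             nn.ReLU(),
                             nn.Conv2d(ch * 2, ch, 3, rng), nn.ReLU(),
                             nn.Conv2d(ch, ch, 3, rng), nn.ReLU()))
            cin = ch
        self.head = nn.Conv2d(cin, config.n_classes, 1, rng)

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for grp in [*self.enc, self.bottleneck, *self.dec, (self.head,)]:
            for layer in grp:
                out.extend(layer.parameters())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.config.input_resolution:
            raise ShapeMismatchError(
                f"expected input resolution {self.config.input_resolution}, "
                f"got {x.shape[-1]}")
        h = x.astype(DTYPE, copy=False)
        skips = []
        for c1, a1, c2, a2, pool in self.enc:
            h = a2.forward(c2.forward(a1.forward(c1.forward(h))))
            skips.append(h)
            h = pool.forward(h)
        c1, a1, c2, a2 = self.bottleneck
        h = a2.forward(c2.forward(a1.forward(c1.forward(h))))
        self._skip_channels = []
        for (up, upc, upa, c1, a1, c2, a2), skip in zip(self.dec,
                                                        reversed(skips)):
            h = upa.forward(upc.forward(up.forward(h)))
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = a2.forward(c2.forward(a1.forward(c1.forward(h))))
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        dh = self.head.backward(dy.astype(DTYPE, copy=False))
        dskips = []
        for (up, upc, upa, c1, a1, c2, a2), ch in zip(
                reversed(self.dec), reversed(self._skip_channels)):
            dh = c1.backward(a1.backward(c2.backward(a2.backward(dh))))
            dskip, dh = dh[:, :ch], dh[:, ch:]
            dskips.append(dskip)
            dh = up.backward(upc.backward(upa.backward(dh)))
        c1, a1, c2, a2 = self.bottleneck
        dh = c1.backward(a1.backward(c2.backward(a2.backward(dh))))
        # dskips were collected finest-first; encoder unwinds deepest-first
        for (c1, a1, c2, a2, pool), dskip in zip(reversed(self.enc),
                                                 reversed(dskips)):
            dh = pool.backward(dh) + dskip
            dh = c1.backward(a1.backward(c2.backward(a2.backward(dh))))


class SegModel:
    """A trained U-Net with its class-to-chamber mapping."""

    def __init__(self, net: UNet, view: str):
        self.net = net
        self.view = view
        self.chambers = VIEW_CHAMBERS[view]

    @property
    def input_resolution(self) -> int:
        return self.net.config.input_resolution

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.parameters())}
        meta = {"config": asdict(self.net.config), "view": self.view}
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = UNet(UNetConfig(**meta["config"]), np.random.default_rng(0))
            for i, p in enumerate(net.parameters()):
                p.value = data[f"p{i}"].astype(DTYPE)
        return cls(net, meta["view"])


# ---------------------------------------------------------------------------
# augmentation


def _draw_affine(spec: AugmentationSpec, size: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random transform within the spec limits, as (matrix, offset) for
    scipy's affine_transform (output->input mapping about the frame center)."""
    theta = math.radians(rng.uniform(-spec.rotation_limit, spec.rotation_limit))
    shear = rng.uniform(-spec.shear_limit, spec.shear_limit)
    zoom = 1.0 + rng.uniform(-spec.zoom_limit, spec.zoom_limit)
    dr = rng.uniform(-spec.height_shift, spec.height_shift) * size
    dc = rng.uniform(-spec.width_shift, spec.width_shift) * size
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    fwd = zoom * (rot @ shr)
    inv = np.linalg.inv(fwd)
    center = (size - 1) / 2.0
    offset = np.array([center, center]) - inv @ np.array([center + dr,
                                                          center + dc])
    return inv, offset


def augment_pair(image: ImageFrame | np.ndarray, masks: dict[str, np.ndarray],
                 spec: AugmentationSpec,
                 rng_seed: int = 0) -> tuple[ImageFrame, dict[str, np.ndarray]]:
    """Apply one seeded random geometric transform to a frame and its masks.

    The frame is interpolated bilinearly, the label image with nearest
    neighbor, so mask labels are preserved exactly.
    """
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
    label = masks_to_label_image(masks)
    if arr.shape != label.shape:
        raise ShapeMismatchError(
            f"image {arr.shape} and mask {label.shape} shapes differ")
    if spec.is_identity():
        return ImageFrame(arr.copy()), {k: v.copy() for k, v in masks.items()}
    rng = np.random.default_rng(rng_seed)
    matrix, offset = _draw_affine(spec, arr.shape[0], rng)
    out_img = affine_transform(arr, matrix, offset=offset, order=1,
                               mode="nearest")
    out_label = affine_transform(label, matrix, offset=offset, order=0,
                                 mode="constant", cval=0)
    return ImageFrame(np.clip(out_img, 0.0, 1.0)), label_image_to_masks(out_label)


def expand_dataset(pairs: list, spec: AugmentationSpec, factor: int,
                   rng_seed: int = 0) -> list:
    """Augment each (frame, masks) pair ``factor`` times with derived seeds."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(pairs) * factor)
    out = []
    k = 0
    for rep in range(factor):
        for image, masks in pairs:
            out.append(augment_pair(image, masks, spec, int(seeds[k])))
            k += 1
    return out


# ---------------------------------------------------------------------------
# training / prediction


def _pairs_to_tensors(pairs: list, config: UNetConfig,
                      view: str) -> tuple[np.ndarray, np.ndarray]:
    chambers = VIEW_CHAMBERS[view]
    xs, ys = [], []
    for image, masks in pairs:
        arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
        if arr.shape[0] != config.input_resolution:
            raise ShapeMismatchError(
                f"pair resolution {arr.shape[0]} != configured "
                f"{config.input_resolution}")
        onehot = np.zeros((config.n_classes,) + arr.shape, dtype=DTYPE)
        claimed = np.zeros(arr.shape, dtype=bool)
        for ci, chamber in enumerate(chambers, start=1):
            m = np.asarray(masks.get(chamber, np.zeros(arr.shape, bool)), bool)
            onehot[ci][m] = 1.0
            claimed |= m
        onehot[0][~claimed] = 1.0
        xs.append(arr[None].astype(DTYPE))
        ys.append(onehot)
    return np.stack(xs), np.stack(ys)


@dataclass
class SegTrainingLog:
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)


def train_unet(pairs: list, unet_config: UNetConfig,
               train_config: SegTrainConfig,
               view: str = "SAX") -> tuple[SegModel, SegTrainingLog]:
    """Train on (frame, masks) pairs; the last validation fraction (after a
    seeded shuffle) is held out and only scored, never fitted."""
    if len(pairs) < 2:
        raise EmptyDatasetError("need at least 2 training pairs")
    x, y = _pairs_to_tensors(pairs, unet_config, view)
    rng = np.random.default_rng(train_config.rng_seed)
    order = rng.permutation(len(pairs))
    x, y = x[order], y[order]
    n_val = max(1, int(round(train_config.validation_split * len(pairs))))
    x_train, y_train = x[:-n_val], y[:-n_val]
    x_val, y_val = x[-n_val:], y[-n_val:]

    net = UNet(unet_config, np.random.default_rng(rng.integers(2 ** 31)))
    opt = nn.Adam(net.parameters(), lr=train_config.learning_rate,
                  beta1=0.9, beta2=0.999)
    log = SegTrainingLog()
    bs = train_config.batch_size
    for _ in range(train_config.epochs):
        perm = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(x_train), bs):
            idx = perm[start:start + bs]
            logits = net.forward(x_train[idx])
            loss, dlogits = _loss_and_grad(logits, y_train[idx],
                                           train_config.loss)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        log.epoch_train_loss.append(float(np.mean(losses)))
        vlosses = []
        for start in range(0, len(x_val), bs):
            logits = net.forward(x_val[start:start + bs])
            vloss, _ = _loss_and_grad(logits, y_val[start:start + bs],
                                      train_config.loss)
            vlosses.append(vloss)
        log.epoch_val_loss.append(float(np.mean(vlosses)))
    return SegModel(net, view), log


def _loss_and_grad(logits: np.ndarray, onehot: np.ndarray,
                   loss: str) -> tuple[float, np.ndarray]:
    if loss == "cross_entropy":
        return nn.softmax_cross_entropy(logits, onehot)
    # soft dice over softmax probabilities, averaged over classes
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    eps = 1.0
    inter = (p * onehot).sum(axis=(0, 2, 3))
    denom = (p + onehot).sum(axis=(0, 2, 3))
    dice = (2 * inter + eps) / (denom + eps)
    loss_val = float(1.0 - dice.mean())
    c = logits.shape[1]
    ddice_dp = (2 * onehot * (denom + eps)[None, :, None, None]
                - (2 * inter + eps)[None, :, None, None]) \
        / np.square(denom + eps)[None, :, None, None]
    dp = -ddice_dp / c
    dot = (dp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dp - dot)
    return loss_val, dlogits.astype(DTYPE)


def predict_segmentation(model: SegModel,
                         image: ImageFrame | np.ndarray) -> dict[str, np.ndarray]:
    """Argmax class map -> disjoint per-chamber masks (background excluded)."""
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
    if arr.shape[0] != model.input_resolution or arr.shape[0] != arr.shape[1]:
        raise ShapeMismatchError(
            f"image shape {arr.shape} does not match model input resolution "
            f"{model.input_resolution} (no silent resizing)")
    logits = model.net.forward(arr[None, None].astype(DTYPE))
    classes = np.argmax(logits[0], axis=0)      # ties -> lowest class index
    return {chamber: classes == ci
            for ci, chamber in enumerate(model.chambers, start=1)}
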