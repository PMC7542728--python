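"""Frame and mask I/O.

Frames are grayscale 2-D images carried in memory as ``ImageFrame`` objects with
intensities normalized to [0, 1].  On disk, frames are 8-bit grayscale PNG and
chamber masks are indexed PNG label images (0 = background, 1 = LV, 2 = RV,
3 = RA).  DICOM single frames and cine loops are read-only inputs; multi-frame
files require an explicit frame index rather than silently taking the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FrameReadError, ResolutionError, ShapeMismatchError

#: label value per chamber in indexed mask PNGs
CHAMBER_LABELS = {"LV": 1, "RV": 2, "RA": 3}
LABEL_CHAMBERS = {v: k for k, v in CHAMBER_LABELS.items()}

_MASK_PALETTE = [0, 0, 0, 220, 50, 50, 60, 120, 220, 240, 200, 60] + [0] * (756)


@dataclass
class ImageFrame:
    """A single grayscale frame with intensities in [0, 1]."""

    pixels: np.ndarray
    path: str | None = None
    source_bit_depth: int | None = None
    source_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeMismatchError(f"frame must be 2-D, got shape {self.pixels.shape}")

    @property
    def resolution(self) -> tuple[int, int]:
        return self.pixels.shape  # (H, W)


def is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def read_frame(path: str | Path, frame_index: int | None = None) -> ImageFrame:
    """Read a PNG or DICOM file into an ImageFrame scaled to [0, 1].

    PNG: fixed scaling by the bit-depth maximum (255 or 65535).  DICOM:
    per-image min-max windowing.  Multi-frame DICOM requires ``frame_index``.
    """
    path = Path(path)
    if not path.exists():
        raise FrameReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".png", ".tif", ".tiff"):
        img = Image.open(path)
        orig_size = img.size
        if img.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(img, dtype=np.float64)
            depth = 16
            arr = arr / 65535.0
        elif img.mode in ("L", "P"):
            arr = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
            depth = 8
        else:
            raise FrameReadError(
                f"{path}: mode {img.mode} is not grayscale; convert explicitly"
            )
        return ImageFrame(arr, path=str(path), source_bit_depth=depth,
                          source_size=orig_size)
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path, frame_index)
    raise FrameReadError(f"{path}: unsupported format {suffix!r}")


def _read_dicom(path: Path, frame_index: int | None) -> ImageFrame:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - malformed files
        raise FrameReadError(f"{path}: DICOM read failed: {exc}") from exc
    if arr.ndim == 3:
        if frame_index is None:
            raise FrameReadError(
                f"{path}: multi-frame DICOM ({arr.shape[0]} frames) requires an "
                "explicit frame_index"
            )
        if not 0 <= frame_index < arr.shape[0]:
            raise FrameReadError(f"{path}: frame_index {frame_index} out of range")
        arr = arr[frame_index]
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    return ImageFrame(scaled, path=str(path),
                      source_bit_depth=int(getattr(ds, "BitsStored", 0) or 0),
                      source_size=(arr.shape[1], arr.shape[0]))


def write_frame(frame: ImageFrame | np.ndarray, path: str | Path) -> None:
    """Write a frame as 8-bit grayscale PNG (values clipped to [0, 1])."""
    pixels = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    arr8 = np.clip(np.round(np.clip(pixels, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr8, mode="L").save(Path(path))


def masks_to_label_image(masks: dict[str, np.ndarray]) -> np.ndarray:
    """Collapse per-chamber binary masks into one label image (uint8)."""
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"mask shapes differ: {shapes}")
    shape = next(iter(shapes))
    label = np.zeros(shape, dtype=np.uint8)
    for chamber, mask in masks.items():
        label[np.asarray(mask, dtype=bool)] = CHAMBER_LABELS[chamber]
    return label


def label_image_to_masks(label: np.ndarray) -> dict[str, np.ndarray]:
    """Split a label image back into per-chamber boolean masks (present labels only)."""
    out = {}
    for value in np.unique(label):
        if value == 0:
            continue
        out[LABEL_CHAMBERS[int(value)]] = label == value
    return out


def write_mask(masks: dict[str, np.ndarray] | np.ndarray, path: str | Path) -> None:
    """Write chamber masks as an indexed PNG (palette mode, labels 0..3)."""
    label = masks if isinstance(masks, np.ndarray) else masks_to_label_image(masks)
    img = Image.fromarray(label.astype(np.uint8), mode="P")
    img.putpalette(_MASK_PALETTE)
    img.save(Path(path))


def read_mask(path: str | Path) -> dict[str, np.ndarray]:
    img = Image.open(Path(path))
    if img.mode not in ("P", "L"):
        raise FrameReadError(f"{path}: mask must be indexed or grayscale PNG")
    return label_image_to_masks(np.asarray(img, dtype=np.uint8))


def resize_frame(frame: ImageFrame, resolution: int) -> ImageFrame:
    """Bilinear resize of a square frame to ``resolution`` (a power of two)."""
    if not is_power_of_two(resolution):
        raise ResolutionError(f"target resolution {resolution} is not a power of two")
    h, w = frame.pixels.shape
    if (h, w) == (resolution, resolution):
        return ImageFrame(frame.pixels.copy(), path=frame.path,
                          source_bit_depth=frame.source_bit_depth,
                          source_size=frame.source_size)
    img = Image.fromarray(frame.pixels.astype(np.float32), mode="F")
    out = np.asarray(img.resize((resolution, resolution), Image.BILINEAR),
                     dtype=np.float64)
    return ImageFrame(np.clip(out, 0.0, 1.0), path=frame.path,
                      source_bit_depth=frame.source_bit_depth,
                      source_size=frame.source_size)


@dataclass
class PairEntry:
    """One manifest row: a frame/mask pair with provenance."""

    frame: str
    mask: str
    view: str
    seed: int = 0
    extra: dict = field(default_factory=dict)


def write_manifest(entries: list[PairEntry], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "mask", "view", "seed"])
        for e in entries:
            writer.writerow([e.frame, e.mask, e.view, e.seed])


def read_manifest(path: str | Path) -> list[PairEntry]:
    import csv

    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(PairEntry(frame=row["frame"], mask=row["mask"],
                                     view=row["view"], seed=int(row["seed"])))
    return entries


def load_pairs(manifest_path: str | Path) -> list[tuple[ImageFrame, dict[str, np.ndarray]]]:
    """Load all (frame, masks) pairs of a manifest; paths relative to the manifest."""
    base = Path(manifest_path).parent
    pairs = []
    for e in read_manifest(manifest_path):
        frame = read_frame(base / e.frame)
        masks = read_mask(base / e.mask)
        pairs.append((frame, masks))
    return pairs
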