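"""Multi-scale sliced Wasserstein similarity between image sets.

Each image is decomposed into a Laplacian pyramid (5-tap binomial filter).
From every band, small normalized patches are sampled as descriptors; two
descriptor clouds are compared by the sliced Wasserstein distance: the average
over random unit projections of the exact 1-D Wasserstein-1 distance between
the projected samples (mean absolute difference of the sorted projections).
Lower distance means the two sets share local statistics at that scale.  The
same machinery ranks reference images by similarity to a query frame, which is
how memorization of training images by a generative model is audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .errors import EmptyDatasetError, ResolutionError, ShapeMismatchError
from .io import ImageFrame, is_power_of_two

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class PyramidBand:
    level: int                 # 0 = finest
    band: np.ndarray
    is_residual: bool = False


@dataclass
class DescriptorSet:
    patches: np.ndarray        # (n_patches, patch_size**2), standardized
    level: int
    patch_size: int


@dataclass
class SimilarityResult:
    per_level: dict[int, float]
    average: float
    ranking: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class SWDConfig:
    """Knobs for the similarity index (all scales are configurable)."""

    patch_size: int = 7
    patches_per_image: int = 128
    n_projections: int = 256
    min_resolution: int = 16
    descriptors_per_level: int = 512   # per side, for set-vs-set comparisons
    seed: int = 0


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
    return arr.astype(np.float64, copy=False)


def _blur(img: np.ndarray) -> np.ndarray:
    out = correlate1d(img, _BINOMIAL5, axis=0, mode="reflect")
    return correlate1d(out, _BINOMIAL5, axis=1, mode="reflect")


def pyramid_downsample(img: np.ndarray) -> np.ndarray:
    return _blur(img)[::2, ::2]


def _upsample_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Polyphase 2x upsampling along one axis: zero insertion followed by the
    2x-gain binomial filter, with constant-preserving boundary handling."""
    # even phase: taps [1, 6, 1]/8 on neighbors; odd phase: midpoint average
    even = correlate1d(a, np.array([1.0, 6.0, 1.0]) / 8.0, axis=axis,
                       mode="reflect")
    a_m = np.moveaxis(a, axis, 0)
    ext = np.concatenate([a_m, a_m[-1:]], axis=0)
    odd = np.moveaxis((ext[:-1] + ext[1:]) / 2.0, 0, axis)
    out_shape = list(a.shape)
    out_shape[axis] *= 2
    out = np.empty(out_shape)
    sl_even = [slice(None)] * a.ndim
    sl_odd = [slice(None)] * a.ndim
    sl_even[axis] = slice(0, None, 2)
    sl_odd[axis] = slice(1, None, 2)
    out[tuple(sl_even)] = even
    out[tuple(sl_odd)] = odd
    return out


def pyramid_upsample(img: np.ndarray) -> np.ndarray:
    return _upsample_axis(_upsample_axis(img, 0), 1)


def laplacian_pyramid(image, min_resolution: int = 16) -> list[PyramidBand]:
    """Difference-of-lowpass bands from full resolution down to the residual.

    The finest band is level 0; the coarsest entry is the low-pass residual at
    ``min_resolution``.  Summing all bands (after upsampling) reconstructs the
    input exactly up to floating-point error.
    """
    img = _as_array(image)
    h, w = img.shape
    if h != w or not is_power_of_two(h):
        raise ResolutionError(f"image must be square power-of-two, got {img.shape}")
    if h < min_resolution:
        raise ResolutionError(
            f"image side {h} below min_resolution {min_resolution}")
    bands: list[PyramidBand] = []
    level = 0
    while img.shape[0] > min_resolution:
        low = pyramid_downsample(img)
        bands.append(PyramidBand(level, img - pyramid_upsample(low)))
        img = low
        level += 1
    bands.append(PyramidBand(level, img, is_residual=True))
    return bands


def reconstruct(bands: list[PyramidBand]) -> np.ndarray:
    img = bands[-1].band
    for b in reversed(bands[:-1]):
        img = pyramid_upsample(img) + b.band
    return img


def _standardize(patches: np.ndarray) -> np.ndarray:
    mean = patches.mean(axis=1, keepdims=True)
    sd = patches.std(axis=1, keepdims=True)
    out = np.where(sd > 1e-12, (patches - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def sample_patch_descriptors(band: PyramidBand, n_patches: int,
                             patch_size: int = 7,
                             rng_seed: int = 0) -> DescriptorSet:
    """Uniformly sample standardized square patches from one pyramid band."""
    arr = band.band
    side = arr.shape[0]
    if patch_size > side:
        raise ShapeMismatchError(
            f"patch_size {patch_size} exceeds band side {side}")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows = rng.integers(0, side - patch_size + 1, size=n_patches)
    cols = rng.integers(0, arr.shape[1] - patch_size + 1, size=n_patches)
    patches = np.stack([
        arr[r:r + patch_size, c:c + patch_size].ravel()
        for r, c in zip(rows, cols)])
    return DescriptorSet(_standardize(patches), band.level, patch_size)


def sliced_wasserstein(descA: DescriptorSet, descB: DescriptorSet,
                       n_projections: int = 256, rng_seed: int = 0) -> float:
    """Average 1-D Wasserstein-1 distance over random unit projections."""
    a, b = descA.patches, descB.patches
    if a.shape[1] != b.shape[1]:
        raise ShapeMismatchError(
            f"descriptor dimensions differ: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[0] != b.shape[0]:
        raise ShapeMismatchError(
            f"descriptor set sizes differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise EmptyDatasetError("descriptor sets are empty")
    rng = np.random.default_rng(rng_seed)
    dirs = rng.standard_normal((a.shape[1], n_projections))
    dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
    pa = np.sort(a @ dirs, axis=0)
    pb = np.sort(b @ dirs, axis=0)
    return float(np.mean(np.abs(pa - pb)))


def _level_descriptors(images: list[np.ndarray], level_bands: list[np.ndarray],
                       n_desc: int, patch_size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_desc`` standardized patches across a set's bands at one level."""
    side = level_bands[0].shape[0]
    img_idx = rng.integers(0, len(level_bands), size=n_desc)
    rows = rng.integers(0, side - patch_size + 1, size=n_desc)
    cols = rng.integers(0, side - patch_size + 1, size=n_desc)
    patches = np.stack([
        level_bands[i][r:r + patch_size, c:c + patch_size].ravel()
        for i, r, c in zip(img_idx, rows, cols)])
    return _standardize(patches)


def multiscale_swd(setA: list, setB: list,
                   config: SWDConfig | None = None) -> SimilarityResult:
    """Per-pyramid-level sliced Wasserstein distances between two image sets.

    Both sets must share one square power-of-two resolution.  For each level an
    equal number of descriptors is drawn from each side (with a level-specific
    seed shared by both sides, so identical sets give distance zero).
    """
    config = config or SWDConfig()
    if not setA or not setB:
        raise EmptyDatasetError("both image sets must be non-empty")
    arrsA = [_as_array(f) for f in setA]
    arrsB = [_as_array(f) for f in setB]
    sizes = {a.shape for a in arrsA + arrsB}
    if len(sizes) > 1:
        raise ShapeMismatchError(f"mixed image sizes: {sizes}")
    pyrA = [laplacian_pyramid(a, config.min_resolution) for a in arrsA]
    pyrB = [laplacian_pyramid(b, config.min_resolution) for b in arrsB]
    n_levels = len(pyrA[0])
    per_level: dict[int, float] = {}
    for lvl in range(n_levels):
        side = pyrA[0][lvl].band.shape[0]
        patch = min(config.patch_size, side)
        n_desc = min(config.descriptors_per_level,
                     config.patches_per_image * max(len(arrsA), len(arrsB)))
        seed = np.random.SeedSequence([config.seed, lvl]).generate_state(1)[0]
        rngA = np.random.default_rng(seed)
        rngB = np.random.default_rng(seed)
        a = _level_descriptors(arrsA, [p[lvl].band for p in pyrA], n_desc,
                               patch, rngA)
        b = _level_descriptors(arrsB, [p[lvl].band for p in pyrB], n_desc,
                               patch, rngB)
        dist = sliced_wasserstein(
            DescriptorSet(a, lvl, patch), DescriptorSet(b, lvl, patch),
            config.n_projections, int(seed))
        per_level[lvl] = dist
    avg = float(np.mean(list(per_level.values())))
    return SimilarityResult(per_level=per_level, average=avg)


def rank_most_similar(query, references: list,
                      config: SWDConfig | None = None) -> SimilarityResult:
    """Rank reference images by ascending average multiscale SWD to the query.

    Identical seeds are used for every query/reference pair, so a bitwise copy
    of a reference scores exactly zero and ranks first.
    """
    config = config or SWDConfig()
    if not references:
        raise EmptyDatasetError("references must be non-empty")
    distances = []
    for j, ref in enumerate(references):
        res = multiscale_swd([query], [ref], config)
        distances.append((j, res.average))
    ranking = sorted(distances, key=lambda t: (t[1], t[0]))
    per_level: dict[int, float] = {}
    best = multiscale_swd([query], [references[ranking[0][0]]], config)
    return SimilarityResult(per_level=best.per_level, average=best.average,
                            ranking=ranking)
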