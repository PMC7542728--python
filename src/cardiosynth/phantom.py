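"""Synthetic cardiac phantom frames with ground-truth chamber masks.

The phantom emulates single cine frames in the two standard cardiac MR planes:

* SAX (short axis): the left ventricle appears as a bright circular blood pool
  surrounded by a darker myocardial annulus, with the right-ventricular blood
  pool as a crescent wrapping around it.
* LAX (4-chamber long axis): left ventricle, right ventricle and right atrium
  appear as adjacent elliptical blood pools separated by myocardial walls.

Tissue classes are piecewise constant (blood pool brighter than myocardium,
myocardium brighter than background) with additive Gaussian noise clipped to
[0, 1].  Geometry is stored in resolution-free units (fractions of the frame
side) so the same parameter draw can be rasterized at any power-of-two
resolution from 4 to 256.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InvalidViewError, OutputPathError, ResolutionError
from .io import (ImageFrame, PairEntry, is_power_of_two, write_frame,
                 write_manifest, write_mask)

VIEWS = ("SAX", "LAX")
VIEW_CHAMBERS = {"SAX": ("LV", "RV"), "LAX": ("LV", "RV", "RA")}

# Anatomical midpoints, in fractions of the frame side.  Centers are (row, col);
# semi-axes are (a_row, a_col).  `wall` is myocardial wall thickness.
_SAX_MID = {
    "LV": {"center": (0.52, 0.60), "semi_axes": (0.155, 0.155), "angle": 0.0,
           "wall": 0.065},
    "RV": {"center": (0.48, 0.40), "semi_axes": (0.245, 0.215), "angle": 15.0,
           "wall": 0.035},
}
_LAX_MID = {
    "LV": {"center": (0.36, 0.63), "semi_axes": (0.20, 0.145), "angle": -12.0,
           "wall": 0.055},
    "RV": {"center": (0.34, 0.345), "semi_axes": (0.185, 0.13), "angle": 10.0,
           "wall": 0.04},
    "RA": {"center": (0.70, 0.40), "semi_axes": (0.135, 0.125), "angle": 0.0,
           "wall": 0.035},
}
# Intensity model midpoints: background level plus two positive contrast gaps,
# so the ordering blood > myocardium > background holds for every draw.
_INTENSITY_MID = {"background": 0.15, "myo_gap": 0.30, "blood_gap": 0.40}
_NOISE_SD_MID = 0.03
_ANGLE_JITTER = 25.0       # deg, at variability 1
_ROTATION_JITTER = 20.0    # deg, at variability 1
_DAMP = 0.8                # relative jitter damping keeps every factor > 0


@dataclass
class PhantomParams:
    """One sampled phantom anatomy + acquisition parameter set."""

    view: str
    chamber_geometries: dict[str, dict]
    intensities: dict[str, float]      # blood_pool_mean, myocardium_mean, background_mean
    noise_sd: float
    global_rotation: float             # degrees
    seed: int

    @property
    def chambers(self) -> tuple[str, ...]:
        return tuple(self.chamber_geometries)

    def to_record(self) -> dict:
        return asdict(self)


def _relative(rng: np.random.Generator, mid: float, variability: float) -> float:
    return mid * (1.0 + _DAMP * variability * rng.uniform(-1.0, 1.0))


def make_phantom_params(view: str, rng_seed: int,
                        variability: float = 0.2) -> PhantomParams:
    """Draw phantom parameters uniformly within +-variability of the midpoints.

    Deterministic given ``rng_seed``.  ``variability`` is a fraction in [0, 1];
    zero reproduces the configured midpoints exactly.
    """
    if view not in VIEWS:
        raise InvalidViewError(f"unknown view {view!r}; expected one of {VIEWS}")
    if not 0.0 <= variability <= 1.0:
        raise ValueError(f"variability must be in [0, 1], got {variability}")
    rng = np.random.default_rng(rng_seed)
    mids = _SAX_MID if view == "SAX" else _LAX_MID

    geoms: dict[str, dict] = {}
    for chamber, mid in mids.items():
        semi = tuple(_relative(rng, s, variability) for s in mid["semi_axes"])
        wall = _relative(rng, mid["wall"], variability)
        center = tuple(_relative(rng, c, variability * 0.5) for c in mid["center"])
        angle = mid["angle"] + _ANGLE_JITTER * variability * rng.uniform(-1, 1)
        # keep the chamber (incl. wall) fully inside the frame
        reach = max(semi) + wall
        center = tuple(min(max(c, reach + 0.02), 0.98 - reach) for c in center)
        geoms[chamber] = {"center": center, "semi_axes": semi, "angle": angle,
                          "wall": wall}

    background = _relative(rng, _INTENSITY_MID["background"], variability)
    myo_gap = _relative(rng, _INTENSITY_MID["myo_gap"], variability)
    blood_gap = _relative(rng, _INTENSITY_MID["blood_gap"], variability)
    myo = background + myo_gap
    blood = min(myo + blood_gap, 0.98)
    noise_sd = _relative(rng, _NOISE_SD_MID, variability)
    noise_sd = min(noise_sd, (blood - myo) / 2.5)  # keeps contrast >= 2.5 sd
    rotation = _ROTATION_JITTER * variability * rng.uniform(-1, 1)

    return PhantomParams(
        view=view,
        chamber_geometries=geoms,
        intensities={"blood_pool_mean": blood, "myocardium_mean": myo,
                     "background_mean": background},
        noise_sd=noise_sd,
        global_rotation=rotation,
        seed=int(rng_seed),
    )


def _ellipse_mask(res: int, center: tuple[float, float],
                  semi_axes: tuple[float, float], angle_deg: float,
                  rotation_deg: float, grow: float = 0.0) -> np.ndarray:
    """Rasterize a rotated ellipse on pixel centers; sizes in frame fractions."""
    coords = (np.arange(res) + 0.5) / res
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    # global rotation about the frame center
    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        r0, c0 = rr - 0.5, cc - 0.5
        rr = 0.5 + np.cos(t) * r0 - np.sin(t) * c0
        cc = 0.5 + np.sin(t) * r0 + np.cos(t) * c0
    a = np.deg2rad(angle_deg)
    dr, dc = rr - center[0], cc - center[1]
    u = np.cos(a) * dr + np.sin(a) * dc
    v = -np.sin(a) * dr + np.cos(a) * dc
    sa, sb = semi_axes[0] + grow, semi_axes[1] + grow
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def render_phantom(params: PhantomParams,
                   resolution: int) -> tuple[ImageFrame, dict[str, np.ndarray]]:
    """Rasterize a parameter draw into a frame and per-chamber blood-pool masks.

    Masks are pairwise disjoint boolean arrays (one per chamber); the frame is
    the piecewise-constant tissue image plus clipped Gaussian noise.
    """
    if not (is_power_of_two(resolution) and 4 <= resolution <= 256):
        raise ResolutionError(
            f"resolution must be a power of two in [4, 256], got {resolution}")
    rot = params.global_rotation
    geoms = params.chamber_geometries
    inten = params.intensities

    image = np.full((resolution, resolution), inten["background_mean"])
    blood_regions: dict[str, np.ndarray] = {}
    wall_regions: dict[str, np.ndarray] = {}
    for chamber, g in geoms.items():
        wall_regions[chamber] = _ellipse_mask(
            resolution, g["center"], g["semi_axes"], g["angle"], rot,
            grow=g["wall"])
        blood_regions[chamber] = _ellipse_mask(
            resolution, g["center"], g["semi_axes"], g["angle"], rot)

    # disjoint masks: the LV (with its thicker wall) wins overlaps, then RV, RA
    order = [c for c in ("LV", "RV", "RA") if c in geoms]
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros_like(image, dtype=bool)
    for chamber in order:
        region = blood_regions[chamber] & ~claimed
        # exclude pixels under a higher-priority chamber's wall
        for prior in order[:order.index(chamber)]:
            region &= ~wall_regions[prior]
        masks[chamber] = region
        claimed |= wall_regions[chamber] | region

    # paint myocardium walls first, then blood pools exactly on the mask regions
    for chamber in geoms:
        image[wall_regions[chamber]] = inten["myocardium_mean"]
    for chamber in geoms:
        image[masks[chamber]] = inten["blood_pool_mean"]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed + 0x5EED)
        image = image + rng.normal(0.0, params.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return ImageFrame(image), masks


@dataclass
class PhantomDataset:
    """A rendered phantom dataset on disk, addressed through its manifest."""

    entries: list[PairEntry]
    manifest_path: str
    resolution: int
    view: str
    params: list[PhantomParams] = field(default_factory=list)


def generate_phantom_dataset(n: int, view: str, resolution: int, rng_seed: int,
                             out_dir: str | Path,
                             variability: float = 0.2) -> PhantomDataset:
    """Render ``n`` frame/mask pairs plus a CSV manifest into ``out_dir``.

    Per-entry seeds derive deterministically from ``rng_seed``, so the same
    call reproduces bitwise-identical files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if view not in VIEWS:
        raise InvalidViewError(f"unknown view {view!r}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OutputPathError(f"cannot write to {out_dir}: {exc}") from exc

    entry_seeds = np.random.SeedSequence(rng_seed).generate_state(n)
    entries, all_params = [], []
    stem = view.lower()
    for i, seed in enumerate(entry_seeds):
        params = make_phantom_params(view, int(seed), variability)
        frame, masks = render_phantom(params, resolution)
        frame_name = f"{stem}_{i:04d}.png"
        mask_name = f"{stem}_{i:04d}_mask.png"
        write_frame(frame, out_dir / frame_name)
        write_mask(masks, out_dir / mask_name)
        entries.append(PairEntry(frame=frame_name, mask=mask_name, view=view,
                                 seed=int(seed)))
        all_params.append(params)
    manifest = out_dir / "manifest.csv"
    write_manifest(entries, manifest)
    return PhantomDataset(entries=entries, manifest_path=str(manifest),
                          resolution=resolution, view=view, params=all_params)
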