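"""Rule-based chamber annotator for phantom-like frames.

Stands in for the manual expert annotation of frames (including generated
ones): blood pools are segmented by intensity (upper multi-Otsu threshold over
the three-tissue histogram), cleaned morphologically, and connected components
are assigned to chambers by shape and position — on the short axis the left
ventricle is the most circular bright component and the right ventricle the
largest remaining one; on the 4-chamber long axis the right atrium is the
lowest component, and of the two upper ones the left ventricle lies to the
right.  Frames whose bright components cannot be assigned are rejected
(returning None), mirroring an annotator discarding uninterpretable frames.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .io import ImageFrame
from .phantom import VIEW_CHAMBERS


def _bright_regions(arr: np.ndarray, min_area: int):
    smooth = ndimage.gaussian_filter(arr, 0.6)
    try:
        thresh = threshold_multiotsu(smooth, classes=3)[-1]
    except ValueError:          # degenerate histogram
        try:
            thresh = threshold_otsu(smooth)
        except ValueError:
            return None
    bright = smooth > thresh
    bright = ndimage.binary_opening(bright, structure=np.ones((2, 2)))
    labels = cc_label(bright)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    props.sort(key=lambda p: p.area, reverse=True)
    return labels, props


def _circularity(prop) -> float:
    per = max(prop.perimeter, 1e-6)
    return 4.0 * np.pi * prop.area / per ** 2


def annotate_frame(image: ImageFrame | np.ndarray,
                   view: str) -> dict[str, np.ndarray] | None:
    """Segment blood pools of a frame into chamber masks, or None on QC fail."""
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
    res = arr.shape[0]
    min_area = max(4, (res // 16) ** 2)
    found = _bright_regions(arr, min_area)
    if found is None:
        return None
    labels, props = found
    needed = len(VIEW_CHAMBERS[view])
    # plausibility QC: a heart-like frame has a handful of compact bright
    # pools covering a moderate fraction of the field of view
    if not needed <= len(props) <= 6:
        return None
    bright_fraction = sum(p.area for p in props) / arr.size
    if not 0.02 <= bright_fraction <= 0.45:
        return None
    if max(_circularity(p) for p in props[:3]) < 0.55:
        return None
    if view == "SAX":
        top = props[:3]
        lv = max(top, key=_circularity)
        rest = [p for p in top if p is not lv]
        rv = rest[0]            # largest remaining
        assign = {"LV": lv, "RV": rv}
    else:                       # LAX
        top = props[:4]
        ra = max(top, key=lambda p: p.centroid[0])      # lowest in the frame
        upper = sorted((p for p in top if p is not ra),
                       key=lambda p: p.area, reverse=True)[:2]
        if len(upper) < 2:
            return None
        lv = max(upper, key=lambda p: p.centroid[1])    # right of the pair
        rv = min(upper, key=lambda p: p.centroid[1])
        if lv is rv:
            return None
        assign = {"LV": lv, "RV": rv, "RA": ra}
    masks = {}
    used = set()
    for chamber, prop in assign.items():
        if prop.label in used:
            return None
        used.add(prop.label)
        masks[chamber] = labels == prop.label
    return masks


def annotate_frames(frames: list, view: str) -> list:
    """Annotate a batch; returns (frame, masks) pairs for frames that pass QC."""
    pairs = []
    for f in frames:
        masks = annotate_frame(f, view)
        if masks is not None:
            pairs.append((f, masks))
    return pairs
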