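"""Debris identification and exclusion.

Straw fragments and clothing lint fluoresce and can be mistaken for roots
where they are linear.  Their distinguishing feature is thickness: debris
is thicker than any root.  The stages are:

1. ``open_thick`` — grey-level morphological opening with a polygonal
   (octagonal) structuring element whose radius is the maximum root
   radius: bright objects thinner than any debris (i.e. the roots) are
   removed, thick bright objects survive.
2. ``build_background`` — connected-component attribute filtering of the
   opened image: compact objects (elongation below the limit) and very
   large regions (area above a fraction of the well area) are kept as part
   of the background; elongated moderate-size objects — the debris
   candidates — are excluded from it.
3. ``debris_mask`` — the 'background removed' image (opened minus
   background, floored at zero) thresholded at a fixed grey level (50).
4. ``exclude_debris`` — set difference removing debris pixels from the
   linear-structures mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.morphology import octagon

from .params import PipelineParams

__all__ = ["DebrisMasks", "open_thick", "build_background", "debris_mask",
           "exclude_debris", "find_debris", "octagon_footprint"]


@dataclass
class DebrisMasks:
    """Intermediate rasters of the debris-exclusion stage."""

    opened: np.ndarray
    background: np.ndarray
    background_removed: np.ndarray
    debris_mask: np.ndarray
    debris_excluded_roots: np.ndarray | None = None


def octagon_footprint(radius: int) -> np.ndarray:
    """Octagonal approximation of a disc with the given circumradius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n = max(1, int(round(radius * 0.414)))     # diagonal truncation
    m = max(1, 2 * radius + 1 - 2 * n)         # total width = m + 2n = 2r+1
    return octagon(m, n)


def open_thick(blue_ds: np.ndarray, params: PipelineParams) -> np.ndarray:
    """Grey-level opening removing bright structures thinner than debris.

    A circle-like polygon of radius ``max_root_radius_px`` must fit inside
    a bright object for it to survive; roots are thinner and are erased.
    """
    footprint = octagon_footprint(params.max_root_radius_px)
    return ndimage.grey_opening(np.asarray(blue_ds, dtype=float),
                                footprint=footprint)


def build_background(opened: np.ndarray, well_area_px: float,
                     params: PipelineParams) -> np.ndarray:
    """Background of the opened image: everything except debris candidates.

    Bright objects are found above the estimated background level; a
    component stays in the background when its elongation (major/minor
    axis ratio) is below ``debris_elongation_max`` OR its area exceeds
    ``debris_area_fraction x well_area_px``.  Elongated moderate-size
    components — the debris candidates — are excluded: their pixels are
    replaced by the background level, so they alone survive the subsequent
    subtraction.
    """
    opened = np.asarray(opened, dtype=float)
    bg_level = float(np.median(opened))
    objects = opened > bg_level + params.background_object_delta
    lab, _ = ndimage.label(objects, structure=np.ones((3, 3), dtype=int))
    candidate = np.zeros_like(objects)
    for rp in skmeasure.regionprops(lab):
        minor = rp.axis_minor_length
        elong = rp.axis_major_length / minor if minor > 0 else np.inf
        compact = elong < params.debris_elongation_max
        huge = rp.area > params.debris_area_fraction * well_area_px
        if not (compact or huge):
            candidate[lab == rp.label] = True
    return np.where(candidate, bg_level, opened)


def debris_mask(opened: np.ndarray, background: np.ndarray,
                params: PipelineParams) -> np.ndarray:
    """Threshold the 'background removed' image at the debris grey level.

    The difference is floored at zero before thresholding (only pixels
    brighter than the background can be debris).
    """
    opened = np.asarray(opened, dtype=float)
    background = np.asarray(background, dtype=float)
    if opened.shape != background.shape:
        raise ValueError("opened and background images differ in shape")
    removed = np.clip(opened - background, 0.0, None)
    return removed > params.debris_threshold


def exclude_debris(linear: np.ndarray, debris: np.ndarray) -> np.ndarray:
    """Remove debris pixels from the linear-structures mask (set difference)."""
    if linear.shape != debris.shape:
        raise ValueError("mask shapes differ")
    return linear & ~debris


def find_debris(blue_ds: np.ndarray, linear: np.ndarray, well_area_px: float,
                params: PipelineParams) -> DebrisMasks:
    """Run the full debris stage and attach the debris-excluded roots.

    Before exclusion the debris mask is dilated by ``debris_dilate_px``:
    the line detector smooths at a scale of a few pixels, so the ridge it
    traces along a debris edge can fall just outside the exact thickness
    mask; a margin of the detector scale removes those edge ridges too.
    """
    from skimage.morphology import dilation, disk

    opened = open_thick(blue_ds, params)
    background = build_background(opened, well_area_px, params)
    removed = np.clip(opened - background, 0.0, None)
    mask = removed > params.debris_threshold
    excl = mask
    if params.debris_dilate_px > 0 and mask.any():
        excl = dilation(mask, disk(params.debris_dilate_px))
    return DebrisMasks(opened=opened, background=background,
                       background_removed=removed, debris_mask=mask,
                       debris_excluded_roots=exclude_debris(linear, excl))
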