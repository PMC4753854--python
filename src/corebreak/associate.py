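"""Association of detected roots with cassette wells.

The measurement of interest is per well (per core face): roots that
originate inside a well are kept — including any portion extending beyond
the well boundary, since core breaking leaves roots protruding past the
well rim — while isolated fragments lying between wells are ignored.

Steps: intersect the debris-excluded root mask with the union of well
discs ('roots within wells'), recover the full extent of every component
that touches a well by morphological reconstruction (seeds grown inside
the original mask), then label each component by the well it belongs to
(majority pixel overlap, ties to the lower well label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .wells import WellMap

__all__ = ["RootComponent", "LabelledRoots", "mask_by_wells",
           "reconstruct_roots", "label_by_well"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class RootComponent:
    """One connected root object assigned to a well."""

    well: int
    pixel_count: int
    pixels: tuple[np.ndarray, np.ndarray]    # (rows, cols) index arrays


@dataclass
class LabelledRoots:
    """Connected root components labelled by their well."""

    label_image: np.ndarray                  # 0 = none, k = pixels of well k
    components: list[RootComponent]

    def components_in_well(self, well: int) -> list[RootComponent]:
        return [c for c in self.components if c.well == well]


def mask_by_wells(roots: np.ndarray, wells: WellMap) -> np.ndarray:
    """Intersect the root mask with the union of well discs.

    Drops isolated roots between wells entirely and truncates roots that
    extend beyond a well rim (their outer part is recovered later by
    reconstruction).
    """
    if roots.shape != wells.label_image.shape:
        raise ValueError("root mask and well map shapes differ")
    return roots & wells.well_mask()


def reconstruct_roots(seeds: np.ndarray, full: np.ndarray) -> np.ndarray:
    """Morphological reconstruction of ``seeds`` inside ``full``.

    Returns the union of the connected components of ``full`` that
    intersect ``seeds`` — i.e. the seeds dilated without bound but
    constrained to ``full`` (binary reconstruction by dilation).
    """
    if seeds.shape != full.shape:
        raise ValueError("mask shapes differ")
    if np.any(seeds & ~full):
        raise ValueError("seeds must be a subset of the containing mask")
    lab, n = ndimage.label(full, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(full)
    hit = np.unique(lab[seeds])
    hit = hit[hit > 0]
    return np.isin(lab, hit)


def label_by_well(reconstructed: np.ndarray, wells: WellMap) -> LabelledRoots:
    """Assign each connected component to the well it shares most pixels
    with; ties break to the lower well label.

    Components are guaranteed to touch at least one well after
    reconstruction from well-masked seeds; a component with no overlap
    indicates an upstream inconsistency and raises.
    """
    if reconstructed.shape != wells.label_image.shape:
        raise ValueError("mask and well map shapes differ")
    lab, n = ndimage.label(reconstructed, structure=_EIGHT)
    label_image = np.zeros_like(wells.label_image)
    components: list[RootComponent] = []
    for comp_id in range(1, n + 1):
        comp = lab == comp_id
        overlap = wells.label_image[comp]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            raise RuntimeError(
                "component intersects no well disc; reconstruction seeds "
                "were not derived from the well mask")
        wlabels, counts = np.unique(overlap, return_counts=True)
        # argmax keeps the first (lowest) label on ties
        well = int(wlabels[np.argmax(counts)])
        label_image[comp] = well
        rows, cols = np.nonzero(comp)
        components.append(RootComponent(well=well, pixel_count=int(comp.sum()),
                                        pixels=(rows, cols)))
    return LabelledRoots(label_image=label_image, components=components)
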