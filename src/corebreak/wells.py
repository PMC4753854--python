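"""Well segmentation from the daily template image.

The cores themselves have unpredictable contrast against the cassette, so
well positions are segmented once per session from a high-contrast template
imaged in the same position as the cassette.  The stages are: blue-channel
extraction and 2x block-average downsampling, median filtering,
attribute-based background suppression (keep near-circular components of
plausible well area, flatten everything else), automatic global
thresholding on a grey-level/gradient bivariate histogram, then per-
component circle fitting (centroid + semi-major axis of the moment ellipse)
and raster-order labelling 1..40.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage import filters, measure as skmeasure

from .params import PipelineParams

__all__ = [
    "WellCircle",
    "WellMap",
    "preprocess_template",
    "suppress_background",
    "threshold_bivariate",
    "fit_well_circles",
    "find_wells",
    "NoThresholdError",
]


class NoThresholdError(ValueError):
    """The image has no grey-level structure to threshold."""


class ChannelError(ValueError):
    """Input image does not have three colour channels."""


@dataclass(frozen=True)
class WellCircle:
    label: int                       # 1..40 raster order
    centre_px: tuple[float, float]   # (x, y), downsampled coordinates
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")


@dataclass
class WellMap:
    """The fitted well circles plus their rasterised label image."""

    circles: list[WellCircle]
    label_image: np.ndarray          # 0 = background, k = well k
    source_shape: tuple[int, int]    # (height, width) of the downsampled frame

    @property
    def n_wells(self) -> int:
        return len(self.circles)

    @property
    def mean_radius_px(self) -> float:
        return float(np.mean([c.radius_px for c in self.circles]))

    def well_mask(self) -> np.ndarray:
        return self.label_image > 0

    def well_area_px(self) -> float:
        """Mean rasterised disc area, used for the debris area criterion."""
        labels, counts = np.unique(self.label_image[self.label_image > 0],
                                   return_counts=True)
        if labels.size == 0:
            raise ValueError("well map has no wells")
        return float(counts.mean())

    # ------------------------------------------------------------- I/O
    def to_yaml(self, path: str | Path) -> None:
        d = {
            "source_shape": list(self.source_shape),
            "circles": [
                {"label": c.label, "centre_px": list(c.centre_px),
                 "radius_px": float(c.radius_px)}
                for c in self.circles
            ],
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WellMap":
        d = yaml.safe_load(Path(path).read_text())
        circles = [WellCircle(label=c["label"],
                              centre_px=tuple(c["centre_px"]),
                              radius_px=c["radius_px"])
                   for c in d["circles"]]
        shape = tuple(d["source_shape"])
        return cls(circles=circles,
                   label_image=rasterize_circles(circles, shape),
                   source_shape=shape)


def rasterize_circles(circles: list[WellCircle],
                      shape: tuple[int, int]) -> np.ndarray:
    """Integer label raster of the well discs (later labels never overwrite
    earlier ones; discs are disjoint for any valid cassette)."""
    out = np.zeros(shape, dtype=np.int32)
    for c in circles:
        cx, cy = c.centre_px
        r = c.radius_px
        x0, x1 = max(0, int(cx - r - 1)), min(shape[1], int(cx + r + 2))
        y0, y1 = max(0, int(cy - r - 1)), min(shape[0], int(cy + r + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        region = out[y0:y1, x0:x1]
        region[disc & (region == 0)] = c.label
    return out


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def downsample_block_mean(channel: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a 2-D array by ``factor`` (trailing rows/cols cropped)."""
    if factor == 1:
        return channel.astype(float)
    h, w = channel.shape
    h2, w2 = h - h % factor, w - w % factor
    blocks = channel[:h2, :w2].astype(float).reshape(
        h2 // factor, factor, w2 // factor, factor)
    return blocks.mean(axis=(1, 3))


def preprocess_template(image: np.ndarray, params: PipelineParams) -> np.ndarray:
    """Blue channel, block-averaged by the downsampling factor, median
    filtered (the blue channel carries the template/well contrast)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelError("expected an RGB image with 3 channels")
    blue = downsample_block_mean(image[..., 2], params.downsample_factor)
    size = 2 * params.median_radius_px + 1
    return ndimage.median_filter(blue, size=size)


# --------------------------------------------------------------------------
# background suppression (attribute filtering)
# --------------------------------------------------------------------------

def _component_attributes(mask: np.ndarray) -> list[tuple[np.ndarray, float, float]]:
    """(component mask slice info) -> list of (labels slice, area, elongation).

    Elongation is the semi-major/semi-minor axis ratio of the moment-based
    best-fit ellipse (1 for a circle).
    """
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out = []
    for rp in skmeasure.regionprops(lab):
        minor = rp.axis_minor_length
        elong = rp.axis_major_length / minor if minor > 0 else np.inf
        out.append((lab == rp.label, float(rp.area), float(elong)))
    return out


def suppress_background(grey: np.ndarray, params: PipelineParams) -> np.ndarray:
    """Retain bright near-circular components of plausible well area;
    flatten all other bright structure to the background level.

    This is a connected-component (attribute) filter: retained components
    keep their original grey values unchanged (contour preserving); every
    other pixel is set to the background level, estimated as the median of
    the non-retained area.  Applying the filter twice gives the same result
    as applying it once.
    """
    grey = np.asarray(grey, dtype=float)
    if np.ptp(grey) == 0:
        return grey.copy()
    thr = filters.threshold_otsu(grey)
    bright = grey > thr
    area_lo, area_hi = params.well_area_range_px
    keep = np.zeros_like(bright)
    for comp, area, elong in _component_attributes(bright):
        if elong < params.well_elongation_max and area_lo <= area <= area_hi:
            keep |= comp
    bg_level = float(np.median(grey[~keep])) if (~keep).any() else 0.0
    out = np.where(keep, grey, bg_level)
    return out


# --------------------------------------------------------------------------
# bivariate-histogram thresholding
# --------------------------------------------------------------------------

def threshold_bivariate(grey: np.ndarray) -> np.ndarray:
    """Binary well mask by automatic global thresholding.

    The threshold is chosen from the joint distribution of grey level and
    gradient magnitude: the grey-level histogram is restricted to pixels
    whose gradient magnitude is below its median (interior pixels of the
    two modes, away from blurred edges), then a two-class
    variance-maximising split is applied to those pixels.  This makes the
    threshold insensitive to the edge-blur pixels that bias a plain
    histogram split.
    """
    grey = np.asarray(grey, dtype=float)
    if np.ptp(grey) == 0:
        raise NoThresholdError("constant image: no threshold exists")
    grad = ndimage.sobel(grey, axis=0) ** 2 + ndimage.sobel(grey, axis=1) ** 2
    low_grad = grad <= np.median(grad)
    sample = grey[low_grad]
    if np.ptp(sample) == 0:
        sample = grey.ravel()
    thr = filters.threshold_otsu(sample)
    return grey > thr


# --------------------------------------------------------------------------
# circle fitting and raster labelling
# --------------------------------------------------------------------------

def _raster_order(centres: np.ndarray, row_tol: float) -> np.ndarray:
    """Indices sorting centres top-left to bottom-right, clustering rows
    by y within ``row_tol`` so small vertical jitter cannot scramble the
    ordering."""
    order = np.argsort(centres[:, 1], kind="stable")
    rows: list[list[int]] = []
    row_y = None
    for idx in order:
        y = centres[idx, 1]
        if row_y is None or y - row_y > row_tol:
            rows.append([idx])
            row_y = y
        else:
            rows[-1].append(idx)
            # running mean keeps the row anchor stable under jitter
            row_y = float(np.mean([centres[i, 1] for i in rows[-1]]))
    out = []
    for row in rows:
        out.extend(sorted(row, key=lambda i: centres[i, 0]))
    return np.array(out, dtype=int)


def fit_well_circles(mask: np.ndarray, params: PipelineParams) -> WellMap:
    """Fit a circle to each well component and label in raster order.

    The circle centre is the component centroid; its radius is the
    semi-major axis of the moment-based best-fit ellipse, which restores a
    circular model for wells rendered slightly elliptical by edge flare.
    A component count different from ``params.expected_wells`` is reported
    as a warning but processing continues.
    """
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no connected components in the well mask")
    props = skmeasure.regionprops(lab)
    centres = np.array([[p.centroid[1], p.centroid[0]] for p in props])
    radii = np.array([p.axis_major_length / 2.0 for p in props])
    if n != params.expected_wells:
        warnings.warn(
            f"found {n} well components, expected {params.expected_wells}",
            stacklevel=2)
    order = _raster_order(centres, row_tol=float(np.median(radii)))
    circles = [
        WellCircle(label=i + 1,
                   centre_px=(float(centres[j, 0]), float(centres[j, 1])),
                   radius_px=float(radii[j]))
        for i, j in enumerate(order)
    ]
    return WellMap(circles=circles,
                   label_image=rasterize_circles(circles, mask.shape),
                   source_shape=mask.shape)


def find_wells(template_rgb: np.ndarray, params: PipelineParams) -> WellMap:
    """Full template stage: preprocess, suppress background, threshold,
    fit circles, label in raster order."""
    grey = preprocess_template(template_rgb, params)
    suppressed = suppress_background(grey, params)
    mask = threshold_bivariate(suppressed)
    return fit_well_circles(mask, params)
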