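"""Root filtering and per-well measurement output.

Labelled root components are filtered on length (longer than a minimum),
hue (must be blue — roots fluoresce blue under 365 nm excitation) and
lightness (brighter than a minimum), then counted and measured per well.
Overlapping or crossing roots form a single connected component and are
deliberately counted as one object; separating them is beyond this
detector.  Results are written as CSV with one row per well:
``Dim,Core,RootNumber,RootLength``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .associate import LabelledRoots, RootComponent
from .params import PipelineParams
from .wells import WellMap

__all__ = ["RootRecord", "WellRow", "CassetteMeasurement", "filter_roots",
           "measure_wells", "length_mm", "areal_density", "write_csv",
           "read_csv", "component_length_px"]

SQRT2 = math.sqrt(2.0)


def component_length_px(pixels: tuple[np.ndarray, np.ndarray]) -> float:
    """Arc length of a centreline component in pixels.

    The component's pixels are connected into a minimum-spanning tree
    over the 8-adjacency graph (axial steps weigh 1, diagonal steps
    sqrt(2)), which discards the phantom diagonal links that raw
    link-counting picks up at staircase corners.  The tree is decomposed
    into simple chains between endpoints and branch points; each chain is
    resampled every few pixels and its Euclidean polyline length summed,
    which removes the upward digitisation bias of stepwise chain codes.
    A single isolated pixel counts as length 1.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import minimum_spanning_tree

    rows, cols = pixels
    n = rows.size
    if n <= 1:
        return 1.0
    r0, c0 = rows.min(), cols.min()
    h = rows.max() - r0 + 1
    w = cols.max() - c0 + 1
    idx = -np.ones((h, w), dtype=np.int64)
    idx[rows - r0, cols - c0] = np.arange(n)
    src, dst, wgt = [], [], []
    for dr, dc, weight in ((0, 1, 1.0), (1, 0, 1.0),
                           (1, 1, SQRT2), (1, -1, SQRT2)):
        rr, cc = rows - r0 + dr, cols - c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        nb = np.full(n, -1, dtype=np.int64)
        nb[ok] = idx[rr[ok], cc[ok]]
        has = nb >= 0
        src.append(np.arange(n)[has])
        dst.append(nb[has])
        wgt.append(np.full(int(has.sum()), weight))
    graph = coo_matrix((np.concatenate(wgt),
                        (np.concatenate(src), np.concatenate(dst))),
                       shape=(n, n))
    mst = minimum_spanning_tree(graph).tocoo()

    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in zip(mst.row, mst.col):
        adj[a].append(b)
        adj[b].append(a)
    degree = np.array([len(a) for a in adj])
    coords = np.column_stack([rows.astype(float), cols.astype(float)])

    def _chain_length(path: list[int], stride: int = 4) -> float:
        pts = coords[path]
        keep = list(range(0, len(pts) - 1, stride)) + [len(pts) - 1]
        p = pts[keep]
        return float(np.hypot(*(np.diff(p, axis=0).T)).sum())

    total = 0.0
    visited = set()
    starts = np.nonzero(degree != 2)[0]
    if starts.size == 0:             # degenerate: pure 2-regular chain
        starts = np.array([0])
    for s in starts:
        for nb0 in adj[s]:
            if (s, nb0) in visited:
                continue
            path = [int(s), int(nb0)]
            visited.add((s, nb0))
            visited.add((nb0, s))
            while degree[path[-1]] == 2:
                nxt = [x for x in adj[path[-1]] if x != path[-2]]
                if not nxt:
                    break
                visited.add((path[-1], nxt[0]))
                visited.add((nxt[0], path[-1]))
                path.append(int(nxt[0]))
            total += _chain_length(path)
    return max(total, 1.0)


@dataclass(frozen=True)
class RootRecord:
    """Colour and geometry summary of one labelled root component."""

    well: int
    pixel_count: int
    mean_hue_deg: float
    mean_lightness: float            # 0-255, HSL lightness
    length_px: float


def _colour_summary(comp: RootComponent, rgb_ds: np.ndarray) -> tuple[float, float]:
    rows, cols = comp.pixels
    px = rgb_ds[rows, cols, :].astype(float) / 255.0
    hsv = rgb2hsv(px[None, :, :])[0]
    ang = hsv[:, 0] * 2.0 * math.pi
    mean_hue = math.degrees(math.atan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    lightness = 255.0 * (px.max(axis=1) + px.min(axis=1)) / 2.0
    return mean_hue, float(lightness.mean())


def root_record(comp: RootComponent, rgb_ds: np.ndarray) -> RootRecord:
    hue, light = _colour_summary(comp, rgb_ds)
    return RootRecord(well=comp.well, pixel_count=comp.pixel_count,
                      mean_hue_deg=hue, mean_lightness=light,
                      length_px=component_length_px(comp.pixels))


def _hue_in_range(hue: float, lo: float, hi: float) -> bool:
    if lo <= hi:
        return lo <= hue <= hi
    return hue >= lo or hue <= hi     # range wraps through 0


def filter_roots(labelled: LabelledRoots, rgb_ds: np.ndarray,
                 params: PipelineParams) -> LabelledRoots:
    """Keep components that are long, blue, and bright.

    A component survives when its length strictly exceeds
    ``min_root_length_px``, its (circular) mean hue lies within
    ``blue_hue_range_deg`` and its mean HSL lightness strictly exceeds
    ``min_lightness``.
    """
    lo, hi = params.blue_hue_range_deg
    kept: list[RootComponent] = []
    label_image = np.zeros_like(labelled.label_image)
    for comp in labelled.components:
        rec = root_record(comp, rgb_ds)
        if (rec.length_px > params.min_root_length_px
                and _hue_in_range(rec.mean_hue_deg, lo, hi)
                and rec.mean_lightness > params.min_lightness):
            kept.append(comp)
            label_image[comp.pixels] = comp.well
    return LabelledRoots(label_image=label_image, components=kept)


@dataclass(frozen=True)
class WellRow:
    core: int                        # well label, raster order 1..40
    root_number: int
    root_length: float               # total length, downsampled pixels


@dataclass
class CassetteMeasurement:
    """Per-well measurement of one cassette face image."""

    dim: int                         # 1 if the frame was under-exposed
    rows: list[WellRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.root_number == 0 and row.root_length != 0:
                raise ValueError("a well with zero roots must have zero length")

    def root_number(self, well: int) -> int:
        return self._row(well).root_number

    def root_length(self, well: int) -> float:
        return self._row(well).root_length

    def _row(self, well: int) -> WellRow:
        for row in self.rows:
            if row.core == well:
                return row
        raise KeyError(f"no well {well}")

    def total_roots(self) -> int:
        return sum(r.root_number for r in self.rows)

    def total_length(self) -> float:
        return sum(r.root_length for r in self.rows)


def measure_wells(filtered: LabelledRoots, wells: WellMap,
                  dim: bool) -> CassetteMeasurement:
    """Count components and sum lengths per well, one row per well label.

    Crossing or touching roots merge into one connected component and are
    counted once; empty wells report (0, 0).
    """
    counts = {c.label: 0 for c in wells.circles}
    lengths = {c.label: 0.0 for c in wells.circles}
    for comp in filtered.components:
        counts[comp.well] += 1
        lengths[comp.well] += component_length_px(comp.pixels)
    rows = [WellRow(core=label, root_number=counts[label],
                    root_length=lengths[label] if counts[label] else 0.0)
            for label in sorted(counts)]
    return CassetteMeasurement(dim=int(dim), rows=rows)


# --------------------------------------------------------------------------
# unit conversions
# --------------------------------------------------------------------------

def length_mm(length_px: float, params: PipelineParams) -> float:
    """Convert a length in downsampled pixels to millimetres."""
    if params.px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    return length_px / (params.px_per_mm / params.downsample_factor)


def areal_density(px_per_mm: float) -> float:
    """Pixels per mm^2 at the sensor's native resolution (13 px/mm -> 169)."""
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    return px_per_mm ** 2


# --------------------------------------------------------------------------
# CSV output
# --------------------------------------------------------------------------

CSV_HEADER = ["Dim", "Core", "RootNumber", "RootLength"]


def write_csv(measurement: CassetteMeasurement, path: str | Path) -> None:
    """One row per well, ordered by well label, fixed header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for row in sorted(measurement.rows, key=lambda r: r.core):
            writer.writerow([measurement.dim, row.core, row.root_number,
                             repr(row.root_length)])


def read_csv(path: str | Path) -> CassetteMeasurement:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != CSV_HEADER:
            raise ValueError(f"unexpected header {header!r}")
        rows, dims = [], set()
        for dim, core, num, length in reader:
            dims.add(int(dim))
            rows.append(WellRow(core=int(core), root_number=int(num),
                                root_length=float(length)))
    if len(dims) != 1:
        raise ValueError("inconsistent Dim column")
    return CassetteMeasurement(dim=dims.pop(), rows=rows)
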