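"""Synthetic cassette scenes with pixel-level ground truth.

Fluorescence imaging of soil-core break faces produces dark, low-chroma
soil backgrounds crossed by bright blue curvilinear roots, occasionally
contaminated by thick fluorescent debris (straw, lint).  No public image
set exists for this instrument class, so this module generates cassette
template images and fluorescence scenes with known ground truth (root
polylines, debris regions, well layout) against which every downstream
stage of the pipeline can be validated.

Conventions
-----------
* Coordinates are ``(x, y)`` in pixels of the *generated* image; the
  analysis pipeline later downsamples by ``PipelineParams.downsample_factor``.
* Roots are rendered with a transverse intensity profile that is strictly
  maximal at the centreline (a smooth quadratic bump), so a unique
  ridgeline exists for the line detector to find.
* Debris is rendered as thick capsules whose minimum width exceeds twice
  the maximum root radius assumed by the debris-exclusion stage.
* All randomness flows through :func:`numpy.random.default_rng`; identical
  seeds and parameters reproduce identical scenes byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree

from .calibrate import CoreProfile, FaceCount

__all__ = [
    "CassetteLayout",
    "GroundTruthRoot",
    "GroundTruthDebris",
    "SyntheticScene",
    "generate_template",
    "generate_scene",
    "random_scene",
    "generate_calibration_dataset",
    "CalibrationDataset",
]


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------

class InvalidLayoutError(ValueError):
    """Raised when wells overlap or extend beyond the image bounds."""


@dataclass(frozen=True)
class CassetteLayout:
    """Geometry of the 40-well imaging cassette in generated-image pixels.

    The default is a 5-column by 8-row grid (40 wells, matching the
    physical cassette) labelled in raster order, top-left to bottom-right,
    at the instrument's working resolution of ~13 px/mm: 45 mm (580 px)
    well diameter in an 18-megapixel portrait frame.  Smaller test scenes
    are obtained with :meth:`scaled` / :meth:`default`.
    """

    rows: int = 8
    cols: int = 5
    well_radius_px: float = 290.0
    pitch_px: float = 640.0
    origin_px: tuple[float, float] = (448.0, 352.0)
    image_size_px: tuple[int, int] = (3456, 5184)  # (width, height)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise InvalidLayoutError("need at least one row and one column")
        if self.pitch_px <= 2 * self.well_radius_px:
            raise InvalidLayoutError("wells overlap: pitch must exceed the diameter")
        w, h = self.image_size_px
        r = self.well_radius_px
        for cx, cy in self.well_centres():
            if not (r <= cx <= w - r and r <= cy <= h - r):
                raise InvalidLayoutError("well extends beyond image bounds")

    def well_centres(self) -> np.ndarray:
        """``(n_wells, 2)`` array of (x, y) centres in raster order."""
        ox, oy = self.origin_px
        xs = ox + self.pitch_px * np.arange(self.cols)
        ys = oy + self.pitch_px * np.arange(self.rows)
        gx, gy = np.meshgrid(xs, ys)  # row-major => raster order
        return np.column_stack([gx.ravel(), gy.ravel()])

    def scaled(self, factor: float) -> "CassetteLayout":
        """Layout with every length multiplied by ``factor``.

        Useful both to build smaller scenes and to express this layout in
        the downsampled coordinates of the analysis pipeline
        (``factor = 1 / downsample_factor``).
        """
        w, h = self.image_size_px
        return replace(
            self,
            well_radius_px=self.well_radius_px * factor,
            pitch_px=self.pitch_px * factor,
            origin_px=(self.origin_px[0] * factor, self.origin_px[1] * factor),
            image_size_px=(int(round(w * factor)), int(round(h * factor))),
        )

    @classmethod
    def default(cls, scale: float = 1.0) -> "CassetteLayout":
        return cls() if scale == 1.0 else cls().scaled(scale)


# --------------------------------------------------------------------------
# ground-truth records
# --------------------------------------------------------------------------

@dataclass
class GroundTruthRoot:
    """One rendered root stroke.

    ``well_index`` is the 1-based raster label of the well the root was
    placed in, or ``None`` for an isolated root lying between wells.
    """

    polyline: np.ndarray           # (N, 2) float (x, y)
    width_px: float
    hue_deg: float = 235.0
    peak_intensity: float = 200.0
    well_index: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (N, 2) array")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def arc_length_px(self) -> float:
        d = np.diff(self.polyline, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class GroundTruthDebris:
    """A thick fluorescent contaminant (straw fragment, lint strip).

    Modelled as a capsule around a spine polyline; ``min_width_px`` is the
    full cross-sectional width.  Debris must be thicker than any root:
    callers pairing a scene with pipeline parameters should keep
    ``min_width_px > 2 * downsample_factor * max_root_radius_px``.
    """

    polyline: np.ndarray           # (N, 2) spine
    min_width_px: float
    intensity: float = 230.0
    hue_deg: float = 230.0

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)

    @property
    def region(self) -> dict:
        return {
            "kind": "capsule",
            "spine": self.polyline.tolist(),
            "width": self.min_width_px,
        }


@dataclass
class SyntheticScene:
    image: np.ndarray              # (H, W, 3) uint8
    layout: CassetteLayout
    roots: list[GroundTruthRoot]
    debris: list[GroundTruthDebris]
    noise_sd: float
    seed: int
    dim: bool = False

    def roots_in_well(self, well_index: int) -> list[GroundTruthRoot]:
        return [r for r in self.roots if r.well_index == well_index]

    # ------------------------------------------------------------- export
    def save(self, image_path: str | Path, sidecar_path: str | Path | None = None,
             jpeg_quality: int = 95) -> None:
        """Write the scene as PNG (or JPEG by extension) plus a JSON sidecar."""
        image_path = Path(image_path)
        img = Image.fromarray(self.image)
        if image_path.suffix.lower() in (".jpg", ".jpeg"):
            img.save(image_path, quality=jpeg_quality)
        else:
            img.save(image_path)
        if sidecar_path is None:
            sidecar_path = image_path.with_suffix(".truth.json")
        truth = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "dim": self.dim,
            "layout": {
                "rows": self.layout.rows,
                "cols": self.layout.cols,
                "well_radius_px": self.layout.well_radius_px,
                "pitch_px": self.layout.pitch_px,
                "origin_px": list(self.layout.origin_px),
                "image_size_px": list(self.layout.image_size_px),
            },
            "roots": [
                {
                    "well_index": r.well_index,
                    "polyline": r.polyline.tolist(),
                    "width_px": r.width_px,
                    "hue_deg": r.hue_deg,
                    "peak_intensity": r.peak_intensity,
                    "arc_length_px": r.arc_length_px,
                    "clipped": r.clipped,
                }
                for r in self.roots
            ],
            "debris": [d.region | {"intensity": d.intensity} for d in self.debris],
        }
        Path(sidecar_path).write_text(json.dumps(truth, indent=1))


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------

def _hue_to_rgb(hue_deg: float) -> np.ndarray:
    """Unit RGB of a fully saturated colour at the given hue."""
    import colorsys

    return np.array(colorsys.hls_to_rgb((hue_deg % 360.0) / 360.0, 0.5, 1.0))


def _densify(polyline: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly ``step``-pixel spacing."""
    pts = [polyline[0]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = np.hypot(*(b - a))
        n = max(1, int(math.ceil(seg / step)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def _render_stroke(canvas: np.ndarray, polyline: np.ndarray, width_px: float,
                   rgb_peak: np.ndarray, profile: str = "bump") -> None:
    """Max-composite a stroke onto a float RGB canvas.

    ``bump``: transverse intensity ``1 - (d/r)^2`` — strictly maximal at the
    centreline, used for roots; drawn with butt caps so the rendered extent
    equals the polyline arc length.  ``dome``: flat-topped
    ``0.8 + 0.2(1-(d/r)^2)`` with an anti-aliased rim, used for debris
    (bright enough across its whole width for a thickness-based opening to
    retain it).
    """
    h, w = canvas.shape[:2]
    r = width_px / 2.0
    pts = _densify(polyline)
    x0 = max(0, int(np.floor(pts[:, 0].min() - r - 2)))
    x1 = min(w, int(np.ceil(pts[:, 0].max() + r + 3)))
    y0 = max(0, int(np.floor(pts[:, 1].min() - r - 2)))
    y1 = min(h, int(np.ceil(pts[:, 1].max() + r + 3)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    dist, nearest = cKDTree(pts).query(grid, workers=1)
    dist = dist.reshape(yy.shape)
    if profile == "bump":
        f = np.clip(1.0 - (dist / (r + 0.5)) ** 2, 0.0, 1.0)
        if len(pts) > 1:             # butt caps: cut beyond the end planes
            nearest = nearest.reshape(yy.shape)
            for end, tangent in ((0, pts[0] - pts[1]),
                                 (len(pts) - 1, pts[-1] - pts[-2])):
                tn = tangent / max(np.hypot(*tangent), 1e-9)
                vec_x = xx - pts[end][0]
                vec_y = yy - pts[end][1]
                outward = vec_x * tn[0] + vec_y * tn[1] > 0.5
                f[(nearest == end) & outward] = 0.0
    elif profile == "dome":
        core = 0.8 + 0.2 * np.clip(1.0 - (dist / (r + 0.5)) ** 2, 0.0, 1.0)
        rim = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        f = core * rim
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown profile {profile!r}")
    patch = f[..., None] * rgb_peak[None, None, :]
    region = canvas[y0:y1, x0:x1]
    np.maximum(region, patch, out=region)


def _clip_polyline(polyline: np.ndarray, size: tuple[int, int]) -> tuple[np.ndarray, bool]:
    w, h = size
    clipped = bool(
        (polyline[:, 0] < 0).any() or (polyline[:, 0] > w - 1).any()
        or (polyline[:, 1] < 0).any() or (polyline[:, 1] > h - 1).any()
    )
    out = polyline.copy()
    out[:, 0] = np.clip(out[:, 0], 0, w - 1)
    out[:, 1] = np.clip(out[:, 1], 0, h - 1)
    return out, clipped


# --------------------------------------------------------------------------
# template generator
# --------------------------------------------------------------------------

def generate_template(layout: CassetteLayout, seed: int = 0, *,
                      jitter_px: float = 0.0, flare: float = 0.0,
                      body_level: int = 30, well_level: int = 220,
                      noise_sd: float = 2.0,
                      return_centres: bool = False):
    """Render the high-contrast well template as an RGB image.

    The template body is dark and the 40 wells are bright discs (contrast
    carried by the blue channel, as in the instrument).  ``jitter_px``
    perturbs each well centre uniformly; ``flare`` adds a mild radial
    brightening toward the image border, emulating the lens flare that
    makes real well regions slightly non-circular.  With
    ``return_centres=True`` also returns the actual (jittered) well
    centres in raster order.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    w, h = layout.image_size_px
    img = np.zeros((h, w, 3), dtype=float)
    img[..., 0] = body_level * 0.8
    img[..., 1] = body_level * 0.8
    img[..., 2] = body_level

    centres = layout.well_centres()
    if jitter_px > 0:
        centres = centres + rng.uniform(-jitter_px, jitter_px, size=centres.shape)
    r = layout.well_radius_px
    for cx, cy in centres:
        x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
        y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
        for c, lvl in enumerate((well_level * 0.85, well_level * 0.85, well_level)):
            ch = img[y0:y1, x0:x1, c]
            np.maximum(ch, alpha * (lvl - img[y0:y1, x0:x1, c]) + img[y0:y1, x0:x1, c],
                       out=ch)
    if flare > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        dnorm = np.hypot((xx - w / 2) / (w / 2), (yy - h / 2) / (h / 2))
        img *= 1.0 + flare * dnorm[..., None] ** 2
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    out = np.clip(img, 0, 255).astype(np.uint8)
    return (out, centres) if return_centres else out


# --------------------------------------------------------------------------
# fluorescence scene generator
# --------------------------------------------------------------------------

def generate_scene(layout: CassetteLayout,
                   roots: Sequence[GroundTruthRoot] = (),
                   debris: Sequence[GroundTruthDebris] = (),
                   noise_sd: float = 0.0,
                   dim: bool = False,
                   seed: int = 0,
                   *,
                   background_rgb: tuple[float, float, float] = (11.0, 10.0, 14.0),
                   texture_sd: float = 1.5,
                   dim_factor: float = 0.04) -> SyntheticScene:
    """Render a fluorescence cassette scene from explicit ground truth.

    The background is dark and low-chroma with gentle large-scale texture
    (soil is non-fluorescent); roots are bright blue ridged strokes; debris
    is thick and bright.  Additive zero-mean Gaussian sensor noise of
    standard deviation ``noise_sd`` is applied last and the result clipped
    to [0, 255].  ``dim`` scales all rendered signal by ``dim_factor``
    before the noise, emulating an under-exposed frame.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    w, h = layout.image_size_px
    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = np.asarray(background_rgb)[None, None, :]
    if texture_sd > 0:
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 12.0)
        tex *= texture_sd / max(tex.std(), 1e-9)
        canvas += tex[..., None]

    kept_roots: list[GroundTruthRoot] = []
    for root in roots:
        poly, clipped = _clip_polyline(root.polyline, layout.image_size_px)
        root = replace(root, polyline=poly, clipped=clipped or root.clipped)
        _render_stroke(canvas, root.polyline, root.width_px,
                       _hue_to_rgb(root.hue_deg) * root.peak_intensity, "bump")
        kept_roots.append(root)
    for d in debris:
        _render_stroke(canvas, d.polyline, d.min_width_px,
                       _hue_to_rgb(d.hue_deg) * d.intensity, "dome")

    if dim:
        canvas *= dim_factor
    if noise_sd > 0:
        canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, layout=layout, roots=kept_roots,
                          debris=list(debris), noise_sd=noise_sd, seed=seed,
                          dim=dim)


def _random_root_polyline(rng: np.random.Generator, centre: np.ndarray,
                          max_r: float, length: float,
                          step: float = 6.0, wiggle: float = 0.05) -> np.ndarray | None:
    """Random smooth polyline staying within ``max_r`` of ``centre``.

    The walk steers back toward the well centre as it nears the boundary,
    so long roots curl inside the well the way unconstrained segments
    settle inside a physical well.
    """
    length = min(length, 2.2 * max_r)   # longer walks cannot stay inside
    max_turn = 0.025 * step             # gentle curvature: radius >= ~40 px
    for _ in range(30):
        start = centre + rng.uniform(-0.55, 0.55, 2) * max_r
        # aim across the well so straight-ish walks stay inside
        target = centre + rng.uniform(-0.5, 0.5, 2) * max_r
        aim = target - start
        theta = (math.atan2(aim[1], aim[0]) if np.hypot(*aim) > 1e-6
                 else rng.uniform(0, 2 * math.pi))
        pts = [start]
        pos, ok = start.copy(), True
        n_steps = max(2, int(round(length / step)))
        for _ in range(n_steps):
            theta += rng.normal(0.0, wiggle)
            turned, cand = 0.0, None
            while turned <= max_turn:
                cand = pos + step * np.array([math.cos(theta), math.sin(theta)])
                if np.hypot(*(cand - centre)) <= max_r:
                    break
                # rotate gently toward the centre direction
                to_centre = math.atan2(*(centre - pos)[::-1])
                delta = (to_centre - theta + math.pi) % (2 * math.pi) - math.pi
                theta += math.copysign(0.02 * step, delta if delta != 0 else 1.0)
                turned += 0.02 * step
            else:
                ok = False
                break
            pos = cand
            pts.append(pos.copy())
        if ok:
            return np.array(pts)
        length = max(length * 0.9, 8 * step)   # ask for less room next try
    return None


def random_scene(layout: CassetteLayout | None = None,
                 seed: int = 0,
                 *,
                 roots_per_well: tuple[int, int] = (0, 3),
                 root_length_px: tuple[float, float] = (120.0, 200.0),
                 root_width_px: tuple[float, float] = (5.0, 7.0),
                 root_peak: tuple[float, float] = (170.0, 230.0),
                 root_hue_deg: tuple[float, float] = (225.0, 250.0),
                 n_debris: int = 0,
                 debris_width_px: tuple[float, float] = (20.0, 26.0),
                 debris_aspect: tuple[float, float] = (6.0, 8.0),
                 min_separation_px: float = 24.0,
                 noise_sd: float = 0.0,
                 dim: bool = False,
                 n_isolated_roots: int = 0) -> SyntheticScene:
    """Generate a scene with randomly placed, mutually well-separated roots.

    Roots are confined to their well disc (with a margin) and kept at least
    ``min_separation_px`` apart, so the ground-truth per-well root count is
    unambiguous.  Debris capsules are placed anywhere in the frame and may
    cross wells.  ``n_isolated_roots`` adds roots in the gaps between wells
    that belong to no well (they should never be counted downstream).
    """
    layout = layout or CassetteLayout.default()
    rng = np.random.default_rng(seed)
    centres = layout.well_centres()
    margin = max(root_width_px[1], 4.0)
    roots: list[GroundTruthRoot] = []
    placed_pts: list[np.ndarray] = []

    def _far_enough(poly: np.ndarray) -> bool:
        if not placed_pts:
            return True
        tree = cKDTree(np.vstack(placed_pts))
        d, _ = tree.query(_densify(poly, 2.0), workers=1)
        return bool(d.min() > min_separation_px)

    for well_idx, centre in enumerate(centres, start=1):
        n = int(rng.integers(roots_per_well[0], roots_per_well[1] + 1))
        for _ in range(n):
            for _attempt in range(150):
                # ask for progressively shorter roots if the well is
                # crowded, but never below a clearly detectable length
                length = max(rng.uniform(*root_length_px) * 0.95 ** _attempt,
                             48.0)
                poly = _random_root_polyline(rng, centre,
                                             layout.well_radius_px - margin, length)
                if poly is not None and _far_enough(poly):
                    roots.append(GroundTruthRoot(
                        polyline=poly,
                        width_px=rng.uniform(*root_width_px),
                        hue_deg=rng.uniform(*root_hue_deg),
                        peak_intensity=rng.uniform(*root_peak),
                        well_index=well_idx,
                    ))
                    placed_pts.append(_densify(poly, 2.0))
                    break

    # isolated roots midway between horizontally adjacent wells
    for k in range(n_isolated_roots):
        row = int(rng.integers(0, layout.rows))
        col = int(rng.integers(0, layout.cols - 1)) if layout.cols > 1 else 0
        idx = row * layout.cols + col
        mid = (centres[idx] + centres[min(idx + 1, len(centres) - 1)]) / 2.0
        gap = layout.pitch_px / 2.0 - layout.well_radius_px
        half = max(gap - 6.0, 8.0) / 2.0
        ang = rng.uniform(0, math.pi)
        d = np.array([math.cos(ang), math.sin(ang)]) * half
        roots.append(GroundTruthRoot(
            polyline=np.array([mid - d, mid + d]),
            width_px=rng.uniform(*root_width_px),
            hue_deg=rng.uniform(*root_hue_deg),
            peak_intensity=rng.uniform(*root_peak),
            well_index=None,
        ))

    debris: list[GroundTruthDebris] = []
    w, h = layout.image_size_px
    debris_pts: list[np.ndarray] = []
    for _ in range(n_debris):
        width = rng.uniform(*debris_width_px)
        # straw fragments are decidedly elongated; the thickness-based
        # debris rule targets exactly such linear contaminants
        length = width * rng.uniform(*debris_aspect)
        for _attempt in range(20):
            p0 = rng.uniform([width, width], [w - width, h - width])
            ang = rng.uniform(0, math.pi)
            d = length * np.array([math.cos(ang), math.sin(ang)])
            p1 = p0 + d
            if not ((width <= p1[0] <= w - width) and (width <= p1[1] <= h - width)):
                p1 = p0 - d     # reflect
            if not ((width <= p1[0] <= w - width) and (width <= p1[1] <= h - width)):
                continue        # will not fit at full length here; retry
            spine = np.array([p0, p1])
            dense = _densify(spine, 2.0)
            # keep clear of roots and of other debris strands: crossed
            # strands merge into a compact object the thickness rule
            # cannot treat as linear debris
            obstacles = placed_pts + debris_pts
            if obstacles:
                dist, _ = cKDTree(np.vstack(obstacles)).query(dense, workers=1)
                if dist.min() <= width + min_separation_px:
                    continue
            debris.append(GroundTruthDebris(
                polyline=spine, min_width_px=width,
                intensity=rng.uniform(200.0, 245.0),
            ))
            debris_pts.append(dense)
            break

    render_seed = int(rng.integers(0, 2**31 - 1))
    return generate_scene(layout, roots, debris, noise_sd=noise_sd, dim=dim,
                          seed=render_seed)


# --------------------------------------------------------------------------
# calibration-campaign generator
# --------------------------------------------------------------------------

def default_depth_profile(z_cm: np.ndarray | float) -> np.ndarray | float:
    """Typical cereal root-length-density decline with depth (cm/cm^3)."""
    return 1.5 * np.exp(-np.asarray(z_cm, dtype=float) / 45.0)


@dataclass
class CalibrationDataset:
    """Simulated core-break campaign: per-face counts plus washed densities."""

    profiles: list[CoreProfile]
    pairs: "object"                 # pandas.DataFrame: core_id, top_cm, bottom_cm, summed_count, rld
    gain: float
    expected_window_gain: float     # slope of windowed count vs density

    def r_observed(self) -> float:
        from scipy.stats import pearsonr

        return float(pearsonr(self.pairs["summed_count"], self.pairs["rld"])[0])


def generate_calibration_dataset(
    depth_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    gain: float = 2.0,
    n_cores: int = 10,
    seed: int = 0,
    *,
    depth_max_cm: int = 200,
    noise: str = "poisson",
    core_sd: float = 0.3,
) -> CalibrationDataset:
    """Simulate a core-break calibration campaign.

    Each 2 m core is broken every 5 cm; the two opposing faces at each
    internal break plane each yield a count drawn with mean
    ``gain x local density`` (``noise='poisson'`` for Poisson counts,
    ``'none'`` for deterministic rounded means).  Washed root length
    densities are measured on 10 cm increments; windows pair the density of
    increment (t, t+10) with the break counts at t, t+5 and t+10 cm.
    Between-core variability enters as a log-normal multiplier with
    log-scale standard deviation ``core_sd``.

    With both faces at a depth summed, the expected windowed count is
    ``6 x gain x density``, which is reported as ``expected_window_gain``.
    """
    import pandas as pd

    if n_cores < 2:
        raise ValueError("n_cores must be >= 2 (correlation undefined otherwise)")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    depth_profile = depth_profile or default_depth_profile
    rng = np.random.default_rng(seed)

    break_depths = np.arange(5, depth_max_cm, 5)          # internal break planes
    window_tops = np.arange(10, depth_max_cm - 10, 10)    # fully interior windows

    profiles: list[CoreProfile] = []
    rows = []
    for core_i in range(n_cores):
        core_id = f"core{core_i + 1:02d}"
        mult = float(np.exp(rng.normal(0.0, core_sd))) if core_sd > 0 else 1.0
        dens = np.maximum(np.asarray(depth_profile(break_depths), dtype=float), 0.0) * mult
        if (dens < 0).any():
            raise ValueError("densities must be non-negative")
        faces = []
        for depth, d in zip(break_depths, dens):
            for side in ("upper", "lower"):
                mean = gain * d
                count = (int(rng.poisson(mean)) if noise == "poisson"
                         else int(round(mean)))
                faces.append(FaceCount(depth_cm=int(depth), face=side,
                                       root_number=count,
                                       root_length_px=float(count) * 50.0))
        profile = CoreProfile(core_id=core_id, faces=faces)
        profiles.append(profile)
        for top in window_tops:
            zz = np.linspace(top, top + 10, 21)
            rld = float(np.mean(np.maximum(depth_profile(zz), 0.0)) * mult)
            total = sum(f.root_number for f in faces
                        if f.depth_cm in (top, top + 5, top + 10))
            rows.append({"core_id": core_id, "top_cm": int(top),
                         "bottom_cm": int(top + 10),
                         "summed_count": total, "rld": rld})

    pairs = pd.DataFrame(rows)
    return CalibrationDataset(profiles=profiles, pairs=pairs, gain=gain,
                              expected_window_gain=6.0 * gain)


def calibration_r_distribution(n_replicates: int = 1000, seed: int = 0,
                               **kwargs) -> np.ndarray:
    """Monte-Carlo distribution of the observed Pearson r for a campaign.

    Re-simulates ``n_replicates`` campaigns with identical parameters and
    returns the observed correlations, from which confidence bands for the
    calibration recovery can be read off.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        ds = generate_calibration_dataset(seed=int(rng.integers(0, 2**31 - 1)),
                                          **kwargs)
        out[i] = ds.r_observed()
    return out
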