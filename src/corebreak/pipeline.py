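"""End-to-end orchestration: template -> wells -> per-image measurement.

One cassette holds the forty 5 cm segments of a single 2 m core with the
break faces exposed; each cassette is photographed, flipped, and
photographed again, so well k of the two images maps to the two faces of
segment k.  The well map is computed once per session from the template
image and reused for every fluorescence image of that day.

Per image the mask lineage follows: linear structures -> debris-excluded
roots -> roots within wells -> reconstructed roots -> filtered roots,
after which per-well counts and lengths are written as CSV.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import associate, calibrate, debris, detect, measure, wells
from .params import PipelineParams
from .synth import CassetteLayout

__all__ = ["FrameResult", "RunConfig", "SessionResult", "params_for_layout",
           "process_frame", "run_session", "run_calibration", "check_lineage",
           "save_overlay"]

log = logging.getLogger("corebreak")


def params_for_layout(layout: CassetteLayout, **overrides) -> PipelineParams:
    """Parameters with the expected well radius taken from a known layout."""
    f = overrides.get("downsample_factor", 2)
    overrides.setdefault("expected_well_radius_px", layout.well_radius_px / f)
    overrides.setdefault("expected_wells", layout.n_wells)
    return PipelineParams(**overrides)


@dataclass
class FrameResult:
    """Every intermediate of one fluorescence image, in pipeline order."""

    frame: detect.FluorescenceFrame
    linear: np.ndarray               # ridge centrelines
    debris_masks: debris.DebrisMasks
    within_wells: np.ndarray
    reconstructed: np.ndarray
    labelled: associate.LabelledRoots
    filtered: associate.LabelledRoots
    measurement: measure.CassetteMeasurement


def process_frame(image: np.ndarray, wellmap: wells.WellMap,
                  params: PipelineParams) -> FrameResult:
    """Run the full per-image pipeline against a precomputed well map."""
    frame = detect.preprocess_frame(image, params)
    linear = detect.detect_linear_structures(frame, params)
    dmasks = debris.find_debris(frame.blue_ds, linear,
                                wellmap.well_area_px(), params)
    within = associate.mask_by_wells(dmasks.debris_excluded_roots, wellmap)
    recon = associate.reconstruct_roots(within, dmasks.debris_excluded_roots)
    labelled = associate.label_by_well(recon, wellmap)
    filtered = measure.filter_roots(labelled, frame.rgb_ds, params)
    meas = measure.measure_wells(filtered, wellmap, frame.dim)
    return FrameResult(frame=frame, linear=linear, debris_masks=dmasks,
                       within_wells=within, reconstructed=recon,
                       labelled=labelled, filtered=filtered, measurement=meas)


def check_lineage(result: FrameResult) -> bool:
    """Verify the mask containment chain:
    filtered <= reconstructed <= debris-excluded <= linear, and
    within-wells <= reconstructed (sandwich)."""
    filt = result.filtered.label_image > 0
    recon = result.reconstructed
    excl = result.debris_masks.debris_excluded_roots
    return bool(
        not np.any(filt & ~recon)
        and not np.any(recon & ~excl)
        and not np.any(excl & ~result.linear)
        and not np.any(result.within_wells & ~recon)
    )


# --------------------------------------------------------------------------
# session running
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    template_path: Path
    image_paths: list[Path]
    params: PipelineParams = field(default_factory=PipelineParams)
    output_dir: Path = Path(".")
    overlay: bool = False


@dataclass
class SessionResult:
    wellmap: wells.WellMap
    records: list[dict]
    failures: list[str]

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_image(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def run_session(config: RunConfig) -> SessionResult:
    """Process a day's images: one well map, one CSV per image.

    Unreadable images are logged and skipped (reported in ``failures``);
    a template failure aborts the whole session.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = _load_image(Path(config.template_path))
    wellmap = wells.find_wells(template, config.params)
    wellmap.to_yaml(out / "wellmap.yaml")
    log.info("well map: %d wells, mean radius %.1f px",
             wellmap.n_wells, wellmap.mean_radius_px)

    records, failures = [], []
    for path in map(Path, config.image_paths):
        t0 = time.perf_counter()
        try:
            image = _load_image(path)
            result = process_frame(image, wellmap, config.params)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            log.error("failed on %s: %s", path, exc)
            failures.append(str(path))
            continue
        csv_path = out / f"{path.stem}.csv"
        measure.write_csv(result.measurement, csv_path)
        if config.overlay:
            save_overlay(result, out / f"{path.stem}_overlay.png")
        rec = {
            "image": str(path),
            "csv": str(csv_path),
            "dim": result.frame.dim,
            "total_roots": result.measurement.total_roots(),
            "total_length_px": result.measurement.total_length(),
            "wall_time_s": time.perf_counter() - t0,
        }
        log.info("%(image)s: dim=%(dim)s roots=%(total_roots)d "
                 "time=%(wall_time_s).2fs", rec)
        records.append(rec)
    return SessionResult(wellmap=wellmap, records=records, failures=failures)


def save_overlay(result: FrameResult, path: str | Path) -> None:
    """Debug overlay: filtered roots in well-label colours on the image."""
    from matplotlib import colormaps

    rgb = np.asarray(result.frame.rgb_ds, dtype=float).copy()
    lab = result.filtered.label_image
    if lab.max() > 0:
        cmap = colormaps["hsv"]
        colours = (np.asarray([cmap((k * 7 % 40) / 40.0)[:3]
                               for k in range(lab.max() + 1)]) * 255)
        mask = lab > 0
        rgb[mask] = colours[lab[mask]]
    Image.fromarray(np.clip(rgb, 0, 255).astype(np.uint8)).save(path)


# --------------------------------------------------------------------------
# calibration over a session
# --------------------------------------------------------------------------

def profiles_from_csvs(manifest: "object") -> list[calibrate.CoreProfile]:
    """Build per-core count profiles from measurement CSVs.

    ``manifest`` is a DataFrame-like with columns ``csv`` (path to a
    per-image measurement), ``core_id`` and ``side`` ('top' = the upper
    faces of the segments are exposed, 'bottom' = cassette flipped).
    Well k holds the segment spanning depths 5(k-1) to 5k cm, so the
    'top' image contributes the face below break plane 5(k-1) and the
    'bottom' image the face above break plane 5k.
    """
    profiles: dict[str, list[calibrate.FaceCount]] = {}
    for _, row in manifest.iterrows():
        m = measure.read_csv(row["csv"])
        side = row["side"]
        if side not in ("top", "bottom"):
            raise ValueError("side must be 'top' or 'bottom'")
        for wrow in m.rows:
            if side == "top":
                depth, face = 5 * (wrow.core - 1), "lower"
            else:
                depth, face = 5 * wrow.core, "upper"
            profiles.setdefault(row["core_id"], []).append(
                calibrate.FaceCount(depth_cm=depth, face=face,
                                    root_number=wrow.root_number,
                                    root_length_px=wrow.root_length))
    return [calibrate.CoreProfile(core_id=cid, faces=faces)
            for cid, faces in sorted(profiles.items())]


def run_calibration(manifest: "object", rld_table: "object",
                    combine: str = "sum") -> calibrate.CalibrationResult:
    """Pair windowed counts with washed densities and calibrate.

    ``rld_table`` is a DataFrame-like with columns ``core_id``, ``top_cm``,
    ``bottom_cm``, ``rld``.  Core identifiers present in the density table
    but missing from the measurement manifest raise an error listing them.
    """
    profiles = {p.core_id: p for p in profiles_from_csvs(manifest)}
    missing = sorted(set(rld_table["core_id"]) - set(profiles))
    if missing:
        raise ValueError(f"no measurements for cores: {', '.join(missing)}")
    pairs = []
    for _, row in rld_table.iterrows():
        window = (int(row["top_cm"]), int(row["bottom_cm"]))
        count = calibrate.window_counts(profiles[row["core_id"]], window,
                                        combine=combine)
        pairs.append(calibrate.CalibrationPair(
            core_id=row["core_id"], window_cm=window,
            summed_count=count, rld=float(row["rld"])))
    return calibrate.calibrate_counts(pairs)
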