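"""Pipeline parameters.

All tunables used by the well-segmentation and root-measurement stages live
in one dataclass so a whole analysis session is reproducible from a single
parameter file.  Defaults follow the published constants of the cassette
imaging workflow (downsampling factor 2, well elongation limit 1.2, debris
threshold 50 grey levels, debris elongation limit 5, debris area fraction
0.25 of the well area, ~13 px/mm sensor resolution); thresholds the original
system left as empirically determined (ridge response, hue window, minimum
length and lightness) are exposed here with defaults chosen for the
synthetic imagery this package generates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineParams:
    # geometry / resolution
    downsample_factor: int = 2
    px_per_mm: float = 13.0          # at full (pre-downsampling) resolution
    expected_wells: int = 40
    expected_well_radius_px: float = 50.0  # downsampled px; used for the area range

    # template / well segmentation
    median_radius_px: int = 1        # 3x3 median window
    well_elongation_max: float = 1.2
    well_area_factor_range: tuple[float, float] = (0.5, 2.0)  # x pi r^2

    # ridge (linear structure) detection
    ridge_sigma: float = 2.0         # Gaussian scale of the line detector
    ridge_high: float = 2.0          # hysteresis upper response threshold
    ridge_low: float = 0.5           # hysteresis lower response threshold
    ridge_end_fraction: float = 0.4  # endpoint retraction, fraction of chain peak
    min_chain_px: int = 3            # discard shorter chains as sensor noise
    gap_close_px: int = 1            # radius used to bridge small centreline gaps

    # debris exclusion
    max_root_radius_px: int = 4      # downsampled px (~0.6 mm root radius)
    debris_threshold: float = 50.0   # grey levels on the background-removed image
    debris_elongation_max: float = 5.0
    debris_area_fraction: float = 0.25   # of the well area
    background_object_delta: float = 25.0  # object/background split in build_background
    debris_dilate_px: int = 4        # safety margin when excluding debris ridges

    # root filtering
    min_root_length_px: float = 10.0
    blue_hue_range_deg: tuple[float, float] = (170.0, 290.0)
    min_lightness: float = 40.0      # 0-255 HSL lightness

    # dim-frame flag
    dim_mean_threshold: float = 8.0  # mean downsampled blue below this => dim

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        lo, hi = self.blue_hue_range_deg
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("hue range must lie in [0, 360)")
        for name in ("median_radius_px", "ridge_sigma", "max_root_radius_px",
                     "debris_threshold", "debris_elongation_max",
                     "debris_area_fraction", "min_root_length_px",
                     "well_elongation_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def well_area_range_px(self) -> tuple[float, float]:
        """Admissible well component area, in downsampled px^2."""
        import math

        area = math.pi * self.expected_well_radius_px ** 2
        lo, hi = self.well_area_factor_range
        return lo * area, hi * area

    # ---------------------------------------------------------------- I/O
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["well_area_factor_range"] = list(self.well_area_factor_range)
        d["blue_hue_range_deg"] = list(self.blue_hue_range_deg)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("well_area_factor_range", "blue_hue_range_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
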