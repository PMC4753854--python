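"""Calibration of core-break counts against washed root length density.

The core-break method estimates root length density (RLD, cm of root per
cm^3 of soil) from the number of roots visible on the fracture faces of a
soil core broken at fixed depth increments.  The relationship between
counts and RLD depends on species and soil structure, so it is calibrated
empirically: a subset of cores is imaged face-by-face, then washed so the
true root length of each 10 cm increment can be measured.

This module implements that workflow:

* :class:`CoreProfile` holds the per-face counts of one core (faces every
  5 cm, both faces of each break plane);
* :func:`window_counts` sums the counts whose break depths bound and bisect
  a 10 cm washed increment — the (t, t+5, t+10) rule: e.g. the washed
  density of the 20-30 cm increment is paired with the counts at 20, 25
  and 30 cm;
* :func:`calibrate_counts` reports the Pearson correlation and the
  least-squares calibration line;
* :func:`empty_well_noise` estimates the false-positive rate from wells
  known to be empty;
* :func:`spectra_contrast` summarises fluorescence-spectroscopy contrast
  between root and soil material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "FaceCount",
    "CoreProfile",
    "CalibrationPair",
    "CalibrationResult",
    "Spectrum",
    "SpectraContrast",
    "window_counts",
    "calibrate_counts",
    "empty_well_noise",
    "spectra_contrast",
]


@dataclass(frozen=True)
class FaceCount:
    """Root count on one face of one break plane of a core."""

    depth_cm: int                    # depth of the break plane, multiple of 5
    face: Literal["upper", "lower"]
    root_number: int
    root_length_px: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_cm % 5 != 0 or self.depth_cm < 0:
            raise ValueError("break depths are non-negative multiples of 5 cm")
        if self.face not in ("upper", "lower"):
            raise ValueError("face must be 'upper' or 'lower'")


@dataclass
class CoreProfile:
    core_id: str
    faces: list[FaceCount]

    def __post_init__(self) -> None:
        self.faces = sorted(self.faces, key=lambda f: (f.depth_cm, f.face))

    def depths(self) -> list[int]:
        return sorted({f.depth_cm for f in self.faces})

    def counts_at(self, depth_cm: int, combine: str = "sum") -> int:
        """Combined count of the faces at one break depth.

        A pulled root appears on exactly one of the two opposing faces, so
        summing both faces counts each root once (the default).  ``mean``
        and ``max`` are provided for sensitivity analysis.
        """
        vals = [f.root_number for f in self.faces if f.depth_cm == depth_cm]
        if not vals:
            raise ValueError(
                f"core {self.core_id}: no face at {depth_cm} cm"
            )
        if combine == "sum":
            return int(sum(vals))
        if combine == "mean":
            return int(round(sum(vals) / len(vals)))
        if combine == "max":
            return int(max(vals))
        raise ValueError("combine must be 'sum', 'mean' or 'max'")


@dataclass(frozen=True)
class CalibrationPair:
    core_id: str
    window_cm: tuple[int, int]
    summed_count: int
    rld: float                       # cm / cm^3

    def __post_init__(self) -> None:
        top, bottom = self.window_cm
        if bottom - top != 10:
            raise ValueError("calibration windows span exactly 10 cm")
        if self.rld < 0:
            raise ValueError("root length density cannot be negative")


def window_counts(profile: CoreProfile, window_cm: tuple[int, int],
                  combine: str = "sum") -> int:
    """Summed count for a 10 cm window: break depths at top, middle, bottom.

    ``window_cm=(20, 30)`` uses the faces at 20, 25 and 30 cm.  Adjacent
    windows deliberately share their boundary depth (the 30 cm faces enter
    both the 20-30 and the 30-40 cm windows).
    """
    top, bottom = window_cm
    if bottom - top != 10:
        raise ValueError("window must span exactly 10 cm")
    return sum(profile.counts_at(d, combine=combine)
               for d in (top, top + 5, bottom))


@dataclass(frozen=True)
class CalibrationResult:
    """Pearson correlation and least-squares line of count vs density."""

    r: float
    n: int
    slope: float
    intercept: float
    p_value: float

    def summary(self) -> str:
        return (
            f"Calibration of windowed core-break counts vs washed RLD\n"
            f"  n pairs    : {self.n}\n"
            f"  Pearson r  : {self.r:.3f} (p = {self.p_value:.3g})\n"
            f"  count = {self.slope:.3f} x RLD + {self.intercept:.3f}\n"
        )


def calibrate_counts(pairs: Sequence[CalibrationPair] | "object") -> CalibrationResult:
    """Correlate windowed counts with washed root length densities.

    Accepts a sequence of :class:`CalibrationPair` or any DataFrame-like
    with ``summed_count`` and ``rld`` columns.  Counts are the response in
    the fitted line (count = slope x RLD + intercept), matching how a new
    count is converted back to a density through the calibration.
    """
    from scipy import stats

    if hasattr(pairs, "columns"):
        counts = np.asarray(pairs["summed_count"], dtype=float)
        rld = np.asarray(pairs["rld"], dtype=float)
    else:
        counts = np.array([p.summed_count for p in pairs], dtype=float)
        rld = np.array([p.rld for p in pairs], dtype=float)
    n = counts.size
    if n < 3:
        raise ValueError("need at least 3 pairs to calibrate")
    if np.ptp(counts) == 0 or np.ptp(rld) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    lr = stats.linregress(rld, counts)
    return CalibrationResult(r=float(lr.rvalue), n=int(n),
                             slope=float(lr.slope),
                             intercept=float(lr.intercept),
                             p_value=float(lr.pvalue))


def empty_well_noise(measurements: Iterable["object"],
                     empty_wells: set[int] | Sequence[int]) -> float:
    """Mean detections per designated-empty well: the false-positive rate.

    ``measurements`` iterates over per-cassette measurement objects exposing
    ``root_number(well)`` (see :mod:`corebreak.measure`); ``empty_wells``
    are 1-based well labels known to contain no core material.
    """
    empty = sorted(set(int(w) for w in empty_wells))
    if not empty:
        raise ValueError("no empty wells designated")
    total, n = 0, 0
    for m in measurements:
        for wlab in empty:
            total += m.root_number(wlab)
            n += 1
    if n == 0:
        raise ValueError("no measurements supplied")
    return total / n


# --------------------------------------------------------------------------
# fluorescence spectroscopy summary
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Normalised fluorescence emissivity of one material (roots or soil).

    Values are emission normalised against the largest measurement across
    both materials; negative values represent absorption.  ``se`` carries
    the per-wavelength standard error across replicates, if known.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    material: str = ""
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelength grid and values must match in shape")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)


def normalize_joint(roots: Spectrum, soil: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Scale both spectra by the single global maximum magnitude."""
    m = max(np.abs(roots.values).max(), np.abs(soil.values).max())
    if m == 0:
        raise ValueError("cannot normalise all-zero spectra")
    scale = 1.0 / m
    return (
        Spectrum(roots.wavelengths_nm, roots.values * scale, roots.material,
                 None if roots.se is None else roots.se * scale),
        Spectrum(soil.wavelengths_nm, soil.values * scale, soil.material,
                 None if soil.se is None else soil.se * scale),
    )


@dataclass(frozen=True)
class SpectraContrast:
    wavelengths_nm: np.ndarray
    difference: np.ndarray
    difference_se: np.ndarray | None
    peak_contrast_nm: float          # wavelength of maximum roots - soil
    peak_emission_nm: float          # wavelength of maximum root emission


def spectra_contrast(roots: Spectrum, soil: Spectrum) -> SpectraContrast:
    """Root-minus-soil difference curve and its peak wavelengths.

    Error bars of the difference are formed by addition of the two standard
    errors (a conservative combination for a difference of means).
    """
    if not np.array_equal(roots.wavelengths_nm, soil.wavelengths_nm):
        raise ValueError("spectra are on different wavelength grids")
    diff = roots.values - soil.values
    se = None
    if roots.se is not None and soil.se is not None:
        se = roots.se + soil.se
    wl = roots.wavelengths_nm
    return SpectraContrast(
        wavelengths_nm=wl,
        difference=diff,
        difference_se=se,
        peak_contrast_nm=float(wl[int(np.argmax(diff))]),
        peak_emission_nm=float(wl[int(np.argmax(roots.values))]),
    )
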