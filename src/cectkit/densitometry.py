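"""Digital densitometry: Safranin-O section images to proteoglycan profiles.

Safranin-O binds stoichiometrically to proteoglycans, so the optical density
(OD) of a stained section measures local PG content.  The camera gray scale
is converted to OD through a linear calibration fitted to imaged neutral
filters of known OD, exactly as the imaging setup intends (residuals are
reported so a nonlinear camera is detectable).  Per section, pixels at the
same depth are averaged into a depthwise profile; profiles are standardized
onto the shared 100-point normalized-depth grid and the (nominally three)
section replicates averaged.

Summaries: *bulk* PG = mean over the full thickness (grid points 1-100),
*superficial* PG = mean over the top 30 % (grid points 1-30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .diffusion_pipeline import standardize_profile

__all__ = [
    "DEFAULT_CALIBRATION_ODS",
    "ODCalibration",
    "ODProfile",
    "calibrate_od",
    "od_profile",
    "summarize",
]

DEFAULT_CALIBRATION_ODS = (0.0, 0.15, 0.3, 0.6, 1.3, 1.6, 2.0, 2.3, 2.6, 3.0)

#: Number of leading grid points forming the superficial zone (top 30 %).
SUPERFICIAL_POINTS = 30


@dataclass
class ODCalibration:
    """Linear gray -> OD map with its calibration residual."""

    slope: float
    intercept: float
    residual_rms: float
    od_range: tuple[float, float]

    def gray_to_od(self, gray: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(gray, dtype=float) + self.intercept


@dataclass
class ODProfile:
    """100-point depthwise optical density; summaries are always derived."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (100,):
            raise ValueError("an OD profile has exactly 100 points")

    @property
    def bulk(self) -> float:
        return float(self.values.mean())

    @property
    def superficial(self) -> float:
        return float(self.values[:SUPERFICIAL_POINTS].mean())


def calibrate_od(
    filter_grays: np.ndarray, nominal_ods: np.ndarray = DEFAULT_CALIBRATION_ODS
) -> ODCalibration:
    """Least-squares line mapping filter mean gray values to nominal OD.

    Requires at least 3 filters and strictly monotone gray values (either
    direction); a non-monotone filter series indicates a broken acquisition.
    """
    grays = np.asarray(filter_grays, dtype=float)
    ods = np.asarray(nominal_ods, dtype=float)
    if grays.size != ods.size:
        raise ValueError("one gray value per nominal OD is required")
    if grays.size < 3:
        raise ValueError("at least 3 calibration filters are required")
    diffs = np.diff(grays[np.argsort(ods)])
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("filter gray values are not monotone in OD")
    slope, intercept = np.polyfit(grays, ods, 1)
    resid = ods - (slope * grays + intercept)
    return ODCalibration(
        slope=float(slope),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        od_range=(float(ods.min()), float(ods.max())),
    )


def od_profile(
    sections: list[np.ndarray], calibration: ODCalibration, surface_at_top: bool = True
) -> ODProfile:
    """Depthwise OD profile averaged over replicate section images.

    Each section (2D, surface at the top row) is reduced to per-row mean
    gray, converted to OD, standardized to the 100-point grid, and the
    replicates are averaged.  Fewer than 3 sections triggers a warning but
    proceeds.
    """
    if len(sections) == 0:
        raise ValueError("no section images provided")
    if len(sections) < 3:
        warnings.warn(
            f"only {len(sections)} section(s); depthwise averaging normally uses 3",
            stacklevel=2,
        )
    profiles = []
    for img in sections:
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError("section images must be 2D")
        if not surface_at_top:
            img = img[::-1]
        row_gray = img.mean(axis=1)
        od = calibration.gray_to_od(row_gray)
        depths = (np.arange(od.size) + 0.5) / od.size * 100.0
        profiles.append(standardize_profile(od, depths, units="OD").values)
    return ODProfile(np.mean(profiles, axis=0))


def summarize(profile: ODProfile) -> tuple[float, float]:
    """(bulk, superficial) mean OD of a standardized profile."""
    return profile.bulk, profile.superficial
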