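"""Hounsfield-unit standardization from air and water phantom scans.

Reconstructed attenuation values are mapped to the HU scale (water = 0,
air = -1000) by the affine transform

    HU(v) = 1000 * (v - mu_water) / (mu_water - mu_air)

where ``mu_water`` and ``mu_air`` are single-number summaries (trimmed
means, robust to reconstruction artifacts) of phantom scans acquired under
the same conditions as the specimen scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError


@dataclass(frozen=True)
class PhantomCalibration:
    """Water/air phantom attenuation summary for one acquisition setup."""

    mu_water: float
    mu_air: float
    acquisition_tag: str = ""
    trim_fraction: float = 0.05

    def __post_init__(self):
        if not self.mu_water > self.mu_air:
            raise CalibrationError(
                f"water attenuation ({self.mu_water}) must exceed air "
                f"({self.mu_air})")


def to_hounsfield(value, cal: PhantomCalibration):
    """Convert attenuation value(s) to HU; affine and order-preserving."""
    v = np.asarray(value, dtype=float)
    out = 1000.0 * (v - cal.mu_water) / (cal.mu_water - cal.mu_air)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def calibrate_from_phantom_stats(water_values, air_values,
                                 trim_fraction: float = 0.05,
                                 acquisition_tag: str = "") -> PhantomCalibration:
    """Estimate phantom attenuations by per-tail trimmed means."""
    water = np.asarray(water_values, dtype=float)
    air = np.asarray(air_values, dtype=float)
    if water.size == 0 or air.size == 0:
        raise CalibrationError("phantom samples must be non-empty")
    if not 0 <= trim_fraction < 0.5:
        raise CalibrationError("trim_fraction must lie in [0, 0.5)")
    mu_water = float(stats.trim_mean(water, trim_fraction))
    mu_air = float(stats.trim_mean(air, trim_fraction))
    if not mu_water > mu_air:
        raise CalibrationError(
            f"phantom distributions overlap: trimmed water mean "
            f"({mu_water}) <= air mean ({mu_air})")
    return PhantomCalibration(mu_water=mu_water, mu_air=mu_air,
                              acquisition_tag=acquisition_tag,
                              trim_fraction=trim_fraction)
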