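"""Per-analyte linear calibration, external-standard quantitation (ESM) and
signal-to-noise based LOD/LOQ estimation.

Calibration is unweighted ordinary least squares of peak *area* on
concentration (ug/mL).  LOD and LOQ are the concentrations whose peaks reach
S/N 3 and 10 given a noise SD expressed in area-equivalent units; published
LOD/LOQ figures are instrument specific and serve only as order-of-magnitude
references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "fit_calibration",
    "esm_quantify",
    "lod_loq",
    "area_noise_equivalent",
]

# area of a Gaussian at unit height with the given half-height width
_AREA_PER_HEIGHT_HW = math.sqrt(2.0 * math.pi) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class CalibrationCurve:
    """Linear response ``area = slope * conc + intercept`` over a range."""

    analyte: str
    slope: float
    intercept: float
    r: float
    range_low: float
    range_high: float
    lod: float | None = None
    loq: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        if self.n and self.n < 3:
            raise ValueError("calibration needs at least 3 points")
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if self.lod is not None and self.loq is not None and not self.lod < self.loq:
            raise ValueError("LOD must be < LOQ")

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


class QuantResult(NamedTuple):
    value: float
    out_of_range: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def fit_calibration(
    concs: Sequence[float], areas: Sequence[float], analyte: str = ""
) -> CalibrationCurve:
    """Unweighted least-squares line through (conc, area) points.

    ``r`` is the Pearson correlation of the points; the linear range is
    [min(conc), max(conc)].
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concs and areas must be 1-D and the same length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    fit = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        range_low=float(x.min()),
        range_high=float(x.max()),
        n=int(x.size),
    )


def esm_quantify(curve: CalibrationCurve, area: float) -> QuantResult:
    """Invert the calibration line: conc = (area - intercept) / slope.

    Values outside the fitted range are returned but flagged, never
    rejected.
    """
    conc = (area - curve.intercept) / curve.slope
    out = not curve.range_low <= conc <= curve.range_high
    return QuantResult(value=float(conc), out_of_range=out)


def area_noise_equivalent(noise_sd: float, half_width: float) -> float:
    """Convert a height-noise SD to area units via a nominal peak shape.

    A Gaussian of height h and half-height width w has area
    h * w * sqrt(2 pi) / (2 sqrt(2 ln 2)) = 1.0645 h w; the same factor maps
    baseline noise SD to the area of a just-detectable peak.
    """
    if noise_sd <= 0 or half_width <= 0:
        raise ValueError("noise_sd and half_width must be > 0")
    return noise_sd * half_width * _AREA_PER_HEIGHT_HW


def lod_loq(
    curve: CalibrationCurve,
    noise_sd_area: float,
    use_intercept: bool = False,
) -> tuple[float, float]:
    """Concentrations at S/N 3 (LOD) and 10 (LOQ).

    By default the intercept is ignored (signal-above-baseline convention),
    making LOQ/LOD exactly 10/3; ``use_intercept=True`` solves the full
    calibration line instead.
    """
    if noise_sd_area <= 0:
        raise ValueError(f"noise SD must be > 0, got {noise_sd_area}")
    if use_intercept:
        lod = (3.0 * noise_sd_area - curve.intercept) / curve.slope
        loq = (10.0 * noise_sd_area - curve.intercept) / curve.slope
    else:
        lod = 3.0 * noise_sd_area / curve.slope
        loq = 10.0 * noise_sd_area / curve.slope
    return float(lod), float(loq)
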