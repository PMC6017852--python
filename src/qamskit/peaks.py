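"""Chromatographic peak processing: baseline estimation, peak detection,
integration, system-suitability metrics and RRT-based analyte assignment.

Times are minutes throughout; integration bounds are half-open ``[start,
end)`` on the sampling grid.  Areas are trapezoidal integrals of the
baseline-subtracted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic import Chromatogram, REFERENCE_ANALYTE

__all__ = [
    "Peak",
    "PeakTable",
    "RRTLibrary",
    "estimate_baseline",
    "detect_peaks",
    "integrate_peak",
    "plates",
    "tailing_factor",
    "resolution",
    "assign_analytes",
    "build_peak_table",
]

# Printed RRT dispersions (SD) of the default method; windows are SD times a
# configurable multiplier.
_DEFAULT_RRT_SD = {
    "PQ-1": (0.45, 0.02),
    "PQ-5": (0.72, 0.02),
    "PQ-4": (0.75, 0.02),
    "PQ-3": (0.83, 0.01),
    "PQ-6": (1.00, 0.01),
    "PQ-2": (1.18, 0.01),
}

#: Fraction of apex height treated as baseline return when no valley is found.
#: 0.001 keeps the truncated Gaussian tail mass below 0.05% of the area.
BASELINE_RETURN_FRACTION = 0.001

#: Base width approximation from half-height width (Gaussian: 4 sigma).
BASE_WIDTH_PER_HALF_WIDTH = 1.699


@dataclass
class Peak:
    """One integrated peak with its suitability metrics."""

    apex_time: float
    height: float
    area: float
    half_width: float
    start: float
    end: float
    snr: float
    plates: float | None = None
    tailing: float | None = None
    resolution: float | None = None
    apex_index: int = -1

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("peak area must be > 0")
        if not self.start < self.apex_time < self.end:
            raise ValueError("apex must lie strictly inside the integration bounds")
        if self.half_width <= 0:
            raise ValueError("half-height width must be > 0")
        if self.snr < 0:
            raise ValueError("SNR must be >= 0")


@dataclass(frozen=True)
class RRTLibrary:
    """Expected relative retention time and acceptance half-window per analyte."""

    entries: Mapping[str, tuple[float, float]]
    reference: str = REFERENCE_ANALYTE

    def __post_init__(self) -> None:
        for analyte, (rrt, tol) in self.entries.items():
            if tol <= 0:
                raise ValueError(f"tolerance for {analyte} must be > 0")
            if rrt <= 0:
                raise ValueError(f"expected RRT for {analyte} must be > 0")

    @classmethod
    def default(cls, tolerance_multiplier: float = 2.0) -> "RRTLibrary":
        return cls(
            {
                a: (rrt, sd * tolerance_multiplier)
                for a, (rrt, sd) in _DEFAULT_RRT_SD.items()
            }
        )

    def window(self, analyte: str) -> tuple[float, float]:
        rrt, tol = self.entries[analyte]
        return rrt - tol, rrt + tol


@dataclass
class PeakTable:
    """Detected peaks plus analyte assignments, RRTs and relative peak areas."""

    peaks: list[Peak]
    assignments: dict[str, int]  # analyte -> index into peaks
    reference: str = REFERENCE_ANALYTE
    rrt: dict[str, float] = field(default_factory=dict)
    rpa: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = list(self.assignments.values())
        if len(idx) != len(set(idx)):
            raise ValueError("one peak cannot carry two analyte labels")

    @property
    def analytes(self) -> list[str]:
        return list(self.assignments)

    def peak_of(self, analyte: str) -> Peak:
        return self.peaks[self.assignments[analyte]]

    def area_of(self, analyte: str) -> float:
        return self.peak_of(analyte).area

    def to_dataframe(self) -> pd.DataFrame:
        by_index = {i: a for a, i in self.assignments.items()}
        rows = []
        for i, p in enumerate(self.peaks):
            analyte = by_index.get(i, "")
            rows.append(
                {
                    "analyte": analyte,
                    "rt_min": p.apex_time,
                    "rrt": self.rrt.get(analyte, np.nan),
                    "area": p.area,
                    "rpa": self.rpa.get(analyte, np.nan),
                    "height": p.height,
                    "snr": p.snr,
                    "plates": np.nan if p.plates is None else p.plates,
                    "tailing": np.nan if p.tailing is None else p.tailing,
                    "resolution": np.nan if p.resolution is None else p.resolution,
                }
            )
        return pd.DataFrame(rows)


def estimate_baseline(
    chrom: Chromatogram, degree: int = 1, n_iter: int = 12, clip: float = 3.0
) -> tuple[np.ndarray, float]:
    """Robust low-order polynomial baseline plus a noise-SD estimate.

    Iteratively refits the polynomial to points within ``clip`` robust SDs of
    the current fit, which masks out peaks; the noise SD is the scaled median
    absolute deviation (1.4826 * MAD) of the retained residuals.
    """
    if chrom.time.size < 10:
        raise ValueError("trace too short for baseline estimation")
    t, y = chrom.time, chrom.intensity
    mask = np.ones(t.size, dtype=bool)
    coeffs = np.polyfit(t, y, degree)
    for _ in range(n_iter):
        coeffs = np.polyfit(t[mask], y[mask], degree)
        resid = y - np.polyval(coeffs, t)
        mad = np.median(np.abs(resid[mask] - np.median(resid[mask])))
        sd = 1.4826 * mad
        if sd == 0:
            # noiseless trace: keep only exact-baseline points
            new_mask = np.abs(resid) <= 1e-12 * max(1.0, np.abs(y).max())
        else:
            new_mask = resid < clip * sd
        if new_mask.sum() < degree + 2 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= degree + 2 else mask
            break
        mask = new_mask
    coeffs = np.polyfit(t[mask], y[mask], degree)
    resid = y - np.polyval(coeffs, t)
    mad = np.median(np.abs(resid[mask] - np.median(resid[mask])))
    return np.polyval(coeffs, t), float(1.4826 * mad)


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = 10.0,
    baseline: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> list[int]:
    """Indices of apexes whose baseline-corrected height is >= min_snr * noise.

    On a noiseless trace the detection floor falls back to a small fraction
    of the maximum signal, so clean synthetic peaks are still found.
    """
    if min_snr <= 0:
        raise ValueError(f"min_snr must be > 0, got {min_snr}")
    if baseline is None or noise_sd is None:
        baseline, noise_sd = estimate_baseline(chrom)
    corrected = chrom.intensity - baseline
    threshold = min_snr * noise_sd
    if threshold == 0:
        peak_scale = float(np.max(corrected, initial=0.0))
        if peak_scale <= 0:
            return []
        threshold = 1e-6 * peak_scale
    idx, _ = find_peaks(corrected, height=threshold, prominence=threshold)
    return [int(i) for i in idx]


def _half_crossing(t, y, i_from, i_to, level) -> float:
    """Linear interpolation of the time where y crosses ``level`` between
    adjacent samples i_from (above) and i_to (below)."""
    y0, y1 = y[i_from], y[i_to]
    if y0 == y1:
        return float(t[i_to])
    frac = (y0 - level) / (y0 - y1)
    return float(t[i_from] + frac * (t[i_to] - t[i_from]))


def _width_at_level(t, y, apex, start, end, level) -> tuple[float, float] | None:
    """(left, right) crossing times at ``level`` inside [start, end]; None if
    the level is not reached on either side."""
    left = None
    for i in range(apex, start, -1):
        if y[i - 1] <= level <= y[i]:
            left = _half_crossing(t, y, i, i - 1, level)
            break
    right = None
    for i in range(apex, end):
        if y[i + 1] <= level <= y[i]:
            right = _half_crossing(t, y, i, i + 1, level)
            break
    if left is None or right is None:
        return None
    return left, right


def _find_bound(corrected, apex, direction, noise_sd) -> int:
    """Walk from the apex towards ``direction`` (+1/-1) to a valley or
    baseline-return point; raises if the peak is clipped at the trace edge."""
    h = corrected[apex]
    return_level = BASELINE_RETURN_FRACTION * h
    rise_threshold = max(5.0 * noise_sd, return_level)
    i = apex
    run_min, run_argmin = h, apex
    last = corrected.size - 1
    while True:
        nxt = i + direction
        if nxt < 0 or nxt > last:
            if corrected[i] > 0.05 * h:
                raise ValueError("peak is clipped at the edge of the run")
            return i
        i = nxt
        v = corrected[i]
        if v < run_min:
            run_min, run_argmin = v, i
        if v <= return_level:
            return i
        if v > run_min + rise_threshold:
            return run_argmin


def integrate_peak(
    chrom: Chromatogram,
    apex: int,
    baseline: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> Peak:
    """Integrate one detected apex into a :class:`Peak`.

    Bounds are the nearest valleys (or baseline-return points) on each side;
    the area is the trapezoidal integral of the baseline-subtracted signal
    over the bounds and the half-height width is measured by linear
    interpolation.
    """
    if baseline is None or noise_sd is None:
        baseline, noise_sd = estimate_baseline(chrom)
    t = chrom.time
    corrected = chrom.intensity - baseline
    height = float(corrected[apex])
    if height <= 0:
        raise ValueError("apex height must be positive after baseline subtraction")
    start = _find_bound(corrected, apex, -1, noise_sd)
    end = _find_bound(corrected, apex, +1, noise_sd)
    if end - start < 2:
        raise ValueError("zero-width peak")
    area = float(np.trapezoid(corrected[start : end + 1], t[start : end + 1]))
    if area <= 0:
        raise ValueError("non-positive integrated area")
    crossings = _width_at_level(t, corrected, apex, start, end, height / 2.0)
    if crossings is None:
        raise ValueError("half-height level not reached inside the bounds")
    half_width = crossings[1] - crossings[0]
    snr = float("inf") if noise_sd == 0 else height / noise_sd
    peak = Peak(
        apex_time=float(t[apex]),
        height=height,
        area=area,
        half_width=half_width,
        start=float(t[start]),
        end=float(t[end]),
        snr=snr,
        apex_index=apex,
    )
    peak.plates = plates(peak)
    peak.tailing = tailing_factor(peak, chrom, baseline)
    return peak


def plates(peak: Peak) -> float:
    """Theoretical plate number from the half-height width: 5.54 (t/w)^2."""
    if peak.half_width <= 0:
        raise ValueError("half-height width must be > 0")
    return 5.54 * (peak.apex_time / peak.half_width) ** 2


def tailing_factor(
    peak: Peak, chrom: Chromatogram, baseline: np.ndarray | None = None
) -> float | None:
    """USP tailing factor T = W05 / (2 f) at 5% of apex height.

    Returns None when the 5% level is not reached inside the integration
    bounds (metric reported as absent).
    """
    if baseline is None:
        baseline, _ = estimate_baseline(chrom)
    t = chrom.time
    corrected = chrom.intensity - baseline
    apex = peak.apex_index if peak.apex_index >= 0 else int(
        np.argmin(np.abs(t - peak.apex_time))
    )
    start = int(np.searchsorted(t, peak.start))
    end = int(np.searchsorted(t, peak.end))
    crossings = _width_at_level(t, corrected, apex, start, end, 0.05 * peak.height)
    if crossings is None:
        return None
    left, right = crossings
    front = t[apex] - left
    if front <= 0:
        return None
    return (right - left) / (2.0 * front)


def resolution(prev: Peak, next: Peak) -> float:
    """Resolution R_s = 2 dt / (W1 + W2), base widths from half-height widths."""
    if prev.apex_time > next.apex_time:
        raise ValueError("peaks must be passed in elution order")
    if prev.apex_time == next.apex_time:
        return 0.0
    w1 = BASE_WIDTH_PER_HALF_WIDTH * prev.half_width
    w2 = BASE_WIDTH_PER_HALF_WIDTH * next.half_width
    return 2.0 * (next.apex_time - prev.apex_time) / (w1 + w2)


def _greedy_assign(
    peaks: Sequence[Peak], ref_index: int, library: RRTLibrary
) -> tuple[dict[str, int], dict[str, float]]:
    ref_time = peaks[ref_index].apex_time
    rrts = [p.apex_time / ref_time for p in peaks]
    candidates = []
    for analyte, (expected, tol) in library.entries.items():
        for i, r in enumerate(rrts):
            if analyte == library.reference and i != ref_index:
                continue
            if abs(r - expected) <= tol:
                candidates.append((abs(r - expected), expected, analyte, i))
    # nearest-RRT wins; exact ties break toward the smaller expected RRT
    candidates.sort(key=lambda c: (c[0], c[1], c[3]))
    assignments: dict[str, int] = {}
    taken: set[int] = set()
    for _, _, analyte, i in candidates:
        if analyte in assignments or i in taken:
            continue
        assignments[analyte] = i
        taken.add(i)
    return assignments, {a: rrts[i] for a, i in assignments.items()}


def assign_analytes(
    peaks: Sequence[Peak], library: RRTLibrary | None = None
) -> PeakTable:
    """Assign analytes to peaks by relative retention time.

    The reference peak is found by provisional referencing: every detected
    peak is tried as the reference, and the candidate whose induced RRTs
    match the most library windows wins (largest area breaks ties).  All
    other peaks are then assigned nearest-expected-RRT within their windows;
    an exact tie between adjacent windows goes to the smaller expected RRT.
    """
    library = library or RRTLibrary.default()
    peaks = sorted(peaks, key=lambda p: p.apex_time)
    if not peaks:
        raise ValueError("reference peak not found: no peaks to assign")

    best = None
    for ref_index in range(len(peaks)):
        assignments, _ = _greedy_assign(peaks, ref_index, library)
        if library.reference not in assignments:
            continue
        score = (len(assignments), peaks[ref_index].area)
        if best is None or score > best[0]:
            best = (score, ref_index)
    if best is None:
        raise ValueError("reference peak not found")
    _, ref_index = best

    assignments, rrts = _greedy_assign(peaks, ref_index, library)
    ref_area = peaks[ref_index].area
    rpas = {a: peaks[i].area / ref_area for a, i in assignments.items()}
    # exact identities for the reference
    rrts[library.reference] = 1.0
    rpas[library.reference] = 1.0

    # resolution against the preceding assigned peak, in elution order
    ordered = sorted(assignments.items(), key=lambda kv: peaks[kv[1]].apex_time)
    for (_, i_prev), (_, i_next) in zip(ordered, ordered[1:]):
        peaks[i_next].resolution = resolution(peaks[i_prev], peaks[i_next])

    return PeakTable(
        peaks=list(peaks),
        assignments=assignments,
        reference=library.reference,
        rrt=rrts,
        rpa=rpas,
    )


def build_peak_table(
    chrom: Chromatogram,
    library: RRTLibrary | None = None,
    min_snr: float = 10.0,
) -> PeakTable:
    """Baseline -> detection -> integration -> assignment in one call."""
    baseline, noise_sd = estimate_baseline(chrom)
    apexes = detect_peaks(chrom, min_snr=min_snr, baseline=baseline, noise_sd=noise_sd)
    peaks = [integrate_peak(chrom, i, baseline, noise_sd) for i in apexes]
    return assign_analytes(peaks, library)
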