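"""Synthetic HPLC-UV chromatogram generation with known ground truth.

Every downstream stage (peak processing, calibration, single-marker
quantitation, validation statistics) is exercised against traces produced
here, so the simulator is deliberately simple and fully deterministic under
a seed: each analyte contributes one (exponentially modified) Gaussian peak
whose *true* integrated area follows the linear detector response
``area = slope * conc + intercept`` (clipped at zero), on top of optional
white Gaussian noise and linear baseline drift.

Gradient-elution physics, column chemistry and spectral effects are out of
scope; retention is encoded purely through relative retention times (RRT)
against the reference analyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import exponnorm

__all__ = [
    "ANALYTES",
    "REFERENCE_ANALYTE",
    "STANDARD_RANGES",
    "ResponseModel",
    "InstrumentProfile",
    "InjectionSpec",
    "Chromatogram",
    "simulate_injection",
    "make_standard_series",
    "make_batch_dataset",
]

#: Canonical analyte identifiers, in elution order of the default profile.
ANALYTES = ("PQ-1", "PQ-5", "PQ-4", "PQ-3", "PQ-6", "PQ-2")

#: Single-marker reference analyte.
REFERENCE_ANALYTE = "PQ-6"

#: Mixed-standard working-solution concentration ranges (ug/mL).
STANDARD_RANGES: dict[str, tuple[float, float]] = {
    "PQ-1": (11.0, 41.3),
    "PQ-2": (1.95, 9.75),
    "PQ-3": (20.6, 62.0),
    "PQ-4": (5.22, 31.3),
    "PQ-5": (2.00, 14.1),
    "PQ-6": (2.00, 100.0),
}

# Default linear detector response (area units per ug/mL, area units).
_DEFAULT_RESPONSE = {
    "PQ-1": (42.681, -59.049),
    "PQ-2": (65.376, -5.5050),
    "PQ-3": (119.41, -110.70),
    "PQ-4": (133.80, -38.727),
    "PQ-5": (96.928, -45.405),
    "PQ-6": (86.712, -2.3510),
}

# Default relative retention times against the reference analyte.
_DEFAULT_RRT = {
    "PQ-1": 0.45,
    "PQ-5": 0.72,
    "PQ-4": 0.75,
    "PQ-3": 0.83,
    "PQ-6": 1.00,
    "PQ-2": 1.18,
}

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class ResponseModel:
    """Per-analyte linear detector response ``area = slope * conc + intercept``."""

    coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RESPONSE)
    )

    def __post_init__(self) -> None:
        for analyte, (slope, _) in self.coefficients.items():
            if slope <= 0:
                raise ValueError(f"slope for {analyte} must be > 0, got {slope}")

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def slope(self, analyte: str) -> float:
        return self.coefficients[analyte][0]

    def intercept(self, analyte: str) -> float:
        return self.coefficients[analyte][1]

    def area(self, analyte: str, conc: float) -> float:
        """True peak area at a concentration; negative responses clip to 0."""
        if conc < 0:
            raise ValueError(f"concentration must be >= 0, got {conc}")
        slope, intercept = self.coefficients[analyte]
        return max(0.0, slope * conc + intercept)

    def without_intercepts(self) -> "ResponseModel":
        """Proportional variant (intercepts zeroed); handy for exactness tests."""
        return ResponseModel({a: (s, 0.0) for a, (s, _) in self.coefficients.items()})


@dataclass(frozen=True)
class InstrumentProfile:
    """Retention geometry, peak shape and noise model of the virtual instrument.

    ``half_width`` is the full width at half maximum (min); widths may be
    overridden per analyte through ``half_widths``.
    """

    reference_rt: float = 35.0
    rrt: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_RRT))
    half_width: float = 0.12
    half_widths: Mapping[str, float] = field(default_factory=dict)
    tailing_target: float = 1.0
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    dt: float = 0.01
    run_length: float = 55.0

    def __post_init__(self) -> None:
        if self.reference_rt <= 0:
            raise ValueError("reference_rt must be > 0")
        if self.run_length <= 0 or self.dt <= 0:
            raise ValueError("run_length and dt must be > 0")
        if self.half_width <= 0 or any(w <= 0 for w in self.half_widths.values()):
            raise ValueError("peak widths must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tailing_target <= 0.5:
            raise ValueError("tailing_target must be > 0.5")
        ref = self.rrt.get(REFERENCE_ANALYTE)
        if ref is not None and ref != 1.0:
            raise ValueError("RRT of the reference analyte must be exactly 1")
        for analyte, r in self.rrt.items():
            if not 0 < r < self.run_length / self.reference_rt:
                raise ValueError(
                    f"RRT {r} for {analyte} puts the peak outside the run"
                )

    def width_of(self, analyte: str) -> float:
        return self.half_widths.get(analyte, self.half_width)

    def retention_time(self, analyte: str) -> float:
        return self.rrt[analyte] * self.reference_rt

    def noiseless(self) -> "InstrumentProfile":
        return replace(self, noise_sd=0.0)


@dataclass(frozen=True)
class InjectionSpec:
    """True per-analyte concentrations of one injection."""

    concentrations: Mapping[str, float]
    label: str = "sample"
    replicate: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for analyte, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(
                    f"concentration for {analyte} must be >= 0, got {conc}"
                )

    @classmethod
    def blank(cls, analytes: Sequence[str] = ANALYTES, **kw) -> "InjectionSpec":
        return cls({a: 0.0 for a in analytes}, label="blank", **kw)


@dataclass
class Chromatogram:
    """Uniformly sampled time/intensity trace plus acquisition metadata."""

    time: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("chromatogram needs at least two samples")
        steps = np.diff(self.time)
        if not np.all(steps > 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("chromatogram contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@lru_cache(maxsize=64)
def _emg_tau_ratio(tailing: float) -> float:
    """Exponential-modification ratio tau/sigma giving a USP tailing factor.

    Solved numerically on the analytic exponnorm density; ``tailing`` must be
    > 1 (pure Gaussian and fronting shapes are handled by the caller).
    """

    def usp_tailing(ratio: float) -> float:
        k = max(ratio, 1e-6)
        dist = exponnorm(K=k, loc=0.0, scale=1.0)
        grid = np.linspace(-8.0, 8.0 + 8.0 * k, 8001)
        pdf = dist.pdf(grid)
        i_mode = int(np.argmax(pdf))
        level = 0.05 * pdf[i_mode]
        left = np.interp(level, pdf[: i_mode + 1], grid[: i_mode + 1])
        # right flank is decreasing; reverse for interp
        right = np.interp(level, pdf[i_mode:][::-1], grid[i_mode:][::-1])
        front = grid[i_mode] - left
        return (right - left) / (2.0 * front)

    return brentq(lambda r: usp_tailing(r) - tailing, 1e-4, 50.0, xtol=1e-10)


def _peak_shape(
    t: np.ndarray, center: float, sigma: float, tailing: float
) -> np.ndarray:
    """Unit-area peak with apex at ``center``; tailing via EMG, fronting mirrored."""
    if abs(tailing - 1.0) < 1e-9:
        return np.exp(-0.5 * ((t - center) / sigma) ** 2) / (
            sigma * math.sqrt(2.0 * math.pi)
        )
    mirror = tailing < 1.0
    if mirror:
        # a time-mirrored EMG with tailing T0 shows USP tailing T0/(2*T0-1)
        tailing = tailing / (2.0 * tailing - 1.0)
    ratio = _emg_tau_ratio(tailing)
    dist = exponnorm(K=ratio, loc=0.0, scale=sigma)
    mode = minimize_scalar(
        lambda x: -dist.pdf(x),
        bounds=(0.0, (ratio + 3.0) * sigma),
        method="bounded",
        options={"xatol": 1e-12},
    ).x
    x = (center - t) if mirror else (t - center)
    return dist.pdf(x + mode)


def simulate_injection(
    spec: InjectionSpec,
    response: ResponseModel | None = None,
    profile: InstrumentProfile | None = None,
    rng: np.random.Generator | None = None,
) -> Chromatogram:
    """Render one injection as a chromatogram.

    The noiseless numerically integrated area of each peak equals the linear
    response at the spec's true concentration (clipped at zero).  Noise and
    drift are added afterwards; a seed (``spec.seed`` or an explicit ``rng``)
    is mandatory whenever the profile has noise.
    """
    response = response or ResponseModel()
    profile = profile or InstrumentProfile()

    n = int(round(profile.run_length / profile.dt)) + 1
    t = np.arange(n) * profile.dt
    y = np.zeros(n)

    truth: dict[str, dict[str, float]] = {}
    for analyte, conc in spec.concentrations.items():
        if conc < 0:
            raise ValueError(f"concentration for {analyte} must be >= 0")
        if conc == 0:
            continue
        center = profile.retention_time(analyte)
        sigma = profile.width_of(analyte) / _FWHM_PER_SIGMA
        if center + 4 * sigma > profile.run_length or center - 4 * sigma < 0:
            raise ValueError(
                f"peak for {analyte} at {center:.2f} min falls outside the "
                f"{profile.run_length:.1f} min run"
            )
        area = response.area(analyte, conc)
        truth[analyte] = {"rt_min": center, "area_true": area, "conc_true": conc}
        if area > 0:
            y += area * _peak_shape(t, center, sigma, profile.tailing_target)

    if profile.drift_slope:
        y += profile.drift_slope * t
    if profile.noise_sd > 0:
        if rng is None:
            if spec.seed is None:
                raise ValueError(
                    "a seed is required to simulate with noise; set "
                    "InjectionSpec.seed or pass an explicit rng"
                )
            rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, profile.noise_sd, size=n)

    meta = {
        "label": spec.label,
        "replicate": spec.replicate,
        "seed": spec.seed,
        "truth": truth,
    }
    return Chromatogram(time=t, intensity=y, meta=meta)


def make_standard_series(
    response: ResponseModel | None = None,
    n_levels: int = 6,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[InjectionSpec]:
    """Mixed-standard dilution series with evenly spaced levels per analyte.

    Level 1 is the low end of each working range and the last level the high
    end; ``n_levels=2`` therefore yields exactly the range endpoints.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    response = response or ResponseModel()
    ranges = dict(ranges or STANDARD_RANGES)
    grids = {
        analyte: np.linspace(low, high, n_levels)
        for analyte, (low, high) in ranges.items()
    }
    return [
        InjectionSpec(
            {analyte: float(grids[analyte][i]) for analyte in grids},
            label=f"standard-C{i + 1}",
        )
        for i in range(n_levels)
    ]


def make_batch_dataset(
    truth,
    response: ResponseModel | None = None,
    profile: InstrumentProfile | None = None,
    replicates: int = 1,
    seed: int | None = None,
) -> list[tuple[InjectionSpec, Chromatogram]]:
    """Simulate every sample of a content matrix, ``replicates`` times each.

    ``truth`` is a :class:`~qamskit.chemometrics.BatchContentMatrix`; column
    order defines the analytes.  Per-injection seeds are drawn from a single
    generator so the whole dataset is reproducible from ``seed``.
    """
    from .chemometrics import BatchContentMatrix  # local import avoids a cycle

    if not isinstance(truth, BatchContentMatrix):
        raise TypeError("truth must be a BatchContentMatrix")
    missing = [a for a in ANALYTES if a not in truth.analytes]
    if missing:
        raise ValueError(f"truth matrix is missing analyte column(s): {missing}")
    if replicates < 0:
        raise ValueError("replicates must be >= 0")

    response = response or ResponseModel()
    profile = profile or InstrumentProfile()
    n_runs = len(truth.samples) * replicates
    if profile.noise_sd > 0 and seed is None and n_runs > 0:
        raise ValueError("a seed is required for a noisy batch dataset")
    seeder = np.random.default_rng(seed)
    run_seeds = seeder.integers(0, 2**31 - 1, size=n_runs)

    out: list[tuple[InjectionSpec, Chromatogram]] = []
    k = 0
    for sample in truth.samples:
        row = truth.row(sample)
        for rep in range(replicates):
            spec = InjectionSpec(
                dict(row), label=sample, replicate=rep, seed=int(run_seeds[k])
            )
            out.append((spec, simulate_injection(spec, response, profile)))
            k += 1
    return out
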