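"""Single-marker quantitation engine.

The relative correction factor (RCF) of analyte x against the reference s is

    f_x = (A_s / C_s) / (A_x / C_x)

i.e. the ratio of response factors.  Quantitation inverts this relation
consistently:

    C_x = f_x * (C_s / A_s) * A_x

The literature sometimes prints the quantitation equation with f in the
denominator, which is not the algebraic inverse of the definition above; the
printed form is available behind ``printed_form=True`` for comparison, but
only the multiplicative form round-trips exactly.

Sample analysis is true single-marker operation: the reference concentration
C_s comes from the same run's reference peak via its own calibration curve,
and every other analyte is quantified from f_x and the two peak areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve, esm_quantify, fit_calibration
from .chemometrics import BatchContentMatrix
from .peaks import PeakTable, RRTLibrary, build_peak_table
from .synthetic import (
    Chromatogram,
    InjectionSpec,
    InstrumentProfile,
    REFERENCE_ANALYTE,
    ResponseModel,
    make_standard_series,
    simulate_injection,
)

__all__ = [
    "RCFEstimate",
    "RobustnessGrid",
    "QuantComparison",
    "rcf_single_level",
    "rcf_estimate",
    "qams_quantify",
    "single_marker_sample_quant",
    "robustness_summary",
    "compare_methods",
    "standard_series_tables",
    "curves_from_series",
    "rcfs_from_series",
    "quantify_batch",
]


def _sample_rsd(values: np.ndarray) -> float:
    return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))


@dataclass
class RCFEstimate:
    """Per-level relative correction factors for one analyte."""

    analyte: str
    levels: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("an RCF estimate needs at least 2 levels")
        for level, f in self.levels.items():
            if f <= 0:
                raise ValueError(f"RCF at level {level} must be > 0, got {f}")

    @property
    def mean_f(self) -> float:
        return float(np.mean(list(self.levels.values())))

    @property
    def rsd_pct(self) -> float:
        return _sample_rsd(np.array(list(self.levels.values())))


@dataclass
class RobustnessGrid:
    """RCF determinations across (instrument, column) cells."""

    cells: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.cells) < 2:
            raise ValueError("a robustness grid needs at least 2 cells")
        for key, fs in self.cells.items():
            for analyte, f in fs.items():
                if f <= 0:
                    raise ValueError(f"RCF in cell {key} for {analyte} must be > 0")

    @property
    def analytes(self) -> list[str]:
        first = next(iter(self.cells.values()))
        return list(first)

    def column(self, analyte: str) -> np.ndarray:
        return np.array([fs[analyte] for fs in self.cells.values()])


@dataclass
class QuantComparison:
    """Cell-wise ESM/QAMS agreement plus per-analyte paired-test p-values."""

    samples: list[str]
    analytes: list[str]
    esm: np.ndarray
    qams: np.ndarray
    pair_sd: np.ndarray
    p_values: dict[str, float] = field(default_factory=dict)


def rcf_single_level(A_s: float, C_s: float, A_x: float, C_x: float) -> float:
    """RCF from one concentration level: f = (A_s/C_s) / (A_x/C_x)."""
    for name, v in (("A_s", A_s), ("C_s", C_s), ("A_x", A_x), ("C_x", C_x)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (A_s / C_s) / (A_x / C_x)


def rcf_estimate(analyte: str, levels: Mapping[str, float]) -> RCFEstimate:
    """Aggregate per-level RCFs into a mean and RSD, preserving level ids."""
    return RCFEstimate(analyte=analyte, levels=dict(levels))


def qams_quantify(
    A_x: float, A_s: float, C_s: float, f_x: float, printed_form: bool = False
) -> float:
    """Quantify an analyte from the reference peak: C_x = f_x (C_s/A_s) A_x.

    ``printed_form=True`` divides by f instead (a common typographic variant
    that does not invert the RCF definition).
    """
    for name, v in (("A_x", A_x), ("A_s", A_s), ("C_s", C_s), ("f_x", f_x)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    if printed_form:
        return A_x * C_s / (A_s * f_x)
    return f_x * (C_s / A_s) * A_x


def single_marker_sample_quant(
    table: PeakTable,
    reference_curve: CalibrationCurve,
    rcfs: Sequence[RCFEstimate],
    reference: str = REFERENCE_ANALYTE,
) -> dict[str, float]:
    """Quantify every analyte of one run from its reference peak alone.

    The reference concentration comes from ``reference_curve`` (ESM on the
    reference's own calibration); analytes without a peak in the table are
    simply absent from the result, never reported as zero.
    """
    if reference not in table.assignments:
        raise ValueError("reference peak not found")
    a_ref = table.area_of(reference)
    c_ref = esm_quantify(reference_curve, a_ref).value
    if c_ref <= 0:
        raise ValueError("reference concentration is non-positive")
    out = {reference: c_ref}
    for est in rcfs:
        if est.analyte == reference or est.analyte not in table.assignments:
            continue
        out[est.analyte] = qams_quantify(
            table.area_of(est.analyte), a_ref, c_ref, est.mean_f
        )
    return out


def robustness_summary(grid: RobustnessGrid) -> dict[str, tuple[float, float, float]]:
    """Grand mean, sample SD and RSD% per analyte over all grid cells."""
    out = {}
    for analyte in grid.analytes:
        col = grid.column(analyte)
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        out[analyte] = (mean, sd, 100.0 * sd / mean)
    return out


def compare_methods(
    esm: BatchContentMatrix, qams: BatchContentMatrix
) -> QuantComparison:
    """Pair the two quantitation methods cell by cell.

    The per-cell SD is the sample SD of the two values, |ESM - QAMS| / sqrt 2;
    the per-analyte test is a two-tailed paired t-test over samples.
    """
    problems = []
    if esm.samples != qams.samples:
        problems.append(f"samples differ: {esm.samples} vs {qams.samples}")
    if esm.analytes != qams.analytes:
        problems.append(f"analytes differ: {esm.analytes} vs {qams.analytes}")
    if problems:
        raise ValueError("; ".join(problems))
    diff = esm.values - qams.values
    pair_sd = np.abs(diff) / math.sqrt(2.0)
    p_values = {}
    for j, analyte in enumerate(esm.analytes):
        d = diff[:, j]
        if np.allclose(d, 0.0):
            p_values[analyte] = 1.0
        else:
            p_values[analyte] = float(
                stats.ttest_rel(esm.values[:, j], qams.values[:, j]).pvalue
            )
    return QuantComparison(
        samples=list(esm.samples),
        analytes=list(esm.analytes),
        esm=esm.values.copy(),
        qams=qams.values.copy(),
        pair_sd=pair_sd,
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# pipeline helpers: simulated standards -> curves and RCFs -> batch analysis
# ---------------------------------------------------------------------------


def standard_series_tables(
    response: ResponseModel | None = None,
    profile: InstrumentProfile | None = None,
    library: RRTLibrary | None = None,
    n_levels: int = 6,
    min_snr: float = 10.0,
    seed: int | None = None,
) -> list[tuple[InjectionSpec, PeakTable]]:
    """Simulate the mixed-standard dilution series and process every level."""
    response = response or ResponseModel()
    profile = profile or InstrumentProfile()
    specs = make_standard_series(response, n_levels=n_levels)
    out = []
    rng = None
    if profile.noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required for a noisy standard series")
        rng = np.random.default_rng(seed)
    for spec in specs:
        chrom = simulate_injection(spec, response, profile, rng=rng)
        out.append((spec, build_peak_table(chrom, library, min_snr=min_snr)))
    return out


def curves_from_series(
    series: Sequence[tuple[InjectionSpec, PeakTable]],
) -> dict[str, CalibrationCurve]:
    """Fit one calibration curve per analyte from processed standard levels."""
    concs: dict[str, list[float]] = {}
    areas: dict[str, list[float]] = {}
    for spec, table in series:
        for analyte in table.assignments:
            c = spec.concentrations.get(analyte)
            if c is None or c <= 0:
                continue
            concs.setdefault(analyte, []).append(c)
            areas.setdefault(analyte, []).append(table.area_of(analyte))
    return {
        analyte: fit_calibration(concs[analyte], areas[analyte], analyte)
        for analyte in concs
    }


def rcfs_from_series(
    series: Sequence[tuple[InjectionSpec, PeakTable]],
    reference: str = REFERENCE_ANALYTE,
) -> list[RCFEstimate]:
    """Per-level RCFs for every non-reference analyte of a processed series."""
    levels: dict[str, dict[str, float]] = {}
    for idx, (spec, table) in enumerate(series, start=1):
        if reference not in table.assignments:
            raise ValueError(f"reference peak not found in level {idx}")
        a_s = table.area_of(reference)
        c_s = spec.concentrations[reference]
        for analyte in table.assignments:
            if analyte == reference:
                continue
            c_x = spec.concentrations.get(analyte)
            if c_x is None or c_x <= 0:
                continue
            f = rcf_single_level(a_s, c_s, table.area_of(analyte), c_x)
            levels.setdefault(analyte, {})[f"C{idx}"] = f
    return [rcf_estimate(a, lv) for a, lv in sorted(levels.items())]


def quantify_batch(
    runs: Sequence[tuple[InjectionSpec, Chromatogram]],
    curves: Mapping[str, CalibrationCurve],
    rcfs: Sequence[RCFEstimate],
    library: RRTLibrary | None = None,
    min_snr: float = 10.0,
    reference: str = REFERENCE_ANALYTE,
) -> tuple[BatchContentMatrix, BatchContentMatrix]:
    """Quantify a batch by both methods; returns (ESM, QAMS) matrices.

    ESM uses each analyte's own curve; QAMS uses the reference curve plus the
    RCF table.  Replicates of a sample are averaged.
    """
    analytes = sorted(curves)
    esm_rows: dict[str, list[dict[str, float]]] = {}
    qams_rows: dict[str, list[dict[str, float]]] = {}
    order: list[str] = []
    for spec, chrom in runs:
        table = build_peak_table(chrom, library, min_snr=min_snr)
        esm_conc = {
            a: esm_quantify(curves[a], table.area_of(a)).value
            for a in analytes
            if a in table.assignments
        }
        qams_conc = single_marker_sample_quant(table, curves[reference], rcfs)
        if spec.label not in esm_rows:
            order.append(spec.label)
        esm_rows.setdefault(spec.label, []).append(esm_conc)
        qams_rows.setdefault(spec.label, []).append(qams_conc)

    def _collapse(rows: dict[str, list[dict[str, float]]], method: str):
        values = np.full((len(order), len(analytes)), np.nan)
        for i, sample in enumerate(order):
            for j, analyte in enumerate(analytes):
                reps = [r[analyte] for r in rows[sample] if analyte in r]
                if reps:
                    values[i, j] = float(np.mean(reps))
        return BatchContentMatrix(
            samples=list(order), analytes=list(analytes), values=values, method=method
        )

    return _collapse(esm_rows, "ESM"), _collapse(qams_rows, "QAMS")
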