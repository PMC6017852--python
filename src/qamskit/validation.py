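"""Method-validation summary statistics: stability, precision, repeatability,
reproducibility (replicate RSDs of relative retention time and relative peak
area) and recovery by standard addition.

All dispersions are sample (n-1) relative standard deviations.  Quantities
relative to the reference peak have zero dispersion for the reference itself
by construction, which is reported as an exact 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import PeakTable
from .synthetic import InjectionSpec, REFERENCE_ANALYTE

__all__ = [
    "CRITERION_DESIGNS",
    "ValidationReport",
    "RecoveryReport",
    "rsd",
    "replicate_assessment",
    "recovery_test",
]

#: Default replicate counts per validation criterion.
CRITERION_DESIGNS = {
    "stability": 5,
    "precision": 6,
    "repeatability": 6,
    "reproducibility": 12,
}


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(v.std(ddof=1)) / mean


@dataclass
class ValidationReport:
    """Replicate RSDs of RRT and RPA per analyte for one criterion."""

    criterion: str
    n: int
    rsd_rrt: dict[str, float]
    rsd_rpa: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": a,
                "criterion": self.criterion,
                "n": self.n,
                "rsd_rrt_pct": self.rsd_rrt[a],
                "rsd_rpa_pct": self.rsd_rpa[a],
            }
            for a in self.rsd_rrt
        ]
        return pd.DataFrame(rows)


def replicate_assessment(
    tables: Sequence[PeakTable],
    criterion: str,
    expected_n: int | None = None,
    reference: str = REFERENCE_ANALYTE,
) -> ValidationReport:
    """RSD of RRT and RPA per analyte across replicate peak tables.

    ``criterion`` picks the default replicate count (stability 5, precision
    6, repeatability 6, reproducibility 12); ``expected_n`` overrides it.
    Every replicate must carry every analyte of the first table.
    """
    if criterion not in CRITERION_DESIGNS and expected_n is None:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of "
            f"{sorted(CRITERION_DESIGNS)} or an explicit expected_n"
        )
    n = expected_n if expected_n is not None else CRITERION_DESIGNS[criterion]
    if len(tables) != n:
        raise ValueError(
            f"{criterion} expects {n} replicates, got {len(tables)}"
        )
    analytes = list(tables[0].assignments)
    for k, table in enumerate(tables):
        for analyte in analytes:
            if analyte not in table.assignments:
                raise ValueError(
                    f"replicate {k} is missing analyte {analyte}"
                )
    rsd_rrt, rsd_rpa = {}, {}
    for analyte in analytes:
        if analyte == reference:
            rsd_rrt[analyte] = 0.0
            rsd_rpa[analyte] = 0.0
            continue
        rsd_rrt[analyte] = rsd([t.rrt[analyte] for t in tables])
        rsd_rpa[analyte] = rsd([t.rpa[analyte] for t in tables])
    return ValidationReport(criterion=criterion, n=n, rsd_rrt=rsd_rrt, rsd_rpa=rsd_rpa)


@dataclass
class RecoveryReport:
    """Standard-addition recovery summaries, overall and per spike level."""

    mean_pct: dict[str, float]
    rsd_pct: dict[str, float]
    per_level: dict[float, dict[str, float]] = field(default_factory=dict)
    n: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": a,
                "recovery_mean_pct": self.mean_pct[a],
                "recovery_rsd_pct": self.rsd_pct[a],
                "n": self.n,
            }
            for a in self.mean_pct
        ]
        return pd.DataFrame(rows)


def recovery_test(
    base: InjectionSpec,
    spike_levels: Sequence[float],
    quantify: Callable[[InjectionSpec], Mapping[str, float]],
    replicates_per_level: int = 2,
    seed: int | None = None,
    convention: str = "marginal",
) -> RecoveryReport:
    """Standard-addition recovery at fractional spike levels of the base.

    For each spike level L and replicate, the base spec is re-simulated with
    concentrations scaled by (1 + L); recovery per analyte is

        marginal:  100 * (found_spiked - found_base) / added
        total:     100 * found_spiked / (found_base + added)

    ``quantify`` maps an :class:`InjectionSpec` to found concentrations (it
    owns simulation and peak processing).  Per-replicate seeds are derived
    from ``seed``.
    """
    if not spike_levels:
        raise ValueError("at least one spike level is required")
    if any(level <= 0 for level in spike_levels):
        raise ValueError("spike fractions must be > 0 (added amount cannot be 0)")
    if convention not in ("marginal", "total"):
        raise ValueError(f"unknown recovery convention {convention!r}")
    analytes = [a for a, c in base.concentrations.items() if c > 0]
    if not analytes:
        raise ValueError("base spec has no analyte to spike")

    seeder = np.random.default_rng(seed)

    def _derive_seed() -> int:
        return int(seeder.integers(0, 2**31 - 1))

    found_base = quantify(
        InjectionSpec(dict(base.concentrations), label="recovery-base", seed=_derive_seed())
    )

    recoveries: dict[str, list[float]] = {a: [] for a in analytes}
    per_level: dict[float, dict[str, list[float]]] = {}
    for level in spike_levels:
        per_level[level] = {a: [] for a in analytes}
        for rep in range(replicates_per_level):
            spiked = InjectionSpec(
                {a: c * (1.0 + level) for a, c in base.concentrations.items()},
                label=f"recovery-spike-{level:g}",
                replicate=rep,
                seed=_derive_seed(),
            )
            found = quantify(spiked)
            for a in analytes:
                added = base.concentrations[a] * level
                if convention == "marginal":
                    rec = 100.0 * (found[a] - found_base[a]) / added
                else:
                    rec = 100.0 * found[a] / (found_base[a] + added)
                recoveries[a].append(rec)
                per_level[level][a].append(rec)

    mean_pct = {a: float(np.mean(v)) for a, v in recoveries.items()}
    rsd_pct = {a: rsd(v) if len(v) > 1 else 0.0 for a, v in recoveries.items()}
    level_means = {
        level: {a: float(np.mean(v)) for a, v in by.items()}
        for level, by in per_level.items()
    }
    n = len(spike_levels) * replicates_per_level
    return RecoveryReport(mean_pct=mean_pct, rsd_pct=rsd_pct, per_level=level_means, n=n)
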