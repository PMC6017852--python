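"""CSV interchange formats and the packaged reference tables.

Four reference tables ship with the package (calibration curves, per-level
RCFs, the RCF robustness grid and the 20-batch content table) at full
printed precision, plus the expected summary values the ``reproduce``
command checks against.  All writers emit plain CSV whose floats round-trip
bit-identically through their own readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .chemometrics import BatchContentMatrix, ClusteringResult
from .qams import QuantComparison, RCFEstimate, RobustnessGrid
from .synthetic import Chromatogram

__all__ = [
    "FIXTURE_NAMES",
    "BatchTables",
    "load_fixture",
    "chromatogram_to_csv",
    "chromatogram_from_csv",
    "truth_to_csv",
    "peak_table_to_csv",
    "curves_to_csv",
    "curves_from_csv",
    "rcf_levels_to_csv",
    "rcf_summary_to_csv",
    "comparison_to_csv",
    "content_matrix_to_csv",
    "content_matrix_from_csv",
    "labels_to_csv",
    "newick_to_file",
]

FIXTURE_NAMES = ("calibration", "rcf_levels", "robustness", "batch_contents")

_ANALYTES_5 = ("PQ-1", "PQ-2", "PQ-3", "PQ-4", "PQ-5")
_ANALYTES_6 = ("PQ-6",) + _ANALYTES_5


@dataclass
class BatchTables:
    """The packaged 20-batch content table in its published layout."""

    esm: BatchContentMatrix
    qams: BatchContentMatrix
    pair_sd: pd.DataFrame
    total: pd.Series


def _fixture_frame(filename: str) -> pd.DataFrame:
    path = resources.files("qamskit.fixtures").joinpath(filename)
    with resources.as_file(path) as p:
        return pd.read_csv(p, float_precision="round_trip")


def load_expected_summaries() -> pd.DataFrame:
    df = _fixture_frame("expected_summaries.csv")
    return df.fillna({"item": "", "note": ""})


def load_fixture(name: str):
    """Load a packaged reference table as a typed object.

    ``calibration`` -> {analyte: CalibrationCurve};
    ``rcf_levels`` -> DataFrame (levels x analytes);
    ``robustness`` -> RobustnessGrid;
    ``batch_contents`` -> BatchTables.
    """
    if name == "calibration":
        df = _fixture_frame("calibration.csv")
        return {
            row.analyte: CalibrationCurve(
                analyte=row.analyte,
                slope=row.slope,
                intercept=row.intercept,
                r=row.r,
                range_low=row.range_low_ug_ml,
                range_high=row.range_high_ug_ml,
                lod=row.lod_ug_ml,
                loq=row.loq_ug_ml,
                n=6,
            )
            for row in df.itertuples()
        }
    if name == "rcf_levels":
        return _fixture_frame("rcf_levels.csv").set_index("level")
    if name == "robustness":
        df = _fixture_frame("robustness.csv")
        cells = {
            (row.instrument, row.column): {
                a: getattr(row, a.replace("-", "_")) for a in _ANALYTES_5
            }
            for row in df.rename(
                columns={a: a.replace("-", "_") for a in _ANALYTES_5}
            ).itertuples()
        }
        return RobustnessGrid(cells=cells)
    if name == "batch_contents":
        df = _fixture_frame("batch_contents.csv").set_index("sample")
        samples = [str(s) for s in df.index]
        esm_vals = np.column_stack(
            [df["PQ-6_esm"]] + [df[f"{a}_esm"] for a in _ANALYTES_5]
        )
        qams_vals = np.column_stack(
            [df["PQ-6_esm"]] + [df[f"{a}_qams"] for a in _ANALYTES_5]
        )
        pair_sd = df[[f"{a}_pair_sd" for a in _ANALYTES_5]].copy()
        pair_sd.columns = list(_ANALYTES_5)
        return BatchTables(
            esm=BatchContentMatrix(samples, list(_ANALYTES_6), esm_vals, "ESM"),
            qams=BatchContentMatrix(samples, list(_ANALYTES_6), qams_vals, "QAMS"),
            pair_sd=pair_sd,
            total=df["total"].copy(),
        )
    raise ValueError(
        f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
    )


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def chromatogram_to_csv(chrom: Chromatogram, path) -> None:
    pd.DataFrame({"time_min": chrom.time, "intensity": chrom.intensity}).to_csv(
        path, index=False
    )


def chromatogram_from_csv(path) -> Chromatogram:
    df = pd.read_csv(path, float_precision="round_trip")
    return Chromatogram(
        time=df["time_min"].to_numpy(), intensity=df["intensity"].to_numpy()
    )


def truth_to_csv(chrom: Chromatogram, path) -> None:
    """Ground-truth peak spec written alongside a simulated chromatogram."""
    truth = chrom.meta.get("truth", {})
    rows = [
        {
            "analyte": analyte,
            "rt_min": info["rt_min"],
            "area_true": info["area_true"],
            "conc_true": info["conc_true"],
        }
        for analyte, info in truth.items()
    ]
    pd.DataFrame(rows, columns=["analyte", "rt_min", "area_true", "conc_true"]).to_csv(
        path, index=False
    )


def peak_table_to_csv(table, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def curves_to_csv(curves: Mapping[str, CalibrationCurve], path) -> None:
    rows = [
        {
            "analyte": c.analyte,
            "slope": c.slope,
            "intercept": c.intercept,
            "r": c.r,
            "range_low_ug_ml": c.range_low,
            "range_high_ug_ml": c.range_high,
            "lod_ug_ml": c.lod if c.lod is not None else "",
            "loq_ug_ml": c.loq if c.loq is not None else "",
            "n": c.n,
        }
        for c in curves.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def curves_from_csv(path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for row in df.to_dict("records"):
        out[row["analyte"]] = CalibrationCurve(
            analyte=row["analyte"],
            slope=row["slope"],
            intercept=row["intercept"],
            r=row["r"],
            range_low=row["range_low_ug_ml"],
            range_high=row["range_high_ug_ml"],
            lod=row.get("lod_ug_ml") if not pd.isna(row.get("lod_ug_ml")) else None,
            loq=row.get("loq_ug_ml") if not pd.isna(row.get("loq_ug_ml")) else None,
            n=int(row.get("n", 0)),
        )
    return out


def rcf_levels_to_csv(rcfs: Sequence[RCFEstimate], path) -> None:
    rows = [
        {"analyte": est.analyte, "level": level, "f": f}
        for est in rcfs
        for level, f in est.levels.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def rcf_levels_from_csv(path) -> list[RCFEstimate]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for analyte, grp in df.groupby("analyte", sort=True):
        out.append(
            RCFEstimate(analyte=analyte, levels=dict(zip(grp["level"], grp["f"])))
        )
    return out


def rcf_summary_to_csv(rcfs: Sequence[RCFEstimate], path) -> None:
    rows = [
        {"analyte": est.analyte, "mean_f": est.mean_f, "rsd_pct": est.rsd_pct}
        for est in rcfs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def comparison_to_csv(comp: QuantComparison, cells_path, pvalues_path) -> None:
    rows = []
    for i, sample in enumerate(comp.samples):
        for j, analyte in enumerate(comp.analytes):
            rows.append(
                {
                    "sample": sample,
                    "analyte": analyte,
                    "esm_ug_ml": comp.esm[i, j],
                    "qams_ug_ml": comp.qams[i, j],
                    "pair_sd": comp.pair_sd[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(cells_path, index=False)
    pd.DataFrame(
        [{"analyte": a, "p_two_tailed": p} for a, p in comp.p_values.items()]
    ).to_csv(pvalues_path, index=False)


def content_matrix_to_csv(matrix: BatchContentMatrix, path) -> None:
    df = matrix.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path)


def content_matrix_from_csv(path, method: str = "ESM") -> BatchContentMatrix:
    df = pd.read_csv(path, index_col="sample", float_precision="round_trip")
    return BatchContentMatrix.from_dataframe(df, method=method)


def labels_to_csv(samples: Sequence[str], labels: Sequence[int], path) -> None:
    pd.DataFrame({"sample": samples, "group": labels}).to_csv(path, index=False)


def newick_to_file(result: ClusteringResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(result.to_newick() + "\n")
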