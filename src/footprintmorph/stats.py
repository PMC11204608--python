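"""Population summary statistics and cohort report tables.

All variability in this pipeline is reported descriptively, as the mean
with the *population* standard deviation (divisor n, not n - 1) and the
coefficient of variation CV = 100 * STD / mean in percent.  Report tables
render values rounded to two decimals, half away from zero; internal values
stay unrounded.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError

__all__ = [
    "SummaryStats",
    "population_stats",
    "mean_of_cvs",
    "aggregate_complex",
    "render_tables",
    "round_half_away",
    "load_reference_table",
    "deviation_table",
    "attachment_table",
    "morphometry_table",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, population STD and CV (%) of a list of values."""

    n: int
    mean: float
    std: float
    cv: float | None  # percent; None when the mean is zero


def population_stats(values, require_cv: bool = False) -> SummaryStats:
    """Mean, population STD (divisor n) and CV% of a value list."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise EmptyInputError("population_stats requires at least one value")
    mean = float(values.mean())
    std = float(values.std(ddof=0))
    if mean == 0:
        if require_cv:
            raise ParameterError("CV is undefined for zero mean")
        cv = None
    else:
        cv = 100.0 * std / mean
    return SummaryStats(n=int(values.size), mean=mean, std=std, cv=cv)


def mean_of_cvs(table: pd.DataFrame, cv_column: str = "cv") -> SummaryStats:
    """Summary of the per-entity CV values of a cohort table.

    Variation across entities (bones, attachments, femoral parameters) is
    condensed as the mean +/- population STD of their individual CVs.
    """
    if cv_column not in table.columns:
        raise ParameterError(f"table has no column {cv_column!r}")
    values = table[cv_column].dropna()
    if values.empty:
        raise EmptyInputError("no CV entries to summarise")
    return population_stats(values)


def aggregate_complex(component_means: dict[str, float]) -> tuple[float, list[str]]:
    """Sum of component mean areas (mm^2) for a muscle complex.

    Used for aggregates such as the conjoined hamstring tendon (long head of
    biceps femoris + semitendinosus origins) or the overall hamstring origin
    (adding the semimembranosus origin).  Returns the sum and the component
    provenance list.
    """
    if not component_means:
        raise EmptyInputError("aggregate_complex requires at least one component")
    names = sorted(component_means)
    return float(sum(component_means[k] for k in names)), names


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (report rendering convention).

    Binary representation noise is removed (at 1e-6 of the last kept digit)
    before applying the half step, so decimal ties like 405.375 -> 405.38
    round as they would on paper.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    scaled = np.round(x * factor, 6)
    out = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def _summary_frame(groups: dict[str, np.ndarray], decimals: int = 2) -> pd.DataFrame:
    rows = []
    for key, values in groups.items():
        s = population_stats(values)
        rows.append(
            {
                "entity": key,
                "n": s.n,
                "mean": round_half_away(s.mean, decimals),
                "std": round_half_away(s.std, decimals),
                "cv": round_half_away(s.cv, decimals) if s.cv is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["entity", "n", "mean", "std", "cv"])


def deviation_table(deviations: pd.DataFrame) -> pd.DataFrame:
    """Per-bone (and overall) summary of repeat-scan surface deviations.

    Input columns: ``specimen``, ``bone``, ``scan``, ``mean_mm``.  Output:
    one summary row per bone plus an ``all`` row over every deviation value.
    """
    _require(deviations, ["specimen", "bone", "scan", "mean_mm"])
    if deviations.empty:
        return pd.DataFrame(columns=["entity", "n", "mean", "std", "cv"])
    groups = {
        bone: grp["mean_mm"].to_numpy() for bone, grp in deviations.groupby("bone", sort=True)
    }
    groups["all"] = deviations["mean_mm"].to_numpy()
    return _summary_frame(groups)


def morphometry_table(metrics: pd.DataFrame, value_columns: list[str]) -> pd.DataFrame:
    """Cohort summary (mean/STD/CV per column) of per-specimen morphometrics."""
    _require(metrics, value_columns)
    if metrics.empty:
        return pd.DataFrame(columns=["entity", "n", "mean", "std", "cv"])
    groups = {col: metrics[col].dropna().to_numpy() for col in value_columns}
    return _summary_frame(groups)


def attachment_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Per-attachment cohort summary of footprint areas and centroids.

    Input columns: ``attachment``, ``specimen``, ``area_mm2`` and optionally
    centroid columns ``cx, cy, cz``.  Output mirrors the attachment report:
    mean +/- STD of the area, its CV, and mean +/- STD per centroid axis.
    """
    _require(areas, ["attachment", "specimen", "area_mm2"])
    if areas.empty:
        return pd.DataFrame(columns=["attachment", "n", "area_mean", "area_std", "cv"])
    rows = []
    for name, grp in areas.groupby("attachment", sort=True):
        s = population_stats(grp["area_mm2"].to_numpy())
        row = {
            "attachment": name,
            "n": s.n,
            "area_mean": round_half_away(s.mean),
            "area_std": round_half_away(s.std),
            "cv": round_half_away(s.cv) if s.cv is not None else np.nan,
        }
        for axis in ("cx", "cy", "cz"):
            if axis in grp.columns:
                a = population_stats(grp[axis].to_numpy())
                row[f"{axis}_mean"] = round_half_away(a.mean)
                row[f"{axis}_std"] = round_half_away(a.std)
        rows.append(row)
    return pd.DataFrame(rows)


def render_tables(
    deviations: pd.DataFrame | None = None,
    bone_morphology: pd.DataFrame | None = None,
    femoral: pd.DataFrame | None = None,
    attachments: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Render the full cohort report table set from per-specimen metric CSVs.

    Produces (where inputs are given) the deviation summary, the bone
    morphology summary (volume / surface area / center of gravity), the
    femoral-parameter summary (MA, TEA, FHD, SD) and the attachment
    footprint summary, each with 2-decimal rounding.
    """
    out: dict[str, pd.DataFrame] = {}
    if deviations is not None:
        out["deviation"] = deviation_table(deviations)
    if bone_morphology is not None:
        _require(bone_morphology, ["specimen", "bone", "volume_mm3", "sa_mm2"])
        if bone_morphology.empty:
            out["bone_morphology"] = pd.DataFrame(
                columns=["entity", "n", "mean", "std", "cv"]
            )
        else:
            groups = {}
            for bone, grp in bone_morphology.groupby("bone", sort=True):
                groups[f"{bone}:volume_mm3"] = grp["volume_mm3"].to_numpy()
                groups[f"{bone}:sa_mm2"] = grp["sa_mm2"].to_numpy()
            out["bone_morphology"] = _summary_frame(groups)
    if femoral is not None:
        out["femoral"] = morphometry_table(femoral, ["MA", "TEA", "FHD", "SD"])
    if attachments is not None:
        out["attachment"] = attachment_table(attachments)
    return out


def _require(df: pd.DataFrame, columns: list[str]):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParameterError(f"input table is missing required columns: {missing}")


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the bundled reference cohort tables.

    These CSVs encode the printed per-specimen / per-entity values of a
    published four-specimen cadaveric knee study (surface deviations,
    femoral morphometrics, bone-morphology CVs and attachment footprint
    summaries) and serve as regression inputs for the statistics layer.
    Available names: ``deviations``, ``femoral``, ``bone_morphology``,
    ``attachments``.
    """
    fname = {
        "deviations": "reference_deviations_mm.csv",
        "femoral": "reference_femoral_morphometrics.csv",
        "bone_morphology": "reference_bone_morphology.csv",
        "attachments": "reference_attachment_footprints.csv",
    }.get(name)
    if fname is None:
        raise ParameterError(f"unknown reference table {name!r}")
    ref = importlib.resources.files("footprintmorph.data") / fname
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
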