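"""Rule-based typing of cultivated-land degradation.

Each unit receives five diagnoses: a *composite* one from the change in its
count-based composite quality grade, and four *single-type* ones, each a
two-stage rule — a vegetation-index screening gate followed by a severity
read from the change in the type's diagnostic soil-property grade:

    acidification       gate: RVI decreasing            severity: pH grade drop
    fertility_decline   gate: NDVI decreasing           severity: SOM grade drop
    erosion             gate: slope > 5 deg AND
                              DVI increasing            severity: SOM grade drop
    physical_structure  gate: DVI decreasing            severity: BD grade drop

If the gate fails the severity is *none* regardless of the property change;
otherwise the shared level-drop mapping applies (one level down -> slight,
two -> moderate, three or more -> severe; no drop -> none).  Erosion reads
its severity from the SOM grade ladder — loss of topsoil shows up as loss of
organic matter — since that is the property ladder shared with fertility.
Types are diagnosed independently: a unit can carry several at once, so
per-type degraded areas may overlap and need not sum to the composite area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grading, indices, quality

DEGRADATION_TYPES = (
    "composite",
    "acidification",
    "fertility_decline",
    "erosion",
    "physical_structure",
)

#: slope threshold (degrees) gating the erosion rule
EROSION_SLOPE_DEG = 5.0

# single-type rules: (gate flag column on the index-change table, property)
_SINGLE_TYPE_RULES = {
    "acidification": ("rvi_decreasing", "ph"),
    "fertility_decline": ("ndvi_decreasing", "som"),
    "erosion": ("dvi_increasing", "som"),
    "physical_structure": ("dvi_decreasing", "bd"),
}


@dataclass(frozen=True)
class TypeDiagnosis:
    """One (unit, degradation type) verdict with its evidence."""

    unit_id: object
    dtype: str
    severity: str
    gate_passed: bool
    grade_early: int | None = None
    grade_late: int | None = None


def _severity(gate: bool, grade_early: int, grade_late: int) -> str:
    if not gate:
        return "none"
    return quality.severity_from_delta(int(grade_early) - int(grade_late))


def diagnose_acidification(change, ph_grades: tuple[int, int]) -> TypeDiagnosis:
    """Acidification: RVI-decline gate, then pH grade drop."""
    gate = bool(change["rvi_decreasing"])
    return TypeDiagnosis(
        change.get("unit_id"), "acidification", _severity(gate, *ph_grades), gate, *ph_grades
    )


def diagnose_fertility(change, som_grades: tuple[int, int]) -> TypeDiagnosis:
    """Fertility decline: NDVI-decline gate, then SOM grade drop."""
    gate = bool(change["ndvi_decreasing"])
    return TypeDiagnosis(
        change.get("unit_id"), "fertility_decline", _severity(gate, *som_grades), gate, *som_grades
    )


def diagnose_erosion(unit, change, som_grades: tuple[int, int]) -> TypeDiagnosis:
    """Erosion: slope > 5 deg and DVI rising, then SOM grade drop."""
    gate = float(unit["slope"]) > EROSION_SLOPE_DEG and bool(change["dvi_increasing"])
    return TypeDiagnosis(
        change.get("unit_id"), "erosion", _severity(gate, *som_grades), gate, *som_grades
    )


def diagnose_physical(change, bd_grades: tuple[int, int]) -> TypeDiagnosis:
    """Physical-structure degradation: DVI-decline gate, then BD grade drop."""
    gate = bool(change["dvi_decreasing"])
    return TypeDiagnosis(
        change.get("unit_id"), "physical_structure", _severity(gate, *bd_grades), gate, *bd_grades
    )


def diagnose_all(
    units: pd.DataFrame,
    soil: pd.DataFrame,
    spectral: pd.DataFrame,
    thresholds: grading.ThresholdTable | None = None,
    eps: float = 0.0,
    epoch_years: tuple[int, int] = (2012, 2019),
) -> pd.DataFrame:
    """Run all five diagnoses for every complete unit.

    Returns a long table with one row per (unit, dtype): columns ``unit_id,
    dtype, severity, gate_passed, grade_early, grade_late`` (composite rows
    carry the composite grades as evidence).  Units lacking a soil or
    spectral epoch are excluded; their count is attached as
    ``result.attrs["n_incomplete"]``.
    """
    thresholds = thresholds or grading.load_thresholds()
    y1, y2 = epoch_years

    complete = units["unit_id"]
    for table, cols in ((soil, ("som", "tn", "ph", "bd")), (spectral, ("nir", "red"))):
        for year in (y1, y2):
            sub = table[table["epoch_year"] == year]
            ok = sub.loc[sub[list(cols)].notna().all(axis=1), "unit_id"]
            complete = complete[complete.isin(ok)]
    n_incomplete = len(units) - len(complete)
    units = units[units["unit_id"].isin(complete)]
    soil = soil[soil["unit_id"].isin(complete)]
    spectral = spectral[spectral["unit_id"].isin(complete)]

    grades = grading.grade_table(units, soil, thresholds)
    changes = indices.index_changes(spectral, epoch_years, eps).set_index("unit_id")
    g1 = grades[grades["epoch_year"] == y1].set_index("unit_id")
    g2 = grades[grades["epoch_year"] == y2].set_index("unit_id")
    uid = units.set_index("unit_id").index
    g1, g2, changes = g1.loc[uid], g2.loc[uid], changes.loc[uid]
    slope = units.set_index("unit_id").loc[uid, "slope"].to_numpy(float)

    frames = []

    comp = quality.quality_table(grades, epoch_years).set_index("unit_id").loc[uid]
    frames.append(
        pd.DataFrame(
            {
                "unit_id": uid,
                "dtype": "composite",
                "severity": comp["severity"].to_numpy(),
                "gate_passed": True,
                "grade_early": comp[f"grade_{y1}"].to_numpy(),
                "grade_late": comp[f"grade_{y2}"].to_numpy(),
            }
        )
    )

    for dtype, (flag, prop) in _SINGLE_TYPE_RULES.items():
        gate = changes[flag].to_numpy(bool)
        if dtype == "erosion":
            gate = gate & (slope > EROSION_SLOPE_DEG)
        e, l = g1[f"{prop}_grade"].to_numpy(int), g2[f"{prop}_grade"].to_numpy(int)
        sev = np.where(gate, quality.severity_from_delta_array(e - l), "none")
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": uid,
                    "dtype": dtype,
                    "severity": sev,
                    "gate_passed": gate,
                    "grade_early": e,
                    "grade_late": l,
                }
            )
        )

    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_incomplete"] = n_incomplete
    return out
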