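"""Per-indicator grading of cultivated-land evaluation units.

Five indicators — soil organic matter (SOM, g/kg), total nitrogen (TN, g/kg),
pH, bulk density (BD, g/cm^3) and slope (degrees) — are each classified into
four quality grades (1 best .. 4 worst) against a land-use-specific threshold
table.  The default table ships with the package
(``degradiag/data/thresholds.yaml``) and mirrors the Chinese cultivated-land
quality grade standard bands for a southern paddy/dryland county; users may
load their own table with :func:`load_thresholds`.

Grading convention: the four classes of an indicator are scanned best to
worst with closed interval bounds, and the first class containing the value
wins.  A value sitting exactly on a boundary between two classes therefore
resolves to the better (lower-numbered) grade.  BD is V-shaped — an optimal
density band flanked by too-loose and too-compacted classes — so its classes
are unions of intervals; all other indicators are monotone ladders.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

INDICATORS = ("som", "tn", "ph", "bd", "slope")
LAND_USES = ("paddy", "dryland")

#: physical value ranges accepted per indicator (closed on finite ends)
PHYSICAL_RANGE: Mapping[str, tuple[float, float]] = {
    "som": (0.0, np.inf),
    "tn": (0.0, np.inf),
    "ph": (0.0, 14.0),
    "bd": (0.0, np.inf),
    "slope": (0.0, 90.0),
}


class ValidationError(ValueError):
    """A value is non-finite or outside its physical range."""


class SchemaError(KeyError):
    """Unknown indicator, land use, or malformed threshold table."""


class IncompleteRecordError(ValueError):
    """A unit is missing one of the five grading inputs."""


@dataclass(frozen=True)
class ThresholdTable:
    """Grade classes per (indicator, land_use).

    ``classes[indicator][land_use]`` is a best-first list of four classes;
    each class is a tuple of closed ``(low, high)`` intervals.
    """

    classes: Mapping[str, Mapping[str, Sequence[Sequence[tuple[float, float]]]]]

    def __post_init__(self) -> None:
        for ind in INDICATORS:
            if ind not in self.classes:
                raise SchemaError(f"threshold table missing indicator {ind!r}")
            for lu in LAND_USES:
                if lu not in self.classes[ind]:
                    raise SchemaError(f"{ind!r} missing land use {lu!r}")
                if len(self.classes[ind][lu]) != 4:
                    raise SchemaError(f"{ind!r}/{lu!r} must define exactly 4 classes")

    def intervals(self, indicator: str, land_use: str, grade: int) -> Sequence[tuple[float, float]]:
        """Closed intervals forming the class of ``grade`` (1..4)."""
        return self.classes[indicator][land_use][grade - 1]


def load_thresholds(path: str | Path | None = None) -> ThresholdTable:
    """Load a threshold table from YAML; the packaged default when ``path`` is None."""
    if path is None:
        text = resources.files("degradiag").joinpath("data/thresholds.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    classes = {
        ind: {
            lu: [tuple((float(lo), float(hi)) for lo, hi in cls) for cls in raw[ind][lu]]
            for lu in raw[ind]
        }
        for ind in raw
    }
    return ThresholdTable(classes)


def _check_value(value: float, indicator: str) -> float:
    if indicator not in INDICATORS:
        raise SchemaError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    v = float(value)
    lo, hi = PHYSICAL_RANGE[indicator]
    if not np.isfinite(v) or v < lo or v > hi:
        raise ValidationError(f"{indicator}={value!r} outside physical range [{lo}, {hi}]")
    return v


def grade_indicator(
    value: float, indicator: str, land_use: str, thresholds: ThresholdTable | None = None
) -> int:
    """Grade a single indicator value (1 best .. 4 worst).

    Boundary values resolve to the better grade (best-first scan, closed
    bounds, first match wins).
    """
    thresholds = thresholds or load_thresholds()
    v = _check_value(value, indicator)
    if land_use not in LAND_USES:
        raise SchemaError(f"unknown land use {land_use!r}")
    for grade in (1, 2, 3, 4):
        for lo, hi in thresholds.intervals(indicator, land_use, grade):
            if lo <= v <= hi:
                return grade
    raise ValidationError(  # pragma: no cover - default table is total
        f"{indicator}={v} not covered by any grade class"
    )


def grade_band(
    value: float, indicator: str, land_use: str, thresholds: ThresholdTable | None = None
) -> tuple[int, float, float]:
    """Return ``(grade, low, high)`` of the interval that captured ``value``."""
    thresholds = thresholds or load_thresholds()
    g = grade_indicator(value, indicator, land_use, thresholds)
    for lo, hi in thresholds.intervals(indicator, land_use, g):
        if lo <= float(value) <= hi:
            return g, lo, hi
    raise ValidationError(f"no band for {indicator}={value}")  # pragma: no cover


def grade_unit(
    unit: Mapping, soil: Mapping, thresholds: ThresholdTable | None = None
) -> dict:
    """Grade one evaluation unit for one soil epoch.

    ``unit`` supplies ``land_use`` and ``slope`` (slope is a property of the
    parcel, shared by both epochs); ``soil`` supplies ``som``, ``tn``, ``ph``,
    ``bd`` for its ``epoch_year``.  Returns a dict with the five grades.
    """
    thresholds = thresholds or load_thresholds()
    values = {
        "som": soil.get("som"),
        "tn": soil.get("tn"),
        "ph": soil.get("ph"),
        "bd": soil.get("bd"),
        "slope": unit.get("slope"),
    }
    missing = [k for k, v in values.items() if v is None or not np.isfinite(float(v))]
    if missing or "land_use" not in unit:
        raise IncompleteRecordError(
            f"unit {unit.get('unit_id')!r} missing inputs: {missing or ['land_use']}"
        )
    lu = unit["land_use"]
    return {
        "unit_id": unit.get("unit_id"),
        "epoch_year": soil.get("epoch_year"),
        **{f"{ind}_grade": grade_indicator(values[ind], ind, lu, thresholds) for ind in INDICATORS},
    }


def grade_table(
    units: pd.DataFrame, soil: pd.DataFrame, thresholds: ThresholdTable | None = None
) -> pd.DataFrame:
    """Vectorised grading of a full soil table (both epochs).

    ``units`` needs columns ``unit_id, land_use, slope``; ``soil`` needs
    ``unit_id, epoch_year, som, tn, ph, bd``.  Returns one row per
    (unit, epoch) with columns ``som_grade .. slope_grade``.
    """
    thresholds = thresholds or load_thresholds()
    merged = soil.merge(units[["unit_id", "land_use", "slope"]], on="unit_id", how="left")
    if merged["land_use"].isna().any():
        bad = merged.loc[merged["land_use"].isna(), "unit_id"].tolist()[:5]
        raise IncompleteRecordError(f"soil rows reference unknown units, e.g. {bad}")
    out = merged[["unit_id", "epoch_year"]].copy()
    for ind in INDICATORS:
        vals = merged["slope"].to_numpy(float) if ind == "slope" else merged[ind].to_numpy(float)
        grades = np.zeros(len(merged), dtype=int)
        for lu in LAND_USES:
            sel = (merged["land_use"] == lu).to_numpy()
            if not sel.any():
                continue
            v = vals[sel]
            lo_r, hi_r = PHYSICAL_RANGE[ind]
            if not np.all(np.isfinite(v) & (v >= lo_r) & (v <= hi_r)):
                raise ValidationError(f"{ind} contains values outside [{lo_r}, {hi_r}]")
            g = np.zeros(v.shape, dtype=int)
            for grade in (4, 3, 2, 1):  # best-first precedence via overwrite
                hit = np.zeros(v.shape, dtype=bool)
                for lo, hi in thresholds.intervals(ind, lu, grade):
                    hit |= (v >= lo) & (v <= hi)
                g = np.where(hit, grade, g)
            grades[sel] = g
        if (grades == 0).any():
            raise ValidationError(f"{ind}: some values not covered by any grade class")
        out[f"{ind}_grade"] = grades
    return out
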