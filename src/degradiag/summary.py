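"""Area-weighted aggregation of degradation diagnoses.

Produces the county-level severity-by-type matrix (area in km^2 and share of
total cultivated area, with a total-degraded column = slight + moderate +
severe) and a per-township breakdown used for mapping the spatial pattern of
each degradation type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import DEGRADATION_TYPES
from .quality import SEVERITY_LEVELS

_SEV_ORDER = {s: i for i, s in enumerate(SEVERITY_LEVELS)}


class AlignmentError(ValueError):
    """A diagnosis references a unit with no area record."""


def _join_area(diagnoses: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    merged = diagnoses.merge(units[["unit_id", "area", "township_id"]], on="unit_id", how="left")
    if merged["area"].isna().any():
        bad = merged.loc[merged["area"].isna(), "unit_id"].unique()[:5]
        raise AlignmentError(f"diagnoses reference units without areas, e.g. {list(bad)}")
    return merged


def summarize(diagnoses: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """County summary: per degradation type, area and percentage by severity.

    Percentages are taken against the total cultivated area (the per-type
    none/slight/moderate/severe shares sum to 100).  Column
    ``total_degraded_*`` is the slight+moderate+severe sum.
    """
    merged = _join_area(diagnoses, units)
    total_area = float(units["area"].sum())
    rows = []
    for dtype in DEGRADATION_TYPES:
        sub = merged[merged["dtype"] == dtype]
        areas = {s: float(sub.loc[sub["severity"] == s, "area"].sum()) for s in SEVERITY_LEVELS}
        degraded = sum(areas[s] for s in ("slight", "moderate", "severe"))
        row = {"dtype": dtype}
        for s in SEVERITY_LEVELS:
            row[f"{s}_km2"] = areas[s]
            row[f"{s}_pct"] = 100.0 * areas[s] / total_area
        row["total_degraded_km2"] = degraded
        row["total_degraded_pct"] = 100.0 * degraded / total_area
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["total_area_km2"] = total_area
    return out


def township_aggregate(diagnoses: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Per (township, dtype): degraded area, share of township area, modal severity.

    The modal severity is over degraded units only; ties break toward the
    worse severity (conservative for mapping).  Townships with no degraded
    units report share 0 and modal severity ``none``.
    """
    merged = _join_area(diagnoses, units)
    town_area = units.groupby("township_id")["area"].sum()
    rows = []
    for (town, dtype), sub in merged.groupby(["township_id", "dtype"], sort=True):
        deg = sub[sub["severity"] != "none"]
        degraded_area = float(deg["area"].sum())
        if degraded_area > 0:
            by_sev = deg.groupby("severity")["area"].sum()
            top = by_sev.max()
            modal = max(
                (s for s in by_sev.index if by_sev[s] == top), key=lambda s: _SEV_ORDER[s]
            )
        else:
            modal = "none"
        rows.append(
            {
                "township_id": town,
                "dtype": dtype,
                "degraded_km2": degraded_area,
                "degraded_pct": 100.0 * degraded_area / float(town_area[town]),
                "modal_severity": modal,
            }
        )
    return pd.DataFrame(rows)
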