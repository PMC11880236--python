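"""Composite cultivated-land quality grade and two-epoch degradation.

The composite grade of a unit is a purely count-based rule over its five
indicator grades.  With n_j the number of indicators at grade j
(n_1+n_2+n_3+n_4 = 5):

    grade 1  if n_2+n_3 <= 1 and n_4 = 0
    grade 2  if 2 <= n_2+n_3 <= 3 and n_4 = 0
    grade 3  if 4 <= n_2+n_3 <= 5 and n_4 = 0, or n_4 = 1
    grade 4  if n_4 >= 2

The degradation grade of a unit between the two survey epochs is
``delta = grade_early - grade_late``; a negative delta means the composite
grade worsened.  Severity follows the level-drop mapping: 0 or better ->
none, -1 -> slight, -2 -> moderate, -3 or worse -> severe.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

SEVERITY_LEVELS = ("none", "slight", "moderate", "severe")

GRADE_COLUMNS = ["som_grade", "tn_grade", "ph_grade", "bd_grade", "slope_grade"]


class GradeValidationError(ValueError):
    """An indicator or composite grade outside 1..4, or |delta| > 3."""


def composite_grade(grades) -> int:
    """Composite quality grade (1..4) from five indicator grades.

    Depends only on the counts of grades, not their order.  The grade-4
    condition is tested first, then 3, 2, 1, keeping the rule deterministic
    even under user-edited (possibly overlapping) conditions.
    """
    g = [int(x) for x in grades]
    if len(g) != 5 or any(x < 1 or x > 4 for x in g):
        raise GradeValidationError(f"need five grades in 1..4, got {grades!r}")
    n4 = g.count(4)
    n23 = g.count(2) + g.count(3)
    if n4 >= 2:
        return 4
    if n4 == 1 or n23 >= 4:
        return 3
    if n23 >= 2:
        return 2
    return 1


def composite_grade_array(grade_matrix: np.ndarray) -> np.ndarray:
    """Vectorised :func:`composite_grade` over an (n, 5) integer matrix."""
    g = np.asarray(grade_matrix, dtype=int)
    if g.ndim != 2 or g.shape[1] != 5:
        raise GradeValidationError(f"expected (n, 5) grade matrix, got {g.shape}")
    if ((g < 1) | (g > 4)).any():
        raise GradeValidationError("indicator grades must lie in 1..4")
    n4 = (g == 4).sum(axis=1)
    n23 = ((g == 2) | (g == 3)).sum(axis=1)
    out = np.ones(len(g), dtype=int)
    out[n23 >= 2] = 2
    out[(n23 >= 4) | (n4 == 1)] = 3
    out[n4 >= 2] = 4
    return out


def degradation_delta(grade_early: int, grade_late: int) -> int:
    """Signed degradation grade: early minus late composite grade.

    Positive = the unit improved (no degradation); negative = degradation.
    """
    for g in (grade_early, grade_late):
        if not 1 <= int(g) <= 4:
            raise GradeValidationError(f"composite grade {g!r} outside 1..4")
    return int(grade_early) - int(grade_late)


def severity_from_delta(delta: int) -> str:
    """Map a signed grade change to none/slight/moderate/severe."""
    d = int(delta)
    if abs(d) > 3:
        raise GradeValidationError(f"|delta| cannot exceed 3, got {d}")
    if d >= 0:
        return "none"
    return SEVERITY_LEVELS[min(-d, 3)]


def severity_from_delta_array(delta: np.ndarray) -> np.ndarray:
    d = np.asarray(delta, dtype=int)
    if (np.abs(d) > 3).any():
        raise GradeValidationError("|delta| cannot exceed 3")
    lev = np.clip(-d, 0, 3)
    return np.asarray(SEVERITY_LEVELS, dtype=object)[lev]


def enumerate_grade_space() -> pd.DataFrame:
    """All 4^5 = 1024 five-tuples of indicator grades with their composite grade.

    Serves as the exhaustive oracle for partition-completeness and
    monotonicity checks of the composite rule.
    """
    rows = [(*t, composite_grade(t)) for t in product((1, 2, 3, 4), repeat=5)]
    return pd.DataFrame(rows, columns=GRADE_COLUMNS + ["grade"])


def quality_table(grades: pd.DataFrame, epoch_years: tuple[int, int]) -> pd.DataFrame:
    """Per-unit composite grades for both epochs, delta and severity.

    ``grades`` is the output of :func:`degradiag.grading.grade_table` and must
    contain both epochs for every unit.
    """
    y1, y2 = epoch_years
    wide = {}
    for year in (y1, y2):
        sub = grades[grades["epoch_year"] == year]
        if sub.empty:
            raise GradeValidationError(f"no grade rows for epoch {year}")
        wide[year] = sub.set_index("unit_id")
    common = wide[y1].index.intersection(wide[y2].index)
    missing = len(wide[y1].index.union(wide[y2].index)) - len(common)
    if missing:
        raise GradeValidationError(f"{missing} units lack one of the two epochs")
    out = pd.DataFrame({"unit_id": common})
    for year in (y1, y2):
        mat = wide[year].loc[common, GRADE_COLUMNS].to_numpy()
        out[f"grade_{year}"] = composite_grade_array(mat)
    out["delta"] = out[f"grade_{y1}"] - out[f"grade_{y2}"]
    out["severity"] = severity_from_delta_array(out["delta"].to_numpy())
    return out
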