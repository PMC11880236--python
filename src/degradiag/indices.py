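"""Vegetation indices from per-unit NIR/RED reflectance and their two-epoch changes.

Three classic broadband indices:

    RVI  = NIR / RED          (ratio vegetation index)
    NDVI = (NIR - RED) / (NIR + RED)
    DVI  = NIR - RED          (difference vegetation index)

The degradation diagnostics screen units on the *sign* of each index change
between the two survey epochs: an index is flagged decreasing when its delta
is below ``-eps`` and increasing when above ``+eps`` (strict comparisons, so
at the default ``eps = 0`` a zero delta is neither).  The module also provides
a Pearson correlation screen used to validate that, on a given dataset, the
index changes actually track the soil-property changes the rules assume
(falling RVI with falling pH, falling NDVI with falling SOM, DVI moving
against bulk density).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class DomainError(ValueError):
    """Reflectance input outside the domain of an index."""


class AlignmentError(ValueError):
    """Units missing one of the two epochs, or mismatched series."""


class UndefinedCorrelationError(ValueError):
    """Zero variance makes the Pearson correlation undefined."""


def _as_arrays(nir, red) -> tuple[np.ndarray, np.ndarray]:
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if not (np.all(np.isfinite(nir)) and np.all(np.isfinite(red))):
        raise DomainError("reflectance values must be finite")
    return nir, red


def rvi(nir, red):
    """Ratio vegetation index NIR/RED; requires RED > 0."""
    nir, red = _as_arrays(nir, red)
    if np.any(red <= 0):
        raise DomainError("RVI undefined for RED <= 0")
    return nir / red


def ndvi(nir, red):
    """Normalised difference vegetation index; in [-1, 1] for non-negative bands."""
    nir, red = _as_arrays(nir, red)
    if np.any(nir + red <= 0):
        raise DomainError("NDVI undefined for NIR + RED <= 0")
    return (nir - red) / (nir + red)


def dvi(nir, red):
    """Difference vegetation index NIR - RED."""
    nir, red = _as_arrays(nir, red)
    return nir - red


def index_changes(
    spectral: pd.DataFrame, epoch_years: tuple[int, int], eps: float = 0.0
) -> pd.DataFrame:
    """Per-unit index deltas (late minus early) with screening flags.

    ``spectral`` has columns ``unit_id, epoch_year, nir, red`` with exactly one
    row per (unit, epoch).  Returns one row per unit with ``d_rvi, d_ndvi,
    d_dvi`` and, per index, ``<ix>_decreasing`` / ``<ix>_increasing`` booleans
    at tolerance ``eps``.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    y1, y2 = epoch_years
    epochs = {}
    for year in (y1, y2):
        sub = spectral[spectral["epoch_year"] == year]
        if sub["unit_id"].duplicated().any():
            raise AlignmentError(f"duplicate spectral rows in epoch {year}")
        epochs[year] = sub.set_index("unit_id")
    common = epochs[y1].index.intersection(epochs[y2].index)
    n_union = len(epochs[y1].index.union(epochs[y2].index))
    if len(common) != n_union:
        raise AlignmentError(f"{n_union - len(common)} units missing a spectral epoch")
    out = pd.DataFrame({"unit_id": common})
    for name, fn in (("rvi", rvi), ("ndvi", ndvi), ("dvi", dvi)):
        early = fn(epochs[y1].loc[common, "nir"], epochs[y1].loc[common, "red"])
        late = fn(epochs[y2].loc[common, "nir"], epochs[y2].loc[common, "red"])
        d = np.asarray(late) - np.asarray(early)
        out[f"d_{name}"] = d
        out[f"{name}_decreasing"] = d < -eps
        out[f"{name}_increasing"] = d > eps
    return out


def correlation_screen(x, y) -> tuple[float, float]:
    """Pearson r and two-sided t-based p-value between two delta series.

    Used to check (and warn) that a screening index is actually coupled to
    its soil property on the data at hand.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("x and y must be 1-d series of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
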