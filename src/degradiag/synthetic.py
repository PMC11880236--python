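"""Seeded synthetic-county generator.

Real county-scale soil-testing datasets of the kind the diagnostics target
(two-epoch SOM/TN/pH/BD records on a cultivated-land parcel map plus driver
covariates) are administrative and rarely public, so this module generates
counties with the statistical structure the pipeline assumes:

* parcels with a plains/hills slope mixture, paddy/dryland split, areas and
  spatial township blocks;
* eleven driver covariates on realistic scales (elevation, aspect, slope,
  precipitation, temperature, distances to rivers/roads, population, GDP,
  straw-return rate, fertilizer rate) with mild, VIF-safe correlations;
* two-epoch soil trajectories in which each degradation type is *planted* on
  the units with the highest latent propensity — a linear function of the
  configured driver effects plus noise — at the configured per-type rate.
  Planted units cross 1–3 grade-class boundaries of their diagnostic
  property (drawn from a severity mix); all other units drift only within
  their grade band, so the planted labels are the exact ground truth of the
  grading rules;
* two-epoch NIR/RED reflectance whose index changes are coupled to the soil
  property changes by a Gaussian-copula construction: falling RVI with
  falling pH, falling NDVI with falling SOM, DVI moving against bulk
  density, and a positive DVI push on eroded slopes.

Because NDVI is a monotone transform of RVI, the RVI–pH and NDVI–SOM
coupling targets cannot both be arbitrary when pH and SOM changes are
uncorrelated; the generator therefore correlates the two soil-delta series
(shared fertilizer effect plus correlated within-band jitter) and solves a
two-target weight system, rescaling to the feasible boundary when the
request is jointly infeasible.

Everything is driven by one integer seed fanned out to per-stage child
seeds, so runs are bit-reproducible and stages individually replayable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import grading

SINGLE_TYPES = ("acidification", "fertility_decline", "erosion", "physical_structure")

#: soil property read by each single degradation type
TYPE_PROPERTY = {
    "acidification": "ph",
    "fertility_decline": "som",
    "erosion": "som",
    "physical_structure": "bd",
}

# worsening direction per property: which side of the ladder degradation moves to
_BAND_WIDTH = {"som": 4.0, "tn": 4.0, "ph": 0.4, "bd": 0.08}
_BAND_MARGIN = {"som": 0.05, "tn": 0.05, "ph": 0.01, "bd": 0.005}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PartialDatasetError(FileNotFoundError):
    """A dataset directory is missing one of its mandatory blocks."""


class DataAlignmentError(ValueError):
    """Unit ids of two generated blocks do not match."""


def _default_driver_effects() -> dict:
    # signed propensity coefficients (positive = exacerbates degradation);
    # directions follow the attribution findings these simulations emulate:
    # precipitation mitigates, fertilizer overuse exacerbates, straw return
    # mitigates, steep slopes erode, structure degrades away from rivers.
    return {
        "acidification": {"far": 1.0, "map": -1.0},
        "fertility_decline": {"far": 0.8, "map": -0.8, "srr": -0.8},
        "erosion": {"slope": 1.0, "map": -0.5},
        "physical_structure": {"srr": -1.0, "slope": 0.5, "dist_rivers": 0.5},
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic county; defaults are the reference scenario."""

    n_units: int = 2000
    seed: int = 0
    paddy_fraction: float = 0.65
    epoch_years: tuple[int, int] = (2012, 2019)
    n_townships: int = 9
    hills_weight: float = 0.30
    degradation_rates: dict = field(
        default_factory=lambda: {
            "acidification": 0.20,
            "fertility_decline": 0.15,
            "erosion": 0.02,
            "physical_structure": 0.03,
        }
    )
    index_coupling: dict = field(
        default_factory=lambda: {"rvi_ph": 0.8, "ndvi_som": 0.8, "dvi_bd": -0.8}
    )
    driver_effects: dict = field(default_factory=_default_driver_effects)
    severity_mix: tuple[float, float, float] = (0.80, 0.18, 0.02)
    propensity_noise: float = 0.5
    noise_scales: dict = field(
        default_factory=lambda: {"som": 0.8, "tn": 0.8, "ph": 0.06, "bd": 0.025}
    )
    jitter_corr: float = 0.6

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if not 0.0 <= self.paddy_fraction <= 1.0:
            raise ConfigError("paddy_fraction must lie in [0, 1]")
        if not 0.0 <= self.hills_weight <= 1.0:
            raise ConfigError("hills_weight must lie in [0, 1]")
        if self.n_townships < 1:
            raise ConfigError("n_townships must be >= 1")
        for t, r in self.degradation_rates.items():
            if t not in SINGLE_TYPES:
                raise ConfigError(f"unknown degradation type {t!r}")
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"degradation rate for {t} must lie in [0, 1]")
        for name, r in self.index_coupling.items():
            if not abs(r) < 1.0:
                raise ConfigError(f"index coupling {name} must satisfy |r| < 1")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9 or min(self.severity_mix) < 0:
            raise ConfigError("severity_mix must be a probability vector over 3 levels")
        if not abs(self.jitter_corr) < 1.0:
            raise ConfigError("jitter_corr must satisfy |rho| < 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_years"] = list(self.epoch_years)
        d["severity_mix"] = list(self.severity_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "epoch_years" in d:
            d["epoch_years"] = tuple(d["epoch_years"])
        if "severity_mix" in d:
            d["severity_mix"] = tuple(d["severity_mix"])
        return cls(**d)


@dataclass
class SyntheticCounty:
    """One generated county: unit, driver, soil, spectral and truth tables."""

    units: pd.DataFrame
    drivers: pd.DataFrame
    soil: pd.DataFrame
    spectral: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _tnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_units(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Unit table: id, land use, slope, area, township and position."""
    rng = rng if rng is not None else _child_rngs(config.seed, 4)[0]
    n = config.n_units
    x, y = rng.random(n), rng.random(n)
    g = int(np.ceil(np.sqrt(config.n_townships)))
    cell = np.minimum((x * g).astype(int), g - 1) + g * np.minimum((y * g).astype(int), g - 1)
    township = cell % config.n_townships
    is_hill = rng.random(n) < config.hills_weight
    slope = np.where(
        is_hill,
        _tnorm(rng, 12.0, 4.0, 5.1, 35.0, n),
        _tnorm(rng, 2.0, 1.2, 0.0, 4.9, n),
    )
    land_use = np.where(rng.random(n) < config.paddy_fraction, "paddy", "dryland")
    area = rng.lognormal(mean=np.log(0.3), sigma=0.45, size=n)
    return pd.DataFrame(
        {
            "unit_id": [f"U{i:06d}" for i in range(n)],
            "land_use": land_use,
            "slope": slope,
            "area": area,
            "township_id": [f"T{t:02d}" for t in township],
            "x": x,
            "y": y,
        }
    )


def generate_drivers(
    units: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Eleven driver covariates per unit, mildly correlated, VIF-safe."""
    rng = rng if rng is not None else _child_rngs(config.seed, 4)[1]
    n = len(units)
    slope = units["slope"].to_numpy()
    dem = np.clip(30.0 + 3.0 * slope + rng.normal(0, 25, n), 5.0, 500.0)
    pop = rng.lognormal(np.log(300.0), 0.6, n)
    return pd.DataFrame(
        {
            "unit_id": units["unit_id"].to_numpy(),
            "dem": dem,
            "aspect": rng.uniform(0, 360, n),
            "slope": slope,
            "map": 1620.0 + 80.0 * (units["y"].to_numpy() - 0.5) + rng.normal(0, 50, n),
            "mat": 17.5 - 0.004 * dem + rng.normal(0, 0.5, n),
            "dist_rivers": rng.exponential(1500.0, n) + 50.0,
            "dist_roads": rng.exponential(1200.0, n) + 50.0,
            "pop": pop,
            "gdp": pop * rng.lognormal(np.log(2000.0), 0.4, n),
            "srr": rng.beta(4.0, 2.0, n),
            "far": np.clip(rng.normal(450.0, 90.0, n), 100.0, 800.0),
        }
    )


_EPOCH1 = {  # (mean, sd, lo, hi) per land use; clips keep every unit off grade 4
    "som": {"paddy": (27.0, 2.5, 16.0, 40.0), "dryland": (17.0, 2.5, 11.0, 28.0)},
    "ph": {"paddy": (5.2, 0.25, 4.55, 6.4), "dryland": (5.7, 0.3, 4.55, 7.5)},
    "bd": {"paddy": (1.12, 0.07, 0.95, 1.28), "dryland": (1.12, 0.07, 0.95, 1.28)},
}


def _target_band_value(rng, indicator, land_use, grade, thresholds) -> float:
    """A value strictly inside the worst-ward interval of grade's class."""
    ivs = thresholds.intervals(indicator, land_use, grade)
    lo, hi = max(ivs, key=lambda iv: iv[0])  # worsening side (compaction for BD)
    w, m = _BAND_WIDTH[indicator], _BAND_MARGIN[indicator]
    if not np.isfinite(hi):
        return float(rng.uniform(lo + m, lo + w))
    lo_eff = max(lo + m, hi - w)
    return float(rng.uniform(lo_eff, hi - m))


def simulate_soil_trajectories(
    units: pd.DataFrame,
    drivers: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    thresholds: grading.ThresholdTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-epoch soil observations plus the planted ground-truth labels.

    Epoch-1 attributes are land-use-specific normals centred inside the
    middle grade bands.  Per type, the units with the highest driver-driven
    latent propensity are planted as degraded (erosion only among slopes
    > 5 degrees); their diagnostic property jumps 1–3 grade classes drawn
    from ``severity_mix`` (capped at grade 4).  Unplanted attributes drift
    within their epoch-1 grade band, so no accidental grade changes occur.
    """
    if not units["unit_id"].equals(drivers["unit_id"]):
        raise DataAlignmentError("units and drivers must share identical unit_id order")
    rng = rng if rng is not None else _child_rngs(config.seed, 4)[2]
    thresholds = thresholds or grading.load_thresholds()
    n = len(units)
    lu = units["land_use"].to_numpy()
    y1, y2 = config.epoch_years

    e1 = {}
    for attr, spec_by_lu in _EPOCH1.items():
        vals = np.empty(n)
        for use, (mean, sd, lo, hi) in spec_by_lu.items():
            sel = lu == use
            vals[sel] = _tnorm(rng, mean, sd, lo, hi, int(sel.sum()))
        e1[attr] = vals
    som_lims = {use: (s[2], s[3]) for use, s in _EPOCH1["som"].items()}
    tn = e1["som"] + rng.normal(0, 1.5, n)
    for use, (lo, hi) in som_lims.items():
        sel = lu == use
        tn[sel] = np.clip(tn[sel], lo, hi)
    e1["tn"] = tn

    # latent propensities and planted sets
    zdrv = drivers.drop(columns=["unit_id"]).apply(lambda c: (c - c.mean()) / c.std())
    planted: dict[str, np.ndarray] = {}
    levels: dict[str, np.ndarray] = {}
    for dtype in SINGLE_TYPES:
        rate = config.degradation_rates.get(dtype, 0.0)
        coeffs = config.driver_effects.get(dtype, {})
        prop = np.zeros(n)
        for name, c in coeffs.items():
            prop += c * zdrv[name].to_numpy()
        prop += rng.normal(0, config.propensity_noise, n)
        k = int(round(rate * n))
        eligible = (
            units["slope"].to_numpy() > 5.0 if dtype == "erosion" else np.ones(n, dtype=bool)
        )
        if k > int(eligible.sum()):
            raise ConfigError(
                f"{dtype}: rate {rate} needs {k} units but only {int(eligible.sum())} eligible"
            )
        mask = np.zeros(n, dtype=bool)
        if k > 0:
            order = np.argsort(np.where(eligible, prop, -np.inf))[::-1]
            mask[order[:k]] = True
        planted[dtype] = mask
        lev = np.zeros(n, dtype=int)
        lev[mask] = rng.choice([1, 2, 3], size=k, p=list(config.severity_mix))
        levels[dtype] = lev

    # epoch-1 property grades (vectorised) — needed to cap planted drops at grade 4
    soil1 = pd.DataFrame({"unit_id": units["unit_id"], "epoch_year": y1, **e1})
    g1_grades = (
        grading.grade_table(units, soil1, thresholds).set_index("unit_id").loc[units["unit_id"]]
    )
    g1_prop = {p: g1_grades[f"{p}_grade"].to_numpy(int) for p in ("ph", "som", "bd")}

    # epoch-2 values: planted -> jump grade bands; unplanted -> within-band jitter
    corr = config.jitter_corr
    chol = np.linalg.cholesky([[1.0, corr], [corr, 1.0]])
    zj = rng.standard_normal((n, 2)) @ chol.T
    jitter = {
        "ph": zj[:, 0] * config.noise_scales["ph"],
        "som": zj[:, 1] * config.noise_scales["som"],
        "tn": rng.normal(0, config.noise_scales["tn"], n),
        "bd": rng.normal(0, config.noise_scales["bd"], n),
    }
    drop_levels = {
        "ph": levels["acidification"],
        "som": np.maximum(levels["fertility_decline"], levels["erosion"]),
        "bd": levels["physical_structure"],
        "tn": np.zeros(n, dtype=int),
    }
    e2 = {}
    for attr in ("som", "tn", "ph", "bd"):
        vals = np.empty(n)
        for i in range(n):
            g1, lo, hi = grading.grade_band(e1[attr][i], attr, lu[i], thresholds)
            if drop_levels[attr][i] > 0:
                target = min(4, g1 + int(drop_levels[attr][i]))
                vals[i] = _target_band_value(rng, attr, lu[i], target, thresholds)
            else:
                m = _BAND_MARGIN[attr]
                lo_c = lo + m if np.isfinite(lo) else -np.inf
                hi_c = hi - m if np.isfinite(hi) else np.inf
                vals[i] = float(np.clip(e1[attr][i] + jitter[attr][i], lo_c, hi_c))
        e2[attr] = vals

    soil = pd.concat(
        [
            pd.DataFrame({"unit_id": units["unit_id"], "epoch_year": y, **vals})
            for y, vals in ((y1, e1), (y2, e2))
        ],
        ignore_index=True,
    )
    # truth severity = realized grade drop (drawn level, capped at grade 4)
    sev_names = np.asarray(["none", "slight", "moderate", "severe"], dtype=object)
    truth_frames = []
    for dtype in SINGLE_TYPES:
        realized = np.minimum(levels[dtype], 4 - g1_prop[TYPE_PROPERTY[dtype]])
        realized = np.where(planted[dtype], realized, 0)
        truth_frames.append(
            pd.DataFrame(
                {
                    "unit_id": units["unit_id"],
                    "dtype": dtype,
                    "planted": realized > 0,  # a unit at grade 4 cannot drop further
                    "severity": sev_names[realized],
                }
            )
        )
    return soil, pd.concat(truth_frames, ignore_index=True)


def _standardize(x: np.ndarray, label: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        warnings.warn(f"{label}: zero variance in soil deltas; index coupling undefined")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_reflectance(
    units: pd.DataFrame,
    soil: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-epoch NIR/RED reflectance coupled to the soil-property changes.

    Index deltas follow a Gaussian copula: the RVI delta loads jointly on the
    standardized pH and SOM deltas (weights solved so the realized RVI–pH and
    NDVI–SOM correlations track ``index_coupling``, rescaled to the feasible
    boundary if the pair is jointly infeasible), the DVI delta loads on the
    BD delta with the configured (negative) sign, and eroded units get a
    positive DVI push.  NIR/RED are then solved from the target RVI and DVI.
    """
    rng = rng if rng is not None else _child_rngs(config.seed, 4)[3]
    y1, y2 = config.epoch_years
    s1 = soil[soil["epoch_year"] == y1].set_index("unit_id").loc[units["unit_id"]]
    s2 = soil[soil["epoch_year"] == y2].set_index("unit_id").loc[units["unit_id"]]
    n = len(units)
    z_ph = _standardize(s2["ph"].to_numpy() - s1["ph"].to_numpy(), "d_ph")
    z_som = _standardize(s2["som"].to_numpy() - s1["som"].to_numpy(), "d_som")
    z_bd = _standardize(s2["bd"].to_numpy() - s1["bd"].to_numpy(), "d_bd")

    r1 = config.index_coupling.get("rvi_ph", 0.8)
    r2 = config.index_coupling.get("ndvi_som", 0.8)
    r3 = config.index_coupling.get("dvi_bd", -0.8)

    if z_ph.std() > 0 and z_som.std() > 0 and n > 2:
        rho = float(np.corrcoef(z_ph, z_som)[0, 1])
    else:
        rho = 0.0
    sigma = np.array([[1.0, rho], [rho, 1.0]])
    target = np.array([r1, r2])
    alpha = np.linalg.solve(sigma, target)
    q = float(target @ alpha)
    if q > 1.0:  # jointly infeasible: project to the feasible boundary
        alpha /= np.sqrt(q)
        resid = 0.0
    else:
        resid = np.sqrt(1.0 - q)
    u = alpha[0] * z_ph + alpha[1] * z_som + resid * rng.standard_normal(n)
    v = r3 * z_bd + np.sqrt(1.0 - r3**2) * rng.standard_normal(n)
    if truth is not None:
        eroded = (
            truth[(truth["dtype"] == "erosion") & truth["planted"]]["unit_id"].to_numpy()
        )
        v[np.isin(units["unit_id"].to_numpy(), eroded)] += 2.0

    rvi1 = _tnorm(rng, 3.2, 0.3, 2.3, 4.3, n)
    red1 = rng.uniform(0.06, 0.12, n)
    nir1 = rvi1 * red1
    dvi1 = nir1 - red1
    rvi2 = np.clip(rvi1 + 0.35 * u, 1.25, 6.0)
    dvi2 = np.clip(dvi1 + 0.03 * v, 0.01, 0.8)
    red2 = np.clip(dvi2 / (rvi2 - 1.0), 0.005, 0.5)
    nir2 = np.clip(red2 * rvi2, 0.01, 0.99)
    return pd.concat(
        [
            pd.DataFrame(
                {"unit_id": units["unit_id"], "epoch_year": y, "nir": nir, "red": red}
            )
            for y, nir, red in ((y1, nir1, red1), (y2, nir2, red2))
        ],
        ignore_index=True,
    )


def generate(config: SimulationConfig) -> SyntheticCounty:
    """Generate a full county from one config (single-seed reproducible)."""
    rng_u, rng_d, rng_s, rng_r = _child_rngs(config.seed, 4)
    units = generate_units(config, rng_u)
    drivers = generate_drivers(units, config, rng_d)
    soil, truth = simulate_soil_trajectories(units, drivers, config, rng_s)
    spectral = simulate_reflectance(units, soil, config, rng_r, truth)
    return SyntheticCounty(units, drivers, soil, spectral, truth, config)


# ---------------------------------------------------------------------------
# disk round-trip

_CSV_BLOCKS = ("soil", "spectral", "drivers", "truth")


def write_dataset(county: SyntheticCounty, directory: str | Path) -> dict[str, Path]:
    """Write a county as units.geojson + CSV blocks + config.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {
                "unit_id": row.unit_id,
                "land_use": row.land_use,
                "slope": row.slope,
                "area": row.area,
                "township_id": row.township_id,
            },
        }
        for row in county.units.itertuples()
    ]
    paths["units"] = directory / "units.geojson"
    paths["units"].write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    for name in _CSV_BLOCKS:
        paths[name] = directory / f"{name}.csv"
        getattr(county, name).to_csv(paths[name], index=False)
    paths["config"] = directory / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(county.config.to_dict()))
    return paths


def read_units(path: str | Path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = []
    for f in gj["features"]:
        props = dict(f["properties"])
        coords = (f.get("geometry") or {}).get("coordinates", [np.nan, np.nan])
        props["x"], props["y"] = coords[0], coords[1]
        rows.append(props)
    df = pd.DataFrame(rows)
    return df[["unit_id", "land_use", "slope", "area", "township_id", "x", "y"]]


def read_dataset(directory: str | Path) -> SyntheticCounty:
    """Read a dataset directory back; raises on any missing mandatory block."""
    directory = Path(directory)
    missing = [
        f
        for f in ["units.geojson", *(f"{b}.csv" for b in _CSV_BLOCKS), "config.yaml"]
        if not (directory / f).exists()
    ]
    if missing:
        raise PartialDatasetError(f"dataset at {directory} missing blocks: {missing}")
    units = read_units(directory / "units.geojson")
    blocks = {b: pd.read_csv(directory / f"{b}.csv") for b in _CSV_BLOCKS}
    config = SimulationConfig.from_dict(
        yaml.safe_load((directory / "config.yaml").read_text())
    )
    return SyntheticCounty(
        units=units,
        drivers=blocks["drivers"],
        soil=blocks["soil"],
        spectral=blocks["spectral"],
        truth=blocks["truth"],
        config=config,
    )
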