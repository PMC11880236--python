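"""End-to-end orchestration: simulate/load -> grade -> diagnose -> summarize -> attribute.

One :class:`PipelineConfig` drives a full run.  Input is either a dataset
directory (units.geojson + soil/spectral/drivers CSVs) or a simulation
config; the run emits per-unit grade and degradation tables, the long
diagnosis table, county and township summaries, per-type driver attributions
and rankings, and a ``manifest.json`` recording the config hash, seeds,
package version, row counts and per-stage status.  All randomness (surrogate
fit, instance/background subsampling, permutation sampling) derives from the
single ``attribution.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, diagnostics, grading, quality, summary, synthetic

__all__ = [
    "AttributionSettings",
    "PipelineConfig",
    "PipelineError",
    "ValidationReport",
    "validate_inputs",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """Fatal validation or stage failure."""


@dataclass
class AttributionSettings:
    dtypes: tuple[str, ...] = diagnostics.DEGRADATION_TYPES
    n_perm: int = 24
    n_instances: int = 128
    background_size: int = 32
    seed: int = 30

    def __post_init__(self) -> None:
        unknown = set(self.dtypes) - set(diagnostics.DEGRADATION_TYPES)
        if unknown:
            raise PipelineError(f"unknown attribution dtypes: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Exactly one of ``simulation`` / ``input_dir`` must be supplied."""

    out_dir: Path
    simulation: synthetic.SimulationConfig | None = None
    input_dir: Path | None = None
    thresholds_path: Path | None = None
    eps: float = 0.0
    epoch_years: tuple[int, int] | None = None  # default: from data/config
    attribution: AttributionSettings = field(default_factory=AttributionSettings)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise PipelineError("supply exactly one of simulation config or input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulation")
        att = raw.get("attribution", {})
        if "dtypes" in att:
            att["dtypes"] = tuple(att["dtypes"])
        return cls(
            out_dir=Path(raw["out_dir"]),
            simulation=synthetic.SimulationConfig.from_dict(sim) if sim else None,
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            thresholds_path=Path(raw["thresholds"]) if raw.get("thresholds") else None,
            eps=float(raw.get("eps", 0.0)),
            epoch_years=tuple(raw["epoch_years"]) if raw.get("epoch_years") else None,
            attribution=AttributionSettings(**att),
        )


@dataclass
class ValidationReport:
    findings: list[str]
    fatal: list[str]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(
    county: synthetic.SyntheticCounty, epoch_years: tuple[int, int]
) -> ValidationReport:
    """Schema, epoch-completeness and physical-range checks on an input county."""
    findings: list[str] = []
    fatal: list[str] = []
    y1, y2 = epoch_years

    need = {
        "units": ({"unit_id", "land_use", "slope", "area", "township_id"}, county.units),
        "soil": ({"unit_id", "epoch_year", "som", "tn", "ph", "bd"}, county.soil),
        "spectral": ({"unit_id", "epoch_year", "nir", "red"}, county.spectral),
        "drivers": ({"unit_id", *attribution.DRIVER_NAMES}, county.drivers),
    }
    for name, (cols, df) in need.items():
        missing = cols - set(df.columns)
        if missing:
            fatal.append(f"{name}: missing columns {sorted(missing)}")
    if fatal:
        return ValidationReport(findings, fatal)

    uids = set(county.units["unit_id"])
    for name, df in (("soil", county.soil), ("spectral", county.spectral)):
        for year in (y1, y2):
            got = set(df.loc[df["epoch_year"] == year, "unit_id"])
            if not got:
                fatal.append(f"{name}: epoch {year} entirely missing")
            else:
                lack = len(uids - got)
                if lack:
                    findings.append(f"{name}: {lack} units missing epoch {year}")

    ranges = {
        ("soil", "ph"): (0.0, 14.0, True),
        ("soil", "som"): (0.0, np.inf, False),
        ("soil", "tn"): (0.0, np.inf, False),
        ("soil", "bd"): (0.0, np.inf, True),
        ("spectral", "nir"): (0.0, 1.0, True),
        ("spectral", "red"): (0.0, 1.0, True),
        ("units", "area"): (0.0, np.inf, True),
        ("units", "slope"): (0.0, 90.0, False),
    }
    for (tbl, col), (lo, hi, open_lo) in ranges.items():
        s = getattr(county, tbl)[col]
        bad = ~np.isfinite(s) | (s <= lo if open_lo else s < lo) | (s > hi)
        if bad.any():
            rows = list(s.index[bad][:5])
            fatal.append(f"{tbl}.{col}: {int(bad.sum())} values out of range, rows {rows}")
    return ValidationReport(findings, fatal)


def _config_hash(cfg: PipelineConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    for k in ("input_dir", "thresholds_path"):
        if d[k] is not None:
            d[k] = str(d[k])
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts to ``config.out_dir``; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "package": "degradiag",
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "rows": {},
    }

    def stage(name):
        def mark(status):
            manifest["stages"][name] = status

        return mark

    # --- inputs
    mark = stage("load")
    if config.simulation is not None:
        county = synthetic.generate(config.simulation)
        synthetic.write_dataset(county, out / "dataset")
    else:
        county = synthetic.read_dataset(config.input_dir)
    epochs = config.epoch_years or county.config.epoch_years
    mark("ok")

    mark = stage("validate")
    report = validate_inputs(county, epochs)
    manifest["validation"] = {"findings": report.findings, "fatal": report.fatal}
    if not report.ok:
        mark("fatal")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"validation failed: {report.fatal}")
    mark("ok")

    thresholds = grading.load_thresholds(config.thresholds_path)

    mark = stage("grade")
    grades = grading.grade_table(county.units, county.soil, thresholds)
    grades.to_csv(out / "grades.csv", index=False)
    qual = quality.quality_table(grades, epochs)
    qual.to_csv(out / "quality.csv", index=False)
    manifest["rows"]["grades"] = len(grades)
    mark("ok")

    mark = stage("diagnose")
    diag = diagnostics.diagnose_all(
        county.units, county.soil, county.spectral, thresholds, config.eps, epochs
    )
    diag.to_csv(out / "diagnoses.csv", index=False)
    manifest["rows"]["diagnoses"] = len(diag)
    manifest["n_incomplete_units"] = diag.attrs.get("n_incomplete", 0)
    mark("ok")

    mark = stage("summarize")
    summ = summary.summarize(diag, county.units)
    summ.to_csv(out / "summary.csv", index=False)
    town = summary.township_aggregate(diag, county.units)
    town.to_csv(out / "townships.csv", index=False)
    mark("ok")

    mark = stage("attribute")
    att = config.attribution
    X = county.drivers.set_index("unit_id")[list(attribution.DRIVER_NAMES)]
    vif = attribution.vif_screen(X)
    vif.to_csv(out / "vif.csv", index=False)
    rng = np.random.default_rng(att.seed)
    manifest["attribution"] = {"seed": att.seed, "n_perm": att.n_perm, "surrogate_r2": {}}
    for dtype in att.dtypes:
        y = attribution.degradation_scores(grades, epochs, dtype).loc[X.index]
        surrogate = attribution.fit_surrogate(X, y, seed=att.seed)
        manifest["attribution"]["surrogate_r2"][dtype] = surrogate.holdout_r2
        inst_idx = rng.choice(len(X), size=min(att.n_instances, len(X)), replace=False)
        bg_idx = rng.choice(len(X), size=min(att.background_size, len(X)), replace=False)
        result = attribution.attribute_sampled(
            surrogate, X.iloc[inst_idx], X.iloc[bg_idx], n_perm=att.n_perm, seed=att.seed
        )
        phi = pd.DataFrame(result.phi, columns=list(result.feature_names))
        phi.insert(0, "unit_id", X.index[inst_idx])
        phi.to_csv(out / f"attribution_{dtype}.csv", index=False)
        ranking = attribution.rank_drivers(result)
        ranking.to_csv(out / f"ranking_{dtype}.csv", index=False)
    mark("ok")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
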