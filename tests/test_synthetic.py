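"""Synthetic county generator: determinism, planted structure, couplings, I/O."""

import numpy as np
import pandas as pd
import pytest

from degradiag import grading, indices, synthetic
from degradiag.synthetic import SimulationConfig


def test_seeded_determinism(tmp_path):
    c1 = synthetic.generate(SimulationConfig(n_units=300, seed=42))
    c2 = synthetic.generate(SimulationConfig(n_units=300, seed=42))
    for block in ("units", "drivers", "soil", "spectral", "truth"):
        pd.testing.assert_frame_equal(getattr(c1, block), getattr(c2, block))
    # byte-identical on disk
    p1, p2 = tmp_path / "a", tmp_path / "b"
    synthetic.write_dataset(c1, p1)
    synthetic.write_dataset(c2, p2)
    for f in sorted(p1.iterdir()):
        assert f.read_bytes() == (p2 / f.name).read_bytes()


def test_config_validation():
    with pytest.raises(synthetic.ConfigError):
        SimulationConfig(n_units=0)
    with pytest.raises(synthetic.ConfigError):
        SimulationConfig(paddy_fraction=1.2)
    with pytest.raises(synthetic.ConfigError):
        SimulationConfig(index_coupling={"rvi_ph": 1.0})
    with pytest.raises(synthetic.ConfigError):
        SimulationConfig(degradation_rates={"acidification": -0.1})
    with pytest.raises(synthetic.ConfigError):
        SimulationConfig(degradation_rates={"rusting": 0.1})


def test_degenerate_paddy_fraction():
    units = synthetic.generate_units(SimulationConfig(n_units=100, seed=0, paddy_fraction=1.0))
    assert (units["land_use"] == "paddy").all()


def test_slope_mixture_weight():
    """Fraction of slopes > 5 deg within 3 binomial s.e. of the hills weight."""
    cfg = SimulationConfig(n_units=2000, seed=3)
    units = synthetic.generate_units(cfg)
    frac = (units["slope"] > 5.0).mean()
    se = np.sqrt(cfg.hills_weight * (1 - cfg.hills_weight) / cfg.n_units)
    assert abs(frac - cfg.hills_weight) <= 3 * se
    assert (units["area"] > 0).all()
    assert units["township_id"].nunique() == cfg.n_townships


def test_null_scenario_pure_noise(null_county):
    """No effects, no planted degradation: zero planted units and no grade
    changes between epochs."""
    assert null_county.truth["planted"].sum() == 0
    g = grading.grade_table(null_county.units, null_county.soil)
    y1 = g[g["epoch_year"] == 2012].set_index("unit_id")
    y2 = g[g["epoch_year"] == 2019].set_index("unit_id").loc[y1.index]
    pd.testing.assert_frame_equal(y1.drop(columns="epoch_year"), y2.drop(columns="epoch_year"))


def test_planted_rate_matches_target():
    cfg = SimulationConfig(n_units=2000, seed=5)
    county = synthetic.generate(cfg)
    rates = county.truth.groupby("dtype")["planted"].mean()
    for dtype, target in cfg.degradation_rates.items():
        se = np.sqrt(max(target * (1 - target), 1e-9) / cfg.n_units)
        assert abs(rates[dtype] - target) <= max(3 * se, 1.0 / cfg.n_units)


def test_far_gradient_in_ph_deltas():
    """Positive FAR coefficient on acidification: high-FAR units acidify more."""
    county = synthetic.generate(SimulationConfig(n_units=2000, seed=6))
    s1 = county.soil[county.soil["epoch_year"] == 2012].set_index("unit_id")
    s2 = county.soil[county.soil["epoch_year"] == 2019].set_index("unit_id")
    d_ph = (s2["ph"] - s1["ph"]).loc[county.drivers["unit_id"]]
    far = county.drivers.set_index("unit_id")["far"]
    hi = d_ph[far >= far.quantile(0.9)].mean()
    lo = d_ph[far <= far.quantile(0.1)].mean()
    assert hi < lo


def test_index_couplings_realized(county):
    """Realized delta-index vs delta-property correlations within 0.1 of target."""
    cfg = county.config
    s1 = county.soil[county.soil["epoch_year"] == 2012].set_index("unit_id")
    s2 = county.soil[county.soil["epoch_year"] == 2019].set_index("unit_id")
    ch = indices.index_changes(county.spectral, cfg.epoch_years).set_index("unit_id")
    pairs = [("d_rvi", "ph", cfg.index_coupling["rvi_ph"]),
             ("d_ndvi", "som", cfg.index_coupling["ndvi_som"]),
             ("d_dvi", "bd", cfg.index_coupling["dvi_bd"])]
    for ix, prop, target in pairs:
        d = (s2[prop] - s1[prop]).loc[ch.index]
        r, _ = indices.correlation_screen(ch[ix].to_numpy(), d.to_numpy())
        assert abs(r - target) <= 0.1, (ix, prop, r, target)


def test_moderate_coupling_realized():
    cfg = SimulationConfig(
        n_units=2000, seed=8, index_coupling={"rvi_ph": 0.5, "ndvi_som": 0.5, "dvi_bd": -0.5}
    )
    county = synthetic.generate(cfg)
    s1 = county.soil[county.soil["epoch_year"] == 2012].set_index("unit_id")
    s2 = county.soil[county.soil["epoch_year"] == 2019].set_index("unit_id")
    ch = indices.index_changes(county.spectral, cfg.epoch_years).set_index("unit_id")
    r, _ = indices.correlation_screen(
        ch["d_rvi"].to_numpy(), (s2["ph"] - s1["ph"]).loc[ch.index].to_numpy()
    )
    assert 0.4 <= r <= 0.6


def test_zero_coupling_independent():
    cfg = SimulationConfig(
        n_units=2000,
        seed=9,
        index_coupling={"rvi_ph": 0.0, "ndvi_som": 0.0, "dvi_bd": 0.0},
        degradation_rates={t: 0.0 for t in synthetic.SINGLE_TYPES},
    )
    county = synthetic.generate(cfg)
    s1 = county.soil[county.soil["epoch_year"] == 2012].set_index("unit_id")
    s2 = county.soil[county.soil["epoch_year"] == 2019].set_index("unit_id")
    ch = indices.index_changes(county.spectral, cfg.epoch_years).set_index("unit_id")
    _, p = indices.correlation_screen(
        ch["d_rvi"].to_numpy(), (s2["ph"] - s1["ph"]).loc[ch.index].to_numpy()
    )
    assert p > 0.01


def test_degenerate_soil_deltas_flagged():
    """Identical soil deltas leave the coupling undefined; the generator warns."""
    county = synthetic.generate(SimulationConfig(n_units=200, seed=10))
    soil = county.soil.copy()
    soil.loc[soil["epoch_year"] == 2019, ["som", "tn", "ph", "bd"]] = (
        soil.loc[soil["epoch_year"] == 2012, ["som", "tn", "ph", "bd"]].to_numpy()
    )
    with pytest.warns(UserWarning, match="zero variance"):
        synthetic.simulate_reflectance(
            county.units, soil, county.config, np.random.default_rng(0)
        )


def test_physical_invariants(county):
    spec = county.spectral
    assert ((spec["nir"] > 0) & (spec["nir"] <= 1)).all()
    assert ((spec["red"] > 0) & (spec["red"] <= 1)).all()
    assert ((county.soil["ph"] > 0) & (county.soil["ph"] < 14)).all()
    counts = county.soil.groupby(["unit_id", "epoch_year"]).size()
    assert (counts == 1).all() and len(counts) == 2 * len(county.units)


def test_write_read_round_trip(tmp_path, county):
    synthetic.write_dataset(county, tmp_path / "ds")
    back = synthetic.read_dataset(tmp_path / "ds")
    for block in ("units", "drivers", "soil", "spectral", "truth"):
        pd.testing.assert_frame_equal(
            getattr(county, block).reset_index(drop=True), getattr(back, block)
        )
    assert back.config == county.config


def test_partial_dataset_error(tmp_path, county):
    synthetic.write_dataset(county, tmp_path / "ds")
    (tmp_path / "ds" / "spectral.csv").unlink()
    with pytest.raises(synthetic.PartialDatasetError, match="spectral"):
        synthetic.read_dataset(tmp_path / "ds")


def test_unit_driver_misalignment_raises(county):
    drv = county.drivers.iloc[::-1].reset_index(drop=True)
    with pytest.raises(synthetic.DataAlignmentError):
        synthetic.simulate_soil_trajectories(county.units, drv, county.config)
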