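import pytest

from degradiag import grading, synthetic


@pytest.fixture(scope="session")
def thresholds():
    return grading.load_thresholds()


@pytest.fixture(scope="session")
def county():
    """Reference synthetic county at the default scenario (n=2000)."""
    return synthetic.generate(synthetic.SimulationConfig(n_units=2000, seed=11))


@pytest.fixture(scope="session")
def null_county():
    """County with no planted degradation and no driver effects."""
    cfg = synthetic.SimulationConfig(
        n_units=600,
        seed=7,
        degradation_rates={t: 0.0 for t in synthetic.SINGLE_TYPES},
        driver_effects={t: {} for t in synthetic.SINGLE_TYPES},
    )
    return synthetic.generate(cfg)
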