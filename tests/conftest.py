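import numpy as np
import pytest

from hipposurvey.simulate import (FlightPlanRow, SimulationConfig,
                                  generate_counts, generate_design)


def small_config(seed=0, **overrides):
    """A reduced survey (42 photos, 4 observers, 7 flights) for fast tests.

    Keeps the full design's structure: equal height stratification,
    within-flight wind/cloud, exact sun multiset, mixed observer panel.
    """
    flights = (
        FlightPlanRow(1, 1, 6, 57, 205.0),
        FlightPlanRow(2, 0, 6, 60, 70.0),
        FlightPlanRow(2, 1, 6, 58, 285.0),
        FlightPlanRow(3, 1, 6, 61, 5.0),
        FlightPlanRow(4, 1, 6, 59, 75.0),
        FlightPlanRow(5, 2, 6, 55, 35.0),
        FlightPlanRow(5, 2, 6, 57, 120.0),
    )
    defaults = dict(
        flights=flights,
        photos_per_height=7,
        n_observers=4,
        n_experienced=2,
        sun_counts=(31, 8, 3),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_survey():
    """One full-size synthetic survey (252 photos x 8 observers)."""
    cfg = SimulationConfig(seed=42)
    design = generate_design(cfg)
    units = generate_counts(design, cfg)
    return {"config": cfg, "design": design, "units": units}


@pytest.fixture(scope="session")
def small_units():
    cfg = small_config(seed=11)
    return generate_counts(generate_design(cfg), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
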