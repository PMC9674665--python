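import datetime as dt

import pytest

from ecoach import ActivityLevel, DailySummary, SimulationConfig, simulate_daily


@pytest.fixture
def day_factory():
    """Build a DailySummary with keyword overrides."""

    def make(steps=0, lpa=0.0, mpa=0.0, vpa=0.0, sedentary=0.0,
             pid="P-1", date=dt.date(2024, 1, 1)):
        return DailySummary(pid, date, steps, lpa, mpa, vpa, sedentary)

    return make


@pytest.fixture(scope="session")
def labeled_cohort():
    """A mid-size simulated cohort with ground-truth labels (shared)."""
    cfg = SimulationConfig(n_participants=10, n_days=40, seed=7)
    return simulate_daily(cfg)


@pytest.fixture
def table13_levels():
    """The seven predicted daily levels of the worked weekly example."""
    return [ActivityLevel(x) for x in (1, 1, 3, 2, 1, 1, 1)]
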