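import numpy as np
import pytest

import deer_cba as d

STRATEGY_IDS = ("1", "2", "3", "4A", "4B")


@pytest.fixture(scope="session")
def schedules():
    return {
        s.id: d.resolve_schedule(s) for s in d.builtin_strategies()
    }


@pytest.fixture(scope="session")
def tables(schedules):
    return {sid: d.stationary_table(sch, 1000.0) for sid, sch in schedules.items()}


@pytest.fixture(scope="session")
def aggregates(tables):
    return {sid: d.aggregate_classes(t) for sid, t in tables.items()}


@pytest.fixture(scope="session")
def fixtures():
    return d.reference_fixtures()


@pytest.fixture(scope="session")
def benchmark():
    return d.ValuationParameters.benchmark()


def random_schedule(rng: np.random.Generator) -> d.MortalitySchedule:
    """Random constraint-respecting schedule for property tests."""
    hunting = {
        sex: rng.uniform(0.0, 0.9, size=25) for sex in ("female", "male")
    }
    return d.effective_mortality(hunting, baseline=rng.uniform(0.0, 0.05))
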