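import pytest

from shelfbed.forcing import ForcingConfig, generate_forcing
from shelfbed.scenarios import builtin_scenario, run_simulation

# Full 21-year scenario runs are shared between the qualitative acceptance
# tests; session scope keeps the suite inside the runtime budget.

_CACHE = {}


def _run(name: str, years: int = 21):
    key = (name, years)
    if key not in _CACHE:
        _CACHE[key] = run_simulation(builtin_scenario(name, years=years))
    return _CACHE[key]


@pytest.fixture(scope="session")
def scenario_runner():
    """Callable returning (cached) full scenario runs by builtin name."""
    return _run


@pytest.fixture()
def short_forcing():
    """Two years of default synthetic forcing."""
    return generate_forcing(ForcingConfig(years=2))
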