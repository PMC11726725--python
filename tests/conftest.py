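import numpy as np
import pytest

from ribostat import RateConstants, Totals, full_equilibrium


@pytest.fixture(scope="session")
def unit_rates():
    """All four rate constants equal to one (the worked scenarios)."""
    return RateConstants.all_equal(1.0)


@pytest.fixture(scope="session")
def spreadsheet_totals():
    """Totals of the spreadsheet scenario: cA=7, cX=100, cY=24.45."""
    return Totals(cA=7.0, cX=100.0, cY=24.45)


@pytest.fixture(scope="session")
def spreadsheet_equilibrium(unit_rates, spreadsheet_totals):
    return full_equilibrium(unit_rates, spreadsheet_totals)


def random_parameter_set(rng: np.random.Generator):
    """A random, well-conditioned (rates, totals) pair for property sweeps."""
    rates = RateConstants(
        k1=rng.uniform(0.2, 5.0), k2=rng.uniform(0.2, 5.0),
        k3=rng.uniform(0.2, 5.0), k4=rng.uniform(0.2, 5.0),
    )
    totals = Totals(
        cA=rng.uniform(0.5, 20.0),
        cX=rng.uniform(0.5, 50.0),
        cY=rng.uniform(0.0, 30.0),
    )
    return rates, totals
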