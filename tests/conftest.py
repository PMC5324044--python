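"""Shared fixtures: the two synthetic worlds used across the test suite.

``montane`` emulates a high-elevation dry-summer conifer site (validation,
calibration and window-scan experiments); ``lowland`` a warm low-elevation
site whose glacial counterpart drives the glacial experiment suite.
"""

import pytest

from ptgrowth import tmodel, worlds


@pytest.fixture(scope="session")
def montane_forcing():
    return worlds.montane_world(seed=1)


@pytest.fixture(scope="session")
def lowland_pair():
    """(modern, glacial) prepared forcings for the warm low-elevation site."""
    return worlds.lowland_pair(seed=1)


@pytest.fixture(scope="session")
def lowland_raw_pair():
    """Same pair but without derived drivers (substitution experiments re-prepare)."""
    return worlds.lowland_pair(seed=1, prepared=False)


@pytest.fixture(scope="session")
def species():
    return tmodel.SpeciesParams()


@pytest.fixture(scope="session")
def gpp_annual(montane_forcing):
    from ptgrowth import pmodel

    monthly = pmodel.run_pmodel(montane_forcing)
    return pmodel.annual_potential_gpp(monthly)
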