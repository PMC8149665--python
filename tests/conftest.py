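import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import heat_equity as he
from heat_equity.grids import NONURBAN, URBAN, WATER, Georeference, ZoneMap

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_city():
    """Hand-built 6x6 city: one UA, two tracts, water and missing cells.

    Layout (row-major): UA covers columns 0-4; column 5 is outside any zone.
    Tract T1 = rows 0-2, tract T2 = rows 3-5 (within the UA).  Urban core in
    the middle, nonurban ring supplies the rural reference, one water cell
    and one missing LST cell exercise the exclusion rules.
    """
    labels = np.full((6, 6), NONURBAN, dtype=int)
    labels[1:5, 1:4] = URBAN
    labels[2, 2] = WATER
    lst = np.full((6, 6), 28.0)
    lst[1:5, 1:4] = 31.0
    lst[2, 2] = 25.0      # water cell, hot-tub cold
    lst[4, 2] = np.nan    # missing urban cell
    ua = np.zeros((6, 6), dtype=int)
    ua[:, :5] = 1
    tract = np.zeros((6, 6), dtype=int)
    tract[:3, :5] = 1
    tract[3:, :5] = 2
    zones = ZoneMap(ua, tract, {1: "UA_TOY"}, {1: "T1", 2: "T2"})
    georef = Georeference(0.0, 6.0, 1.0)
    return (he.LandCoverGrid(labels, georef), he.TemperatureGrid(lst, georef), zones)


@pytest.fixture(scope="session")
def small_config():
    return he.SyntheticConfig(n_cities=6, grid_size=24, n_tracts_per_city=12)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return he.generate_panel(small_config, seed=42)


@pytest.fixture(scope="session")
def panel_tables(small_panel):
    """SUHI frame plus built demographic tables for the small panel."""
    schemes = he.default_schemes()
    raw = small_panel.demographics_frame()
    tables = {name: he.build_groups(raw, s) for name, s in schemes.items()}
    return small_panel.suhi_frame(), tables, small_panel.zone_labels


def random_city_grids(rng, nrow, ncol, n_tracts=3, missing_frac=0.1):
    """Random aligned grids for oracle-equivalence tests (single UA)."""
    labels = rng.choice([URBAN, NONURBAN, WATER], size=(nrow, ncol), p=[0.5, 0.4, 0.1])
    lst = rng.normal(30.0, 3.0, size=(nrow, ncol))
    lst[rng.random((nrow, ncol)) < missing_frac] = np.nan
    ua = (rng.random((nrow, ncol)) < 0.8).astype(int)
    tract = np.where(ua > 0, rng.integers(1, n_tracts + 1, size=(nrow, ncol)), 0)
    zones = ZoneMap(ua, tract, {1: "UA_R"},
                    {t: f"R{t}" for t in range(1, n_tracts + 1)})
    georef = Georeference()
    return he.LandCoverGrid(labels, georef), he.TemperatureGrid(lst, georef), zones
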