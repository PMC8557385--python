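import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mixstand.allometry import default_species_params
from mixstand.records import PlotDefinition, TREE_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_params():
    return default_species_params()


@pytest.fixture
def small_plot():
    return PlotDefinition("p1", 40.0, 40.0, (50.0, 55.0), ("spruce",))


def make_frame(rows):
    """Build a tree-list frame from (tree_id, species, x, y, survey, age, d, h, status)."""
    df = pd.DataFrame(
        [("p1", tid, sp, x, y, k, age, d, h, np.nan, status)
         for tid, sp, x, y, k, age, d, h, status in rows],
        columns=TREE_COLUMNS)
    return df


@pytest.fixture
def frame_builder():
    return make_frame


def random_stand_frame(rng, plot, n, species=("spruce", "beech"),
                       growth=2.0):
    """Two-survey random tree list on ``plot`` with uniform positions."""
    x = rng.uniform(0, plot.width, n)
    y = rng.uniform(0, plot.height, n)
    sp = rng.choice(species, n)
    d0 = rng.lognormal(3.0, 0.2, n)
    rows = []
    for k, age, dd in ((0, plot.survey_ages[0], d0),
                       (1, plot.survey_ages[1], d0 + growth)):
        for i in range(n):
            rows.append(("p1", f"t{i:04d}", sp[i], x[i], y[i], k, age,
                         dd[i], np.nan, np.nan, "live"))
    return pd.DataFrame(rows, columns=TREE_COLUMNS)


@pytest.fixture
def random_stand():
    return random_stand_frame
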