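import numpy as np
import pandas as pd
import pytest

from guildgam.hgam import ModelSpec, fit_hgam
from guildgam.simulate import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A 25-site synthetic survey shared by read-only tests."""
    return simulate_survey(SimulationConfig(n_sites=25, seed=3))


@pytest.fixture(scope="session")
def survey_fit(small_survey):
    """A moderately sized fitted model with habitat + space terms.

    Growing-season rows only; trap random effects off and reduced smooth
    families keep this fast enough to share across test modules.
    """
    df = small_survey.richness[
        small_survey.richness.week.between(14, 43)
    ].reset_index(drop=True)
    spec = ModelSpec(
        global_smooths=("season", "temp", "space"),
        guild_smooths=("season",),
        habitat_slopes=True,
        guild_intercepts=True,
        site_effects=False,
        theta=5.0,
    )
    return fit_hgam(df, spec, max_outer=25), df
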