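"""Phenophase scans, temperature trends, lags and guild composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildgam.phenology import (
    PhenophaseEstimate,
    SeasonalTrend,
    average_temperature_trend,
    compute_phenophases,
    guild_proportions,
    guild_trend,
    host_parasitoid_lags,
)


def test_phenophase_worked_example():
    ph = compute_phenophases(
        weeks=np.arange(1, 7, dtype=float),
        values=np.array([0.0, 0.0, 2.0, 10.0, 4.0, 0.0]),
    )
    assert (ph.start_week, ph.peak_week, ph.end_week) == (3.0, 4.0, 5.0)
    assert ph.sr_min == 0.0 and ph.sr_max == 10.0


def test_phenophase_nonzero_minimum():
    ph = compute_phenophases(
        weeks=np.arange(1, 7, dtype=float),
        values=np.array([5.0, 6.0, 7.0, 8.0, 7.0, 6.0]),
    )
    # threshold 5 + 0.8 = 5.8
    assert (ph.start_week, ph.peak_week, ph.end_week) == (2.0, 4.0, 6.0)


def test_flat_trend_flagged_degenerate():
    ph = compute_phenophases(
        weeks=np.arange(1, 11, dtype=float), values=np.full(10, 3.3)
    )
    assert ph.degenerate
    assert np.isnan(ph.start_week) and np.isnan(ph.end_week)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(0.0, 100.0), min_size=3, max_size=52),
    st.floats(0.01, 50.0),
)
def test_phenophases_invariant_to_positive_rescaling(vals, c):
    weeks = np.arange(1, len(vals) + 1, dtype=float)
    a = compute_phenophases(weeks=weeks, values=np.asarray(vals))
    b = compute_phenophases(weeks=weeks, values=np.asarray(vals) * c)
    for attr in ("start_week", "peak_week", "end_week"):
        x, y = getattr(a, attr), getattr(b, attr)
        assert (np.isnan(x) and np.isnan(y)) or x == y
    if not a.degenerate:
        assert a.start_week <= a.peak_week <= a.end_week


def test_interval_from_draws():
    weeks = np.arange(1, 53, dtype=float)
    rng = np.random.default_rng(0)
    base = np.exp(-0.5 * ((weeks - 25) / 4) ** 2)
    draws = np.array(
        [np.exp(-0.5 * ((weeks - rng.normal(25, 1)) / 4) ** 2) for _ in range(200)]
    )
    ph = compute_phenophases(weeks=weeks, values=base, draws=draws)
    lo, hi = ph.intervals["peak"]
    assert lo <= 25 <= hi and hi - lo < 10


# -- temperature trend ----------------------------------------------------


def test_constant_temperature_gives_flat_trend():
    clim = pd.DataFrame(
        {"week": np.tile(np.arange(1, 53), 3), "temperature": 10.0}
    )
    curve = average_temperature_trend(clim)
    assert np.max(np.abs(curve - 10.0)) < 1e-6


def test_sinusoid_recovered():
    weeks = np.arange(1, 53, dtype=float)
    temp = 8.0 + 10.0 * np.cos(2 * np.pi * (weeks - 29) / 52)
    clim = pd.DataFrame({"week": weeks, "temperature": temp})
    curve = average_temperature_trend(clim)
    assert np.max(np.abs(curve - temp)) < 0.1


def test_trend_wraps_at_year_end():
    weeks = np.arange(1, 53, dtype=float)
    temp = 8.0 + 10.0 * np.cos(2 * np.pi * (weeks - 29) / 52)
    clim = pd.DataFrame({"week": weeks, "temperature": temp})
    w1, w53 = average_temperature_trend(clim, weeks_out=np.array([1.0, 53.0]))
    assert w1 == pytest.approx(w53, abs=1e-9)


def test_too_few_weeks_rejected():
    clim = pd.DataFrame({"week": [1, 2, 3], "temperature": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="at least"):
        average_temperature_trend(clim, k=6)


# -- guild trends from a fit ----------------------------------------------


def test_zero_guild_deviations_equalise_trends(survey_fit):
    import copy

    f, df = survey_fit
    f0 = copy.copy(f)
    f0.beta = f.beta.copy()
    for b in f.design.blocks:
        if b.term.startswith("guild_") or b.term == "habitat":
            f0.beta[b.start : b.stop] = 0.0
    temp = np.full(52, float(df["temperature"].mean()))
    trends = guild_trend(f0, temp)
    vals = np.array([t.values for t in trends.values()])
    assert np.max(np.abs(vals - vals[0])) < 1e-10


def test_constant_added_to_eta_scales_trend(survey_fit):
    import copy

    f, df = survey_fit
    temp = np.full(52, float(df["temperature"].mean()))
    t1 = guild_trend(f, temp)
    f2 = copy.copy(f)
    f2.beta = f.beta.copy()
    f2.beta[0] += 0.7  # intercept shift = constant added to eta
    t2 = guild_trend(f2, temp)
    for g in t1:
        assert np.allclose(t2[g].values, np.exp(0.7) * t1[g].values, rtol=1e-12)


# -- lags and proportions --------------------------------------------------


def _phase(g, peak):
    return PhenophaseEstimate(
        guild=g, start_week=peak - 5, peak_week=peak, end_week=peak + 5,
        sr_min=0.0, sr_max=1.0,
    )


def test_lag_table_simple():
    phases = {
        "phytophage": _phase("phytophage", 20.0),
        "phytophage_parasitoid": _phase("phytophage_parasitoid", 24.0),
        "predator": _phase("predator", 22.0),
        "predator_parasitoid": _phase("predator_parasitoid", 22.0),
    }
    out = host_parasitoid_lags(phases)
    assert set(out["host"]) == {"phytophage", "predator"}  # saprophage omitted
    assert out.set_index("host").loc["phytophage", "lag_weeks"] == 4.0
    assert out.set_index("host").loc["predator", "lag_weeks"] == 0.0


def test_guild_proportions_shares_and_ratio():
    weeks = np.arange(1, 53, dtype=float)
    vals = {
        "phytophage": 6.0,
        "predator": 3.0,
        "saprophage": 1.0,
        "phytophage_parasitoid": 0.0,
        "predator_parasitoid": 0.0,
        "saprophage_parasitoid": 0.0,
    }
    trends = {
        g: SeasonalTrend(g, weeks, np.full(52, v)) for g, v in vals.items()
    }
    out = guild_proportions(trends, weeks=(26.0,))
    shares = out[~out["guild"].str.contains(":")].set_index("guild")[
        "proportion"
    ]
    assert shares["phytophage"] == pytest.approx(0.6)
    assert shares["predator"] == pytest.approx(0.3)
    assert shares.sum() == pytest.approx(1.0, abs=1e-12)
    ratio = out[out["guild"] == "phytophage_parasitoid:phytophage"][
        "proportion"
    ].item()
    assert ratio == pytest.approx(0.0)


def test_parasitoid_host_ratio_value():
    weeks = np.arange(1, 4, dtype=float)
    trends = {
        "phytophage": SeasonalTrend("phytophage", weeks, np.full(3, 10.0)),
        "phytophage_parasitoid": SeasonalTrend(
            "phytophage_parasitoid", weeks, np.full(3, 1.2)
        ),
    }
    out = guild_proportions(trends, weeks=(2.0,))
    ratio = out[out["guild"] == "phytophage_parasitoid:phytophage"][
        "proportion"
    ].item()
    assert ratio == pytest.approx(0.12)
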