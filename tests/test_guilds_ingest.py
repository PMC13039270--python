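"""Guild assignment and table aggregation rules."""

import numpy as np
import pandas as pd
import pytest

from guildgam.guilds import GUILDS, TraitTableError, assign_guilds
from guildgam.ingest import (
    aggregate_habitat,
    aggregate_richness,
    build_richness_table,
    weekly_climate,
)
from guildgam.simulate import (
    SimulationConfig,
    occurrences_from_richness,
    simulate_survey,
    toy_trait_table,
)


@pytest.fixture
def traits():
    return pd.DataFrame(
        {
            "taxon_group": ["Ichneumonidae", "Pimplinae", "Chrysomelidae",
                            "Carabidae"],
            "guild": ["predator_parasitoid", "phytophage_parasitoid",
                      "phytophage", "predator"],
        }
    )


def test_subfamily_precedes_family(traits):
    otus = pd.DataFrame(
        {
            "otu_id": ["o1"],
            "family": ["Ichneumonidae"],
            "subfamily": ["Pimplinae"],
        }
    )
    out = assign_guilds(otus, traits)
    assert out.loc[0, "guild"] == "phytophage_parasitoid"


def test_unmatched_family_flagged(traits):
    otus = pd.DataFrame({"otu_id": ["o1"], "family": ["Syrphidae"]})
    out = assign_guilds(otus, traits)
    assert bool(out.loc[0, "unassigned"])
    assert pd.isna(out.loc[0, "guild"])


def test_guild_counts(traits):
    otus = pd.DataFrame(
        {
            "otu_id": ["A", "B", "C"],
            "family": ["Chrysomelidae", "Chrysomelidae", "Carabidae"],
        }
    )
    counts = assign_guilds(otus, traits)["guild"].value_counts()
    assert counts["phytophage"] == 2 and counts["predator"] == 1


def test_duplicate_taxon_group_rejected(traits):
    dup = pd.concat([traits, traits.iloc[[0]]], ignore_index=True)
    with pytest.raises(TraitTableError, match="duplicate"):
        assign_guilds(pd.DataFrame({"otu_id": [], "family": []}), dup)


def test_assignment_order_independent(traits):
    otus = pd.DataFrame(
        {
            "otu_id": ["A", "B", "C"],
            "family": ["Chrysomelidae", "Carabidae", "Ichneumonidae"],
        }
    )
    a = assign_guilds(otus, traits)
    b = assign_guilds(otus.iloc[::-1].reset_index(drop=True), traits)
    merged = a.merge(b, on="otu_id", suffixes=("_a", "_b"))
    assert (merged["guild_a"] == merged["guild_b"]).all()


# -- aggregation ----------------------------------------------------------


def _samples():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "site_id": ["X", "X", "Y"],
            "week": [20, 20, 21],
            "exposure_days": [7.0, 7.0, 7.0],
        }
    )


def test_distinct_count_and_zero_fill():
    occ = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1"],
            "otu_id": ["A", "A", "B"],
            "guild": ["phytophage"] * 3,
        }
    )
    out = aggregate_richness(occ, _samples(), guilds=("phytophage", "predator"))
    row = out[(out.site_id == "X") & (out.guild == "phytophage")]
    assert row["richness"].item() == 2  # duplicate A counted once
    zero = out[(out.site_id == "Y") & (out.guild == "predator")]
    assert zero["richness"].item() == 0  # sampled week, absent guild


def test_same_site_week_samples_pooled():
    occ = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "otu_id": ["A", "A"],  # same OTU seen in both pooled samples
            "guild": ["phytophage", "phytophage"],
        }
    )
    out = aggregate_richness(occ, _samples(), guilds=("phytophage",))
    row = out[(out.site_id == "X") & (out.week == 20)]
    assert row["richness"].item() == 1
    assert row["exposure_days"].item() == 14.0  # exposures summed


def test_unknown_sample_id_rejected():
    occ = pd.DataFrame(
        {"sample_id": ["nope"], "otu_id": ["A"], "guild": ["phytophage"]}
    )
    with pytest.raises(ValueError, match="nope"):
        aggregate_richness(occ, _samples())


def test_richness_conserves_distinct_otus():
    rng = np.random.default_rng(5)
    guilds = list(GUILDS)
    occ = pd.DataFrame(
        {
            "sample_id": rng.choice(["s1", "s3"], 60),
            "otu_id": [f"o{i}" for i in rng.integers(0, 25, 60)],
            "guild": rng.choice(guilds, 60),
        }
    ).drop_duplicates(["sample_id", "otu_id"])  # a given OTU has one guild
    occ = occ.drop_duplicates(["sample_id", "otu_id"])
    out = aggregate_richness(occ, _samples())
    for sid, grp in occ.groupby("sample_id"):
        site = _samples().set_index("sample_id").loc[sid, "site_id"]
        total = out[out.site_id == site]["richness"].sum()
        assert total == grp["otu_id"].nunique()


def test_round_trip_from_synthetic_survey():
    """Expanding richness to occurrences and re-aggregating is lossless."""
    sv = simulate_survey(SimulationConfig(n_sites=4, seed=9))
    occ = occurrences_from_richness(sv.richness, sv.samples)
    ann = assign_guilds(occ, toy_trait_table())
    agg = aggregate_richness(ann, sv.samples)
    merged = sv.richness.merge(
        agg, on=["site_id", "week", "guild"], suffixes=("_true", "_agg")
    )
    assert len(merged) == len(sv.richness)
    assert (merged["richness_true"] == merged["richness_agg"]).all()


# -- climate & habitat ----------------------------------------------------


def test_weekly_temperature_mean_of_extremes():
    daily = pd.DataFrame(
        {
            "site_id": ["X"] * 2,
            "week": [20, 20],
            "tmax": [10.0, 12.0],
            "tmin": [2.0, 4.0],
            "precipitation": [3.0, 3.0],
        }
    )
    out = weekly_climate(daily)
    assert out["temperature"].item() == pytest.approx(7.0)
    assert out["precipitation"].item() == pytest.approx(3.0)


def test_weekly_climate_single_day_and_missing():
    daily = pd.DataFrame(
        {
            "site_id": ["X", "X"],
            "week": [20, 20],
            "tmax": [5.0, np.nan],
            "tmin": [5.0, 1.0],
            "precipitation": [0.0, 99.0],
        }
    )
    out = weekly_climate(daily)  # incomplete day dropped
    assert out["temperature"].item() == pytest.approx(5.0)
    assert out["precipitation"].item() == pytest.approx(0.0)


def test_habitat_pixel_means():
    pix = pd.DataFrame(
        {
            "site_id": ["X"] * 100,
            "crop": 0.0,
            "shrub": 0.1,
            "forest": 0.5,
            "grass": np.linspace(0, 1, 100),
        }
    )
    out = aggregate_habitat(pix)
    assert out["forest"].item() == pytest.approx(0.5)
    assert out["crop"].item() == 0.0
    assert out["grass"].item() == pytest.approx(0.5, abs=1e-9)


def test_habitat_cover_out_of_range_rejected():
    pix = pd.DataFrame(
        {"site_id": ["X"], "crop": [1.2], "shrub": [0.0], "forest": [0.0],
         "grass": [0.0]}
    )
    with pytest.raises(ValueError, match="crop"):
        aggregate_habitat(pix)


def test_build_richness_table_joins_covariates():
    sv = simulate_survey(SimulationConfig(n_sites=3, seed=1))
    rich = sv.richness[["site_id", "week", "guild", "richness",
                        "exposure_days"]]
    tab = build_richness_table(
        rich,
        sv.sites[["site_id", "lat", "lon", "crop", "shrub", "forest",
                  "grass"]],
        sv.climate[["site_id", "week", "temperature", "precipitation"]],
    )
    assert {"temperature", "precipitation", "lat", "lon", "crop"} <= set(
        tab.columns
    )
    assert len(tab) == len(rich)
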