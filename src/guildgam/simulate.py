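"""Seeded synthetic Malaise-trap survey generator.

Emulates a nationwide trap network: ~200 sites spread over a ~14-degree
latitudinal gradient, sampled weekly through the growing season (weeks
14-43) and monthly otherwise, with high-latitude sites skipping the
off-season.  Guild-level richness counts are drawn from a negative binomial
whose log mean combines a guild baseline, a latitudinal decline, a cyclic
seasonal bump (host bumps preceding their parasitoids' by a configured
lag), a guild-specific response to weekly temperature anomalies, guild x
habitat-cover slopes, a site random effect and a log-exposure offset.

Temperature responses act on the *anomaly* of weekly temperature around its
site- and week-specific climatological mean, so the configured bump peak is
exactly the argmax of the noiseless true seasonal curve; this keeps season
and temperature identifiable and makes configured phenophases exact ground
truth for recovery tests.

One RNG stream per run, seeded from the config, makes every output table
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .guilds import GUILDS, HOSTS, PARASITOID_OF

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticSurvey",
    "generate_sites",
    "generate_calendar",
    "generate_climate",
    "generate_richness",
    "simulate_survey",
    "occurrences_from_richness",
    "toy_trait_table",
]

COVERS = ("crop", "shrub", "forest", "grass")

#: common habitat-cover archetypes used to seed site compositions
#: (grass-dominated, agricultural mosaic, mixed mosaic, heavily forested)
COVER_ARCHETYPES = {
    "GD": (0.0, 0.247, 0.131, 0.607),
    "AM": (0.379, 0.125, 0.238, 0.217),
    "MM": (0.218, 0.131, 0.352, 0.269),
    "HF": (0.00657, 0.0867, 0.762, 0.139),
}

#: off-season months: (mid-week index, exposure days)
OFF_SEASON_MONTHS = (
    ("jan", 3, 31.0),
    ("feb", 7, 28.0),
    ("mar", 11, 31.0),
    ("nov", 46, 30.0),
    ("dec", 50, 31.0),
)
SEASON_WEEKS = range(14, 44)  # April-October, sampled weekly


def _default_baselines():
    # log weekly off-season richness per guild; summer peaks are carried by
    # the bump amplitudes.  Saprophages stay relatively rich in winter.
    return {
        "phytophage": 0.3,
        "predator": 0.0,
        "saprophage": 1.0,
        "phytophage_parasitoid": -1.6,
        "predator_parasitoid": -2.0,
        "saprophage_parasitoid": -1.2,
    }


def _default_amplitudes():
    return {
        "phytophage": 2.3,
        "predator": 2.2,
        "saprophage": 1.8,
        "phytophage_parasitoid": 2.3,
        "predator_parasitoid": 2.2,
        "saprophage_parasitoid": 1.9,
    }


def _default_widths():
    return {g: 5.0 for g in GUILDS}


def _default_temp_effects():
    # (curve kind, scale on the anomaly axis); saturating responses level
    # off at high anomalies
    return {
        "phytophage": ("linear", 0.10),
        "predator": ("linear", 0.08),
        "saprophage": ("saturating", 0.10),
        "phytophage_parasitoid": ("linear", 0.08),
        "predator_parasitoid": ("saturating", 0.10),
        "saprophage_parasitoid": ("saturating", 0.10),
    }


def _default_habitat_slopes():
    # log-scale response to (crop, shrub, forest, grass) cover; phytophages,
    # predators and their parasitoids favour agricultural mosaics,
    # saprophages favour grassland, their parasitoids forest
    return {
        "phytophage": (0.9, 0.1, 0.2, -0.4),
        "predator": (0.7, 0.2, 0.1, -0.3),
        "saprophage": (-0.1, 0.0, -0.5, 0.6),
        "phytophage_parasitoid": (0.8, 0.1, 0.2, -0.4),
        "predator_parasitoid": (0.7, 0.1, 0.1, -0.3),
        "saprophage_parasitoid": (0.0, 0.1, 0.7, -0.5),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    Defaults emulate the study conditions: ~200 sites over latitudes
    55-69 N, weekly growing-season sampling, six guilds in three
    host-parasitoid pairs with lags of 1 (phytophages) and 5 (saprophages,
    predators) weeks, over-dispersed counts with NB dispersion theta = 5.
    """

    n_sites: int = 200
    lat_range: tuple[float, float] = (55.0, 69.0)
    lon_range: tuple[float, float] = (11.0, 24.0)
    weeks: int = 52
    host_peaks: dict = field(
        default_factory=lambda: {"phytophage": 24.0, "predator": 22.0,
                                 "saprophage": 22.0}
    )
    lags: dict = field(
        default_factory=lambda: {"phytophage": 1.0, "predator": 5.0,
                                 "saprophage": 5.0}
    )
    baselines: dict = field(default_factory=_default_baselines)
    amplitudes: dict = field(default_factory=_default_amplitudes)
    widths: dict = field(default_factory=_default_widths)
    temp_effects: dict = field(default_factory=_default_temp_effects)
    habitat_slopes: dict = field(default_factory=_default_habitat_slopes)
    site_sd: float = 0.3
    nb_dispersion: float = 5.0
    latitude_gradient: float = -0.06  # log richness per degree north
    temp_anomaly_sd: float = 1.5  # deg C around the climatological mean
    high_lat_threshold: float = 66.0  # sites above skip the off-season
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.weeks <= 52):
            raise ValueError("weeks must lie in 1..52")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion theta must be > 0")
        if self.lat_range[0] > self.lat_range[1] or self.lon_range[0] > self.lon_range[1]:
            raise ValueError("degenerate coordinate range (min > max)")
        if set(self.host_peaks) != set(HOSTS) or set(self.lags) != set(HOSTS):
            raise ValueError("host_peaks and lags must cover the three host guilds")
        if any(v < 0 for v in self.lags.values()):
            raise ValueError("host-parasitoid lags must be >= 0")
        for d in (self.baselines, self.amplitudes, self.widths,
                  self.temp_effects, self.habitat_slopes):
            if set(d) != set(GUILDS):
                raise ValueError("per-guild parameters must cover all six guilds")

    def peak_week(self, guild: str) -> float:
        """Configured peak week; parasitoid peaks are host peak + lag."""
        if guild in self.host_peaks:
            return float(self.host_peaks[guild])
        host = next(h for h, p in PARASITOID_OF.items() if p == guild)
        return float(self.host_peaks[host] + self.lags[host])

    # -- (de)serialization for YAML/JSON configs ------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lat_range"] = list(self.lat_range)
        d["lon_range"] = list(self.lon_range)
        d["temp_effects"] = {g: list(v) for g, v in self.temp_effects.items()}
        d["habitat_slopes"] = {g: list(v) for g, v in self.habitat_slopes.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("lat_range", "lon_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "temp_effects" in d:
            d["temp_effects"] = {g: tuple(v) for g, v in d["temp_effects"].items()}
        if "habitat_slopes" in d:
            d["habitat_slopes"] = {g: tuple(v) for g, v in d["habitat_slopes"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Noiseless ground truth recorded alongside a simulated survey."""

    weeks: np.ndarray  # 1..52
    curves: dict  # guild -> expected weekly richness at reference conditions
    peak_weeks: dict  # guild -> configured peak week
    start_weeks: dict
    end_weeks: dict
    habitat_slopes: dict
    site_effects: pd.DataFrame  # site_id, effect

    def to_json(self, path) -> None:
        obj = {
            "weeks": self.weeks.tolist(),
            "curves": {g: v.tolist() for g, v in self.curves.items()},
            "peak_weeks": self.peak_weeks,
            "start_weeks": self.start_weeks,
            "end_weeks": self.end_weeks,
            "habitat_slopes": {g: list(v) for g, v in self.habitat_slopes.items()},
            "site_effects": self.site_effects.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(obj))


@dataclass
class SyntheticSurvey:
    """All tables of one simulated survey plus its ground truth."""

    config: SimulationConfig
    sites: pd.DataFrame
    samples: pd.DataFrame
    climate: pd.DataFrame
    richness: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.climate.to_csv(outdir / "climate.tsv", sep="\t", index=False)
        self.richness.to_csv(outdir / "richness.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


def _rng(config: SimulationConfig, rng: np.random.Generator | None):
    return rng if rng is not None else np.random.default_rng(config.seed)


def generate_sites(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Site table: coordinates, habitat composition, site random effect.

    Habitat compositions are drawn from a uniform mixture over four common
    cover archetypes with Dirichlet-style jitter, renormalised to sum to 1.
    """
    if config.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = _rng(config, rng)
    n = config.n_sites
    lat = rng.uniform(*config.lat_range, n)
    lon = rng.uniform(*config.lon_range, n)
    arch = rng.integers(0, len(COVER_ARCHETYPES), n)
    bases = np.array(list(COVER_ARCHETYPES.values()))
    covers = bases[arch] + rng.dirichlet(np.ones(4) * 2.0, n) * 0.3
    covers = np.clip(covers, 0.0, None)
    covers /= covers.sum(axis=1, keepdims=True)
    effects = (
        rng.normal(0.0, config.site_sd, n) if config.site_sd > 0 else np.zeros(n)
    )
    df = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            **{c: covers[:, j] for j, c in enumerate(COVERS)},
            "site_effect": effects,
        }
    )
    return df


def generate_calendar(
    config: SimulationConfig, sites: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample table: one trap collection per site-week.

    Weekly samples (7-day exposure) through the growing season, weeks
    14-43; one sample per off-season month assigned to the month's
    mid-week with the month's length as exposure.  Sites above the
    high-latitude threshold skip the off-season entirely.
    """
    rows = []
    for _, s in sites.iterrows():
        for w in SEASON_WEEKS:
            rows.append((s.site_id, w, 7.0))
        if s.lat <= config.high_lat_threshold:
            for _, w, days in OFF_SEASON_MONTHS:
                rows.append((s.site_id, w, days))
    df = pd.DataFrame(rows, columns=["site_id", "week", "exposure_days"])
    df.insert(0, "sample_id", [f"M{i:05d}" for i in range(len(df))])
    return df.sort_values(["site_id", "week"], ignore_index=True)


def climatological_temperature(week, lat, lat0=55.0):
    """Deterministic seasonal temperature norm by week and latitude."""
    week = np.asarray(week, float)
    return (
        8.0
        - 0.7 * (np.asarray(lat, float) - lat0)
        + 11.0 * np.cos(2.0 * np.pi * (week - 29.0) / 52.0)
    )


def generate_climate(
    config: SimulationConfig, sites: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Weekly temperature (norm + anomaly) and precipitation per site."""
    rng = _rng(config, rng)
    weeks = np.arange(1, 53)
    recs = []
    for _, s in sites.iterrows():
        norm = climatological_temperature(weeks, s.lat, config.lat_range[0])
        anom = rng.normal(0.0, config.temp_anomaly_sd, len(weeks))
        precip = rng.gamma(2.0, 2.0, len(weeks))
        recs.append(
            pd.DataFrame(
                {
                    "site_id": s.site_id,
                    "week": weeks,
                    "temperature": norm + anom,
                    "temperature_norm": norm,
                    "precipitation": precip,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def _bump(week, peak, width, amplitude):
    """Cyclically wrapped Gaussian bump on the 52-week axis."""
    week = np.asarray(week, float)
    d = np.abs(week - peak)
    d = np.minimum(d, 52.0 - d)
    return amplitude * np.exp(-0.5 * (d / width) ** 2)


def _temp_response(kind: str, scale: float, anomaly):
    if kind == "linear":
        return scale * np.asarray(anomaly, float)
    if kind == "saturating":
        return scale * 2.0 * np.tanh(np.asarray(anomaly, float) / 2.0)
    raise ValueError(f"unknown temperature curve kind {kind!r}")


def generate_richness(
    config: SimulationConfig,
    sites: pd.DataFrame,
    calendar: pd.DataFrame,
    climate: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw NB guild richness for every sample and record the ground truth.

    The NB mean is (exposure/7) * exp(eta); eta sums the guild baseline,
    latitudinal gradient, seasonal bump, temperature-anomaly response,
    habitat-slope term and site effect.  Counts are drawn as a
    gamma-Poisson mixture, exact for real-valued dispersion.
    """
    rng = _rng(config, rng)
    if climate is None:
        climate = generate_climate(config, sites, rng)
    if not set(calendar["site_id"]) <= set(sites["site_id"]):
        raise ValueError("calendar references unknown site ids")

    base = calendar.merge(sites, on="site_id").merge(
        climate, on=["site_id", "week"]
    )
    anomaly = base["temperature"] - base["temperature_norm"]
    covers = base[list(COVERS)].to_numpy()
    out = []
    for g in GUILDS:
        eta_parts = {
            "baseline": np.full(len(base), config.baselines[g]),
            "latitude": config.latitude_gradient
            * (base["lat"].to_numpy() - config.lat_range[0]),
            "season": _bump(
                base["week"], config.peak_week(g), config.widths[g],
                config.amplitudes[g],
            ),
            "temperature": _temp_response(*config.temp_effects[g], anomaly),
            "habitat": covers @ np.asarray(config.habitat_slopes[g], float),
            "site": base["site_effect"].to_numpy(),
        }
        eta = np.zeros(len(base))
        for name, part in eta_parts.items():
            if not np.all(np.isfinite(part)):
                raise FloatingPointError(
                    f"non-finite linear-predictor component {name!r} "
                    f"for guild {g!r}"
                )
            eta = eta + part
        mu = base["exposure_days"].to_numpy() / 7.0 * np.exp(eta)
        theta = config.nb_dispersion
        y = rng.poisson(rng.gamma(theta, mu / theta))
        df = base[["site_id", "week", "exposure_days", "lat", "lon",
                   "temperature", "precipitation", *COVERS]].copy()
        df.insert(2, "guild", g)
        df.insert(3, "richness", y)
        out.append(df)
    richness = pd.concat(out, ignore_index=True)
    richness = richness.sort_values(
        ["site_id", "week", "guild"], ignore_index=True
    )

    truth = _make_truth(config, sites)
    return richness, truth


def _make_truth(config: SimulationConfig, sites: pd.DataFrame) -> SyntheticTruth:
    from .phenology import compute_phenophases  # local import, no cycle

    weeks = np.arange(1, 53, dtype=float)
    curves, peaks, starts, ends = {}, {}, {}, {}
    for g in GUILDS:
        peak = config.peak_week(g)
        curve = np.exp(
            config.baselines[g]
            + _bump(weeks, peak, config.widths[g], config.amplitudes[g])
        )
        curves[g] = curve
        peaks[g] = peak
        ph = compute_phenophases(weeks=weeks, values=curve, guild=g)
        starts[g] = ph.start_week
        ends[g] = ph.end_week
    return SyntheticTruth(
        weeks=weeks,
        curves=curves,
        peak_weeks=peaks,
        start_weeks=starts,
        end_weeks=ends,
        habitat_slopes=dict(config.habitat_slopes),
        site_effects=sites[["site_id", "site_effect"]].copy(),
    )


def simulate_survey(config: SimulationConfig) -> SyntheticSurvey:
    """Run the full generator on a single RNG stream seeded by the config."""
    rng = np.random.default_rng(config.seed)
    sites = generate_sites(config, rng)
    samples = generate_calendar(config, sites, rng)
    climate = generate_climate(config, sites, rng)
    richness, truth = generate_richness(config, sites, samples, climate, rng)
    return SyntheticSurvey(config, sites, samples, climate, richness, truth)


# ---------------------------------------------------------------------------
# OTU-level round-trip fixtures
# ---------------------------------------------------------------------------


def toy_trait_table() -> pd.DataFrame:
    """A minimal trait table mapping one dummy family per guild."""
    return pd.DataFrame(
        {
            "taxon_group": [f"Fam_{g}" for g in GUILDS],
            "guild": list(GUILDS),
        }
    )


def occurrences_from_richness(
    richness: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Expand a guild richness table into per-sample OTU occurrences.

    Each (site, week, guild) row with richness y yields y distinct dummy
    OTUs of a guild-specific dummy family, so re-aggregating through guild
    assignment reproduces the richness table exactly.
    """
    key = samples.set_index(["site_id", "week"])["sample_id"]
    rows = []
    for r in richness.itertuples():
        sid = key.loc[(r.site_id, r.week)]
        if isinstance(sid, pd.Series):  # pooled duplicate samples: use first
            sid = sid.iloc[0]
        for i in range(int(r.richness)):
            rows.append(
                (sid, f"{r.guild}_{i:04d}", f"Fam_{r.guild}")
            )
    return pd.DataFrame(rows, columns=["sample_id", "otu_id", "family"])
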