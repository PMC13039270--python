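"""Reading survey tables and building the guild-level richness table.

The analysis consumes flat TSV tables: a sample table (one deployed
trap-week per row), OTU occurrences, a trait table, weekly (or daily)
climate summaries per site, and fractional habitat covers per site.  This
module validates them on read, aggregates occurrences to guild-level
richness per site-week (zero-filling guilds that were sampled but not
detected, never filling unsampled weeks), and attaches covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .guilds import GUILDS, assign_guilds  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

__all__ = [
    "read_table",
    "aggregate_richness",
    "weekly_climate",
    "aggregate_habitat",
    "build_richness_table",
]


def read_table(path, required: tuple[str, ...] = (), sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and check the required columns exist."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    for col in ("site_id", "week", "exposure_days"):
        if col not in samples:
            raise ValueError(f"sample table lacks column {col!r}")
    weeks = samples["week"].to_numpy()
    bad = np.flatnonzero((weeks < 1) | (weeks > 53))
    if len(bad):
        raise ValueError(f"sample weeks outside 1..53 at rows {bad[:10].tolist()}")
    if (samples["exposure_days"] <= 0).any():
        rows = np.flatnonzero(samples["exposure_days"].to_numpy() <= 0)
        raise ValueError(f"non-positive exposure at rows {rows[:10].tolist()}")
    out = samples.copy()
    # week 53 folded onto 52 to keep a fixed 52-week cyclic year
    out["week"] = out["week"].clip(upper=52).astype(int)
    return out


def aggregate_richness(
    annotated_otus: pd.DataFrame,
    samples: pd.DataFrame,
    guilds: tuple[str, ...] = GUILDS,
) -> pd.DataFrame:
    """Guild-level species richness per site-week.

    ``annotated_otus`` is the output of :func:`guilds.assign_guilds` with a
    ``sample_id`` column referencing ``samples``; richness is the number of
    distinct OTUs of a guild detected in a site-week.  Multiple samples from
    the same site and week are pooled (occurrences unioned, exposures
    summed).  Site-weeks with a deployed trap but no detections of a guild
    get richness 0; weeks with no sample are omitted.
    """
    samples = _validate_samples(samples)
    if "sample_id" not in samples:
        raise ValueError("sample table lacks column 'sample_id'")
    if "sample_id" not in annotated_otus:
        raise ValueError("occurrence table lacks column 'sample_id'")
    unknown = set(annotated_otus["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(
            f"occurrences reference unknown sample ids: {sorted(unknown)[:10]}"
        )
    occ = annotated_otus
    if "unassigned" in occ:
        occ = occ[~occ["unassigned"]]
    occ = occ.merge(
        samples[["sample_id", "site_id", "week"]], on="sample_id", how="left"
    )
    rich = (
        occ.groupby(["site_id", "week", "guild"], observed=True)["otu_id"]
        .nunique()
        .rename("richness")
        .reset_index()
    )
    # pooled effort per site-week
    effort = (
        samples.groupby(["site_id", "week"], as_index=False)["exposure_days"]
        .sum()
    )
    grid = effort.merge(pd.DataFrame({"guild": list(guilds)}), how="cross")
    out = grid.merge(rich, on=["site_id", "week", "guild"], how="left")
    out["richness"] = out["richness"].fillna(0).astype(int)
    return out


def weekly_climate(daily: pd.DataFrame) -> pd.DataFrame:
    """Weekly mean temperature and precipitation per site.

    The daily mean temperature is the mean of the daily maximum and minimum;
    the weekly value is the mean of daily means.  Days missing either
    temperature extreme are dropped with a warning.
    """
    for col in ("site_id", "week", "tmax", "tmin", "precipitation"):
        if col not in daily:
            raise ValueError(f"daily climate table lacks column {col!r}")
    d = daily.copy()
    bad = d["tmax"].isna() | d["tmin"].isna()
    if bad.any():
        logger.warning(
            "dropping %d daily records with missing temperature extremes",
            int(bad.sum()),
        )
        d = d[~bad]
    if len(d) == 0:
        raise ValueError("no complete daily climate records")
    d["tmean"] = (d["tmax"] + d["tmin"]) / 2.0
    out = (
        d.groupby(["site_id", "week"], as_index=False)
        .agg(temperature=("tmean", "mean"), precipitation=("precipitation", "mean"))
    )
    return out


def aggregate_habitat(
    pixels: pd.DataFrame, covers: tuple[str, ...] = ("crop", "shrub", "forest", "grass")
) -> pd.DataFrame:
    """Mean fractional cover per site over the surrounding landscape pixels."""
    if "site_id" not in pixels:
        raise ValueError("pixel table lacks column 'site_id'")
    for c in covers:
        if c not in pixels:
            raise ValueError(f"pixel table lacks cover column {c!r}")
        vals = pixels[c].to_numpy(float)
        bad = np.flatnonzero((vals < 0) | (vals > 1))
        if len(bad):
            raise ValueError(
                f"cover {c!r} outside [0, 1] at rows {bad[:10].tolist()}"
            )
    return pixels.groupby("site_id", as_index=False)[list(covers)].mean()


def build_richness_table(
    richness: pd.DataFrame,
    sites: pd.DataFrame,
    climate: pd.DataFrame,
    habitat: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join richness counts with climate, coordinates and habitat covers.

    ``sites`` needs ``site_id``, ``lat``, ``lon`` (habitat covers may live
    here or in a separate ``habitat`` table); ``climate`` is weekly per
    site-week.  Rows missing a climate record are dropped with a warning.
    """
    out = richness.merge(sites, on="site_id", how="left")
    if out["lat"].isna().any():
        missing = out.loc[out["lat"].isna(), "site_id"].unique()
        raise ValueError(f"sites missing coordinates: {sorted(missing)[:10]}")
    if habitat is not None:
        out = out.merge(habitat, on="site_id", how="left")
    out = out.merge(climate, on=["site_id", "week"], how="left")
    miss = out["temperature"].isna()
    if miss.any():
        logger.warning(
            "dropping %d richness rows lacking a weekly climate record",
            int(miss.sum()),
        )
        out = out[~miss]
    return out.reset_index(drop=True)
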