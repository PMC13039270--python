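"""Seasonal trends, phenophases, host-parasitoid lags and guild composition.

Guild-level seasonal trends are counterfactual predictions from a fitted
hierarchical GAM along the year: week runs 1..52, temperature follows the
cross-site average annual temperature trend (itself a cyclic penalized
smooth of weekly means), precipitation sits at its training mean, spatial
terms and random effects are zero.  Phenophases are read off each trend:

* start — first week at or above the threshold SRmin + 0.1 * SRmax,
* peak  — week of maximum richness (earliest week on ties),
* end   — last week at or above the threshold,

where SRmin/SRmax are the trend's minimum and maximum.  The minimum-richness
offset makes guilds with different absolute richness comparable.  Credible
intervals come from applying the same scan to each posterior draw of the
trend.  Host-parasitoid lags are differences of paired peak weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .guilds import HOSTS, PARASITOID_OF
from .hgam import HGAMFit, predict, simulate_posterior
from .smooths import SmoothSpec, build_cyclic_basis

__all__ = [
    "SeasonalTrend",
    "PhenophaseEstimate",
    "average_temperature_trend",
    "guild_trend",
    "compute_phenophases",
    "host_parasitoid_lags",
    "guild_proportions",
]

DEFAULT_WEEKS = np.arange(1, 53, dtype=float)


@dataclass
class SeasonalTrend:
    """Expected weekly richness for one guild, with optional posterior draws."""

    guild: str
    weeks: np.ndarray
    values: np.ndarray
    draws: np.ndarray | None = None  # (n_draws, n_weeks)
    reference: dict = field(default_factory=dict)


@dataclass
class PhenophaseEstimate:
    guild: str
    start_week: float
    peak_week: float
    end_week: float
    sr_min: float
    sr_max: float
    intervals: dict = field(default_factory=dict)  # phase -> (lo, hi)
    degenerate: bool = False


def average_temperature_trend(
    climate: pd.DataFrame,
    k: int = 6,
    weeks_out: np.ndarray = DEFAULT_WEEKS,
) -> np.ndarray:
    """Cyclic penalized smooth of cross-site weekly mean temperature.

    The smoothing parameter is chosen by generalized cross-validation over a
    log-spaced grid; returns the curve evaluated at ``weeks_out``.
    """
    if not {"week", "temperature"} <= set(climate.columns):
        raise ValueError("climate table needs 'week' and 'temperature'")
    weekly = climate.groupby("week", as_index=False)["temperature"].mean()
    if len(weekly) < k:
        raise ValueError(
            f"need at least k={k} distinct weeks, got {len(weekly)}"
        )
    x = weekly["week"].to_numpy(float)
    y = weekly["temperature"].to_numpy(float)
    spec = SmoothSpec("cyclic_cubic", ("week",), k=k, period=52.0)
    basis = build_cyclic_basis(x, spec)
    X = np.hstack([np.ones((len(x), 1)), basis.X])
    S = np.zeros((X.shape[1], X.shape[1]))
    S[1:, 1:] = basis.S_wiggle
    best = None
    for lam in np.logspace(-4, 6, 41):
        A = X.T @ X + lam * S
        coef = np.linalg.solve(A, X.T @ y)
        H_tr = np.trace(np.linalg.solve(A, X.T @ X))
        resid = y - X @ coef
        gcv = len(y) * (resid @ resid) / max(len(y) - H_tr, 1e-6) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, coef)
    coef = best[1]
    Xo = np.hstack(
        [np.ones((len(weeks_out), 1)), basis.evaluate(np.asarray(weeks_out, float))]
    )
    return Xo @ coef


def guild_trend(
    fit: HGAMFit,
    temperature_curve: np.ndarray,
    n_draws: int = 0,
    rng: np.random.Generator | int | None = None,
    weeks: np.ndarray = DEFAULT_WEEKS,
    reference: dict | None = None,
) -> dict[str, SeasonalTrend]:
    """Counterfactual weekly richness per guild along the temperature trend.

    Precipitation and habitat covers sit at their training means (overridable
    via ``reference``); spatial smooths and site random effects are excluded
    (set to zero).  Predictions are per standard 7-day trap week.
    """
    design = fit.design
    ref = dict(design.reference)
    if reference:
        ref.update(reference)
    terms = tuple(
        t for t in {b.term for b in design.blocks}
        if t not in ("global_space", "guild_space", "site_effect")
    )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trends: dict[str, SeasonalTrend] = {}
    guilds = design.guilds or ("all",)
    for g in guilds:
        nd = pd.DataFrame(
            {
                "week": np.asarray(weeks, float),
                "temperature": np.asarray(temperature_curve, float),
                "guild": g,
            }
        )
        for col in ("precipitation", *design.spec.covers):
            if col in ref:
                nd[col] = ref[col]
        vals = predict(fit, nd, terms=terms, offset=0.0)
        draws = None
        if n_draws:
            draws = simulate_posterior(
                fit, nd, n_draws, rng=rng, terms=terms, offset=0.0
            )
        trends[g] = SeasonalTrend(
            guild=g, weeks=np.asarray(weeks, float), values=vals, draws=draws,
            reference=ref,
        )
    return trends


def _scan_phases(weeks: np.ndarray, v: np.ndarray):
    """Threshold scan of one trend: (start, peak, end, srmin, srmax, degenerate)."""
    srmin = float(v.min())
    srmax = float(v.max())
    tau = srmin + srmax * 10.0 / 100.0
    peak = float(weeks[int(np.argmax(v))])  # earliest week on ties
    above = v >= tau
    if srmax <= srmin or not above.any():  # flat trend: no season to delimit
        return (np.nan, peak, np.nan, srmin, srmax, True)
    start = float(weeks[int(np.argmax(above))])
    end = float(weeks[len(v) - 1 - int(np.argmax(above[::-1]))])
    return (start, peak, end, srmin, srmax, False)


def compute_phenophases(
    trend: SeasonalTrend | None = None,
    *,
    weeks: np.ndarray | None = None,
    values: np.ndarray | None = None,
    draws: np.ndarray | None = None,
    guild: str = "",
    ci: tuple[float, float] = (2.5, 97.5),
) -> PhenophaseEstimate:
    """Start/peak/end weeks of a seasonal trend.

    Accepts either a :class:`SeasonalTrend` or raw ``weeks``/``values``
    arrays.  A completely flat trend has no crossing of its threshold
    (the threshold exceeds every value); it is returned with ``degenerate``
    set rather than raising.
    """
    if trend is not None:
        weeks = trend.weeks
        values = trend.values
        draws = trend.draws if draws is None else draws
        guild = guild or trend.guild
    weeks = np.asarray(weeks, float)
    values = np.asarray(values, float)
    if len(weeks) < 3:
        raise ValueError("trend needs at least 3 weeks")
    start, peak, end, srmin, srmax, degen = _scan_phases(weeks, values)
    intervals = {}
    if draws is not None and len(draws):
        phases = np.array([_scan_phases(weeks, d)[:3] for d in draws])
        for i, name in enumerate(("start", "peak", "end")):
            col = phases[:, i]
            col = col[np.isfinite(col)]
            if len(col):
                intervals[name] = (
                    float(np.percentile(col, ci[0])),
                    float(np.percentile(col, ci[1])),
                )
    return PhenophaseEstimate(
        guild=guild,
        start_week=start,
        peak_week=peak,
        end_week=end,
        sr_min=srmin,
        sr_max=srmax,
        intervals=intervals,
        degenerate=degen,
    )


def host_parasitoid_lags(
    phenophases: dict[str, PhenophaseEstimate],
    trends: dict[str, SeasonalTrend] | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Peak-week lag (parasitoid - host) per host-parasitoid pair.

    When ``trends`` with paired posterior draws are supplied, a credible
    interval of each lag is computed from draw-wise paired peak weeks.
    Pairs with a missing member are omitted with a warning column absent.
    """
    rows = []
    for host in HOSTS:
        para = PARASITOID_OF[host]
        if host not in phenophases or para not in phenophases:
            continue
        lag = phenophases[para].peak_week - phenophases[host].peak_week
        lo = hi = np.nan
        if (
            trends is not None
            and host in trends
            and para in trends
            and trends[host].draws is not None
            and trends[para].draws is not None
        ):
            wk = trends[host].weeks
            ph = wk[np.argmax(trends[host].draws, axis=1)]
            pp = wk[np.argmax(trends[para].draws, axis=1)]
            lags = pp - ph
            lo, hi = np.percentile(lags, ci)
        rows.append(
            {
                "host": host,
                "parasitoid": para,
                "host_peak": phenophases[host].peak_week,
                "parasitoid_peak": phenophases[para].peak_week,
                "lag_weeks": lag,
                "lag_lo": lo,
                "lag_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def guild_proportions(
    trends: dict[str, SeasonalTrend],
    weeks: tuple[float, ...] = (10.0, 26.0, 40.0),
) -> pd.DataFrame:
    """Guild shares of total richness and parasitoid:host ratios by week.

    At each selected week, each guild's proportion of the summed expected
    richness is reported (flagged undefined when the total is zero), plus
    the parasitoid:host richness ratio for each pair.
    """
    names = list(trends)
    rows = []
    for w in weeks:
        vals = {}
        for g in names:
            t = trends[g]
            idx = int(np.argmin(np.abs(t.weeks - w)))
            vals[g] = float(t.values[idx])
        total = sum(vals.values())
        for g in names:
            rows.append(
                {
                    "week": w,
                    "guild": g,
                    "richness": vals[g],
                    "proportion": vals[g] / total if total > 0 else np.nan,
                    "undefined": total <= 0,
                }
            )
        for host in HOSTS:
            para = PARASITOID_OF[host]
            if host in vals and para in vals:
                rows.append(
                    {
                        "week": w,
                        "guild": f"{para}:{host}",
                        "richness": np.nan,
                        "proportion": (
                            vals[para] / vals[host] if vals[host] > 0 else np.nan
                        ),
                        "undefined": vals[host] <= 0,
                    }
                )
    return pd.DataFrame(rows)
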