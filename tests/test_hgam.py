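"""HGAM engine: design bookkeeping, fitting oracles, prediction contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from guildgam.hgam import (
    ModelSpec,
    assemble_design,
    fit,
    log_exposure_offset,
    nb_deviance,
    nb_loglik,
    predict,
    simulate_posterior,
)

RNG = np.random.default_rng(21)


def _two_guild_frame(n=300):
    week = RNG.uniform(1, 53, n)
    guild = RNG.choice(["hostA", "paraA"], n)
    mu = np.exp(0.8 + 1.2 * np.exp(-0.5 * ((week - 24) / 5) ** 2))
    y = RNG.poisson(mu)
    return pd.DataFrame({"richness": y, "week": week, "guild": guild})


def test_design_dimension_bookkeeping_two_guilds():
    """Season-only model, 2 guilds: 5-col global + two 5-col guild blocks
    under a single shared wiggliness penalty."""
    df = _two_guild_frame()
    spec = ModelSpec(
        global_smooths=("season",),
        guild_smooths=("season",),
        habitat_slopes=False,
        guild_intercepts=False,
        site_effects=False,
    )
    d = assemble_design(df, spec)
    widths = {b.name: b.stop - b.start for b in d.blocks}
    assert widths["global_season"] == 5
    assert widths["guild_season:hostA"] == 5
    assert widths["guild_season:paraA"] == 5
    wig = [p for p in d.penalties if p.name == "wiggle_season"]
    assert len(wig) == 1 and len(wig[0].cols) == 15


def test_guild_intercepts_are_ridge_penalized():
    df = _two_guild_frame()
    df["guild"] = RNG.choice([f"g{i}" for i in range(6)], len(df))
    spec = ModelSpec(
        global_smooths=("season",),
        guild_smooths=(),
        habitat_slopes=False,
        guild_intercepts=True,
        site_effects=False,
    )
    d = assemble_design(df, spec)
    blk = next(b for b in d.blocks if b.term == "guild_intercept")
    assert blk.stop - blk.start == 6
    pen = next(p for p in d.penalties if p.name == "ridge_guild_intercept")
    assert np.array_equal(pen.S, np.eye(6))


def test_missing_covariate_row_named():
    df = _two_guild_frame(50)
    df.loc[7, "week"] = np.nan
    spec = ModelSpec(
        global_smooths=("season",), guild_smooths=(),
        habitat_slopes=False, guild_intercepts=False, site_effects=False,
    )
    with pytest.raises(ValueError, match="7"):
        assemble_design(df, spec)


def test_intercept_only_nb_fit_is_log_mean():
    df = pd.DataFrame({"richness": [2, 2, 2, 2]})
    spec = ModelSpec(global_smooths=(), guild_smooths=(), habitat_slopes=False,
                     guild_intercepts=False, site_effects=False)
    d = assemble_design(df, spec)
    f = fit(d, df["richness"].to_numpy(), theta=1.0, select=False)
    assert f.beta[0] == pytest.approx(np.log(2.0), abs=1e-6)


def test_nb_loglik_closed_form_points():
    assert nb_loglik(np.array([0]), np.array([1.0]), 1.0) == pytest.approx(
        np.log(0.5), abs=1e-12
    )
    # theta/(theta+mu))^theta at y=0, mu=2, theta=3
    assert nb_loglik(np.array([0]), np.array([2.0]), 3.0) == pytest.approx(
        3.0 * np.log(3.0 / 5.0), abs=1e-12
    )


def test_negative_counts_rejected():
    df = pd.DataFrame({"richness": [1, -1, 2]})
    spec = ModelSpec(global_smooths=(), guild_smooths=(), habitat_slopes=False,
                     guild_intercepts=False, site_effects=False)
    d = assemble_design(df, spec)
    with pytest.raises(ValueError, match="non-negative"):
        fit(d, df["richness"].to_numpy())


def test_pirls_matches_direct_penalized_optimum_fixed_lambda():
    """At fixed lambda the PIRLS solution is the penalized NB ML optimum."""
    n = 50
    rng = np.random.default_rng(3)
    x = rng.uniform(-2, 2, n)
    y = rng.poisson(np.exp(0.5 + np.sin(x)))
    df = pd.DataFrame({"richness": y, "temperature": x})
    spec = ModelSpec(global_smooths=("temp",), guild_smooths=(),
                     habitat_slopes=False, guild_intercepts=False,
                     site_effects=False)
    d = assemble_design(df, spec)
    lam = {p.name: 2.5 for p in d.penalties}
    f = fit(d, y, theta=4.0, lambdas=lam, select=False)
    X = d.X.toarray()
    S = d.total_penalty(lam)

    def obj(b):
        mu = np.exp(X @ b)
        return -nb_loglik(y, mu, 4.0) + 0.5 * b @ S @ b

    res = minimize(obj, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    assert np.max(np.abs(f.beta - res.x)) < 1e-5


def test_infinite_lambda_drives_edf_to_null_dimension():
    n = 400
    rng = np.random.default_rng(8)
    x = rng.uniform(-2, 2, n)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    df = pd.DataFrame({"richness": y, "temperature": x})
    spec = ModelSpec(global_smooths=("temp",), guild_smooths=(),
                     habitat_slopes=False, guild_intercepts=False,
                     site_effects=False)
    d = assemble_design(df, spec)
    # wiggliness penalized out, null space left free: EDF -> null dim (1)
    f1 = fit(d, y, theta=10.0, select=False,
             lambdas={"wiggle_temp": 1e9, "null_temp_global": 1e-7})
    assert f1.edf("global_temp") == pytest.approx(1.0, abs=0.05)
    # double penalty: whole term removed
    f2 = fit(d, y, theta=10.0, select=False,
             lambdas={"wiggle_temp": 1e9, "null_temp_global": 1e9})
    assert f2.edf("global_temp") < 0.01


def test_predict_round_trip_and_term_subsets(survey_fit):
    f, df = survey_fit
    mu_hat = predict(f, df)
    X = f.design.X
    eta = X @ f.beta + log_exposure_offset(df)
    assert np.max(np.abs(mu_hat - np.exp(eta))) < 1e-10
    # all terms excluded: exp(intercept) only
    p0 = predict(f, df.head(5), terms=(), offset=0.0)
    assert np.allclose(p0, np.exp(f.beta[0]))


def test_offset_contract_doubles_counts(survey_fit):
    f, df = survey_fit
    p1 = predict(f, df.assign(exposure_days=7.0))
    p2 = predict(f, df.assign(exposure_days=14.0))
    assert np.array_equal(p2, 2.0 * p1)


def test_posterior_draws_seeded_and_degenerate(survey_fit):
    import copy

    f, df = survey_fit
    nd = df.head(20)
    d1 = simulate_posterior(f, nd, 50, rng=123)
    d2 = simulate_posterior(f, nd, 50, rng=123)
    assert np.array_equal(d1, d2)
    f0 = copy.copy(f)
    f0.V = np.zeros_like(f.V)
    d0 = simulate_posterior(f0, nd, 20, rng=0, offset=0.0)
    point = predict(f0, nd, offset=0.0)
    assert np.allclose(d0, point[None, :], atol=1e-12)


def test_fit_serialization_round_trip(tmp_path, survey_fit):
    from guildgam.hgam import HGAMFit

    f, df = survey_fit
    path = tmp_path / "model.json"
    f.to_json(path)
    f2 = HGAMFit.from_json(path)
    nd = df.head(50)
    assert np.allclose(predict(f, nd), predict(f2, nd), atol=1e-10)
    assert f2.theta == f.theta


def test_deviance_zero_at_saturation():
    y = np.array([1.0, 4.0, 7.0])
    assert nb_deviance(y, y, 3.0) == pytest.approx(0.0, abs=1e-12)
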