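"""Hierarchical negative-binomial GAM engine.

The model has two levels.  A global linear predictor carries smooth effects
shared by all guilds — a cyclic seasonal smooth of week, thin-plate smooths of
weekly temperature and precipitation, and an isotropic 2-D thin-plate smooth
of (lon, lat).  Guild-level deviation smooths of the same covariates, guild x
habitat-cover random slopes, guild random intercepts and trap x guild random
effects are added on top.  Guild deviation smooths share one wiggliness
smoothing parameter with their global counterpart, so all guilds share the
same degree of flexibility; separate null-space shrinkage penalties (the
double penalty) let whole terms be removed during fitting.  The response is
negative binomial with log link and a log-exposure offset normalised so that
a standard 7-day trap week has offset zero.

Fitting is penalized IRLS inside an outer loop that updates every smoothing
parameter with extended Fellner-Schall restricted-marginal-likelihood steps
and profiles the NB dispersion.  The coefficient posterior is approximated as
Gaussian with covariance (X'WX + S_lambda)^{-1}, from which credible
intervals for derived quantities are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .smooths import PenalizedBasis, SmoothSpec, build_smooth

__all__ = [
    "ModelSpec",
    "HGAMDesign",
    "HGAMFit",
    "assemble_design",
    "fit",
    "predict",
    "simulate_posterior",
    "nb_loglik",
    "nb_deviance",
]

#: covariate columns used by each smooth-term family
FAMILY_COVS = {
    "season": ("week",),
    "temp": ("temperature",),
    "precip": ("precipitation",),
    "space": ("lon", "lat"),
}
FAMILY_KIND = {
    "season": "cyclic_cubic",
    "temp": "thinplate_1d",
    "precip": "thinplate_1d",
    "space": "thinplate_2d",
}

WEEKS_PER_YEAR = 52.0
REFERENCE_EXPOSURE_DAYS = 7.0


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the stacked two-level design.

    The default reproduces the full model: four global smooths, four guild
    deviation smooths per guild, guild x habitat random slopes, guild random
    intercepts and trap x guild random effects, NB dispersion estimated.
    """

    guilds: tuple[str, ...] = ()
    covers: tuple[str, ...] = ("crop", "shrub", "forest", "grass")
    k: int = 6
    global_smooths: tuple[str, ...] = ("season", "temp", "precip", "space")
    guild_smooths: tuple[str, ...] = ("season", "temp", "precip", "space")
    linear_terms: tuple[str, ...] = ()
    habitat_slopes: bool = True
    guild_intercepts: bool = True
    site_effects: bool = True
    theta: float | None = None  # None -> estimated

    def __post_init__(self):
        for f in self.global_smooths + self.guild_smooths:
            if f not in FAMILY_COVS:
                raise ValueError(f"unknown smooth family {f!r}")


@dataclass
class Block:
    """One contiguous column block of the stacked design."""

    name: str  # e.g. "global_season", "guild_season:predator"
    term: str  # logical term: "global_season", "guild_season", "habitat", ...
    start: int
    stop: int
    guild: str | None = None

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class Penalty:
    name: str
    cols: np.ndarray
    S: np.ndarray


class HGAMDesign:
    """Stacked design matrix, penalty list and prediction-time transforms."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.bases: dict[str, PenalizedBasis] = {}
        self.blocks: list[Block] = []
        self.penalties: list[Penalty] = []
        self.guilds: tuple[str, ...] = ()
        self.sites: tuple = ()
        self.n_cols = 0
        self.reference: dict[str, float] = {}
        self.X: sp.csr_matrix | None = None

    # -- assembly --------------------------------------------------------

    @classmethod
    def assemble(cls, data: pd.DataFrame, spec: ModelSpec) -> "HGAMDesign":
        d = cls(spec)
        guilds = spec.guilds or tuple(
            sorted(data["guild"].unique()) if "guild" in data else ()
        )
        d.guilds = tuple(guilds)
        needs_guild = bool(
            spec.guild_smooths or spec.habitat_slopes or spec.guild_intercepts
        ) and len(d.guilds) > 0
        if needs_guild and "guild" not in data:
            raise ValueError("data must carry a 'guild' column")
        if spec.site_effects:
            if "site_id" not in data:
                raise ValueError("site effects need a 'site_id' column")
            d.sites = tuple(sorted(map(str, data["site_id"].unique())))

        families = sorted(
            set(spec.global_smooths) | set(spec.guild_smooths),
            key=list(FAMILY_COVS).index,
        )
        for fam in families:
            covs = FAMILY_COVS[fam]
            _check_covariates(data, covs)
            x = data[list(covs)].to_numpy(float)
            if len(covs) == 1:
                x = x.ravel()
            sspec = SmoothSpec(
                kind=FAMILY_KIND[fam],
                covariates=covs,
                k=spec.k,
                period=WEEKS_PER_YEAR if fam == "season" else None,
            )
            d.bases[fam] = build_smooth(x, sspec)

        # column layout
        pos = 0

        def add_block(name, term, width, guild=None):
            nonlocal pos
            d.blocks.append(Block(name, term, pos, pos + width, guild))
            pos += width

        add_block("intercept", "intercept", 1)
        for col in spec.linear_terms:
            _check_covariates(data, (col,))
            add_block(f"linear_{col}", f"linear_{col}", 1)
        for fam in spec.global_smooths:
            add_block(f"global_{fam}", f"global_{fam}", d.bases[fam].p)
        for fam in spec.guild_smooths:
            for g in d.guilds:
                add_block(f"guild_{fam}:{g}", f"guild_{fam}", d.bases[fam].p, g)
        if spec.habitat_slopes and d.guilds:
            _check_covariates(data, spec.covers)
            add_block("habitat", "habitat", len(spec.covers) * len(d.guilds))
        if spec.guild_intercepts and d.guilds:
            add_block("guild_intercept", "guild_intercept", len(d.guilds))
        if spec.site_effects:
            add_block("site_effect", "site_effect", len(d.sites) * max(len(d.guilds), 1))
        d.n_cols = pos

        d._build_penalties()
        d.X = d.model_matrix(data)
        d.reference = _reference_values(data, spec)
        return d

    def _build_penalties(self):
        spec = self.spec
        by_term: dict[str, list[Block]] = {}
        for b in self.blocks:
            by_term.setdefault(b.term, []).append(b)
        for fam in sorted(
            set(spec.global_smooths) | set(spec.guild_smooths),
            key=list(FAMILY_COVS).index,
        ):
            basis = self.bases[fam]
            wiggle_blocks = by_term.get(f"global_{fam}", []) + by_term.get(
                f"guild_{fam}", []
            )
            cols = np.concatenate([b.cols for b in wiggle_blocks])
            S = _blockdiag([basis.S_wiggle] * len(wiggle_blocks))
            self.penalties.append(Penalty(f"wiggle_{fam}", cols, S))
            if np.any(basis.S_null):
                if f"global_{fam}" in by_term:
                    b = by_term[f"global_{fam}"][0]
                    self.penalties.append(
                        Penalty(f"null_{fam}_global", b.cols, basis.S_null.copy())
                    )
                gblocks = by_term.get(f"guild_{fam}", [])
                if gblocks:
                    cols_g = np.concatenate([b.cols for b in gblocks])
                    self.penalties.append(
                        Penalty(
                            f"null_{fam}_guild",
                            cols_g,
                            _blockdiag([basis.S_null] * len(gblocks)),
                        )
                    )
        for term, name in [
            ("habitat", "ridge_habitat"),
            ("guild_intercept", "ridge_guild_intercept"),
            ("site_effect", "ridge_site"),
        ]:
            if term in by_term:
                b = by_term[term][0]
                self.penalties.append(
                    Penalty(name, b.cols, np.eye(b.stop - b.start))
                )

    # -- model matrix ----------------------------------------------------

    def model_matrix(
        self, data: pd.DataFrame, terms: tuple[str, ...] | None = None
    ) -> sp.csr_matrix:
        """Sparse design for ``data``.

        ``terms`` restricts to a subset of logical term names; excluded
        blocks contribute zero columns (the matrix keeps full width so the
        coefficient vector always applies).  The intercept is always
        included.
        """
        n = len(data)
        spec = self.spec
        parts: list[sp.spmatrix] = []

        def include(term):
            return terms is None or term == "intercept" or term in terms

        guild_col = (
            data["guild"].astype(str).to_numpy() if "guild" in data else None
        )
        smooth_cache: dict[str, np.ndarray] = {}

        def fam_design(fam):
            if fam not in smooth_cache:
                covs = FAMILY_COVS[fam]
                _check_covariates(data, covs)
                x = data[list(covs)].to_numpy(float)
                if len(covs) == 1:
                    x = x.ravel()
                smooth_cache[fam] = self.bases[fam].evaluate(x)
            return smooth_cache[fam]

        for b in self.blocks:
            w = b.stop - b.start
            if not include(b.term):
                parts.append(sp.csr_matrix((n, w)))
                continue
            if b.term == "intercept":
                parts.append(sp.csr_matrix(np.ones((n, 1))))
            elif b.term.startswith("linear_"):
                col = b.term[len("linear_") :]
                _check_covariates(data, (col,))
                parts.append(sp.csr_matrix(data[col].to_numpy(float)[:, None]))
            elif b.term == "guild_intercept":
                gi = {g: i for i, g in enumerate(self.guilds)}
                idx = np.array([gi[g] for g in guild_col])
                parts.append(
                    sp.csr_matrix(
                        (np.ones(n), (np.arange(n), idx)), shape=(n, w)
                    )
                )
            elif b.term.startswith("global_"):
                parts.append(sp.csr_matrix(fam_design(b.term[len("global_") :])))
            elif b.term.startswith("guild_"):
                fam = b.term[len("guild_") :]
                B = fam_design(fam)
                mask = guild_col == b.guild
                M = np.where(mask[:, None], B, 0.0)
                parts.append(sp.csr_matrix(M))
            elif b.term == "habitat":
                _check_covariates(data, spec.covers)
                covers = data[list(spec.covers)].to_numpy(float)
                rows, cols_i, vals = [], [], []
                for gi, g in enumerate(self.guilds):
                    mask = np.flatnonzero(guild_col == g)
                    for hi in range(len(spec.covers)):
                        rows.append(mask)
                        cols_i.append(
                            np.full(len(mask), gi * len(spec.covers) + hi)
                        )
                        vals.append(covers[mask, hi])
                parts.append(
                    sp.csr_matrix(
                        (
                            np.concatenate(vals),
                            (np.concatenate(rows), np.concatenate(cols_i)),
                        ),
                        shape=(n, w),
                    )
                )
            elif b.term == "site_effect":
                si = {s: i for i, s in enumerate(self.sites)}
                ng = max(len(self.guilds), 1)
                gi = {g: i for i, g in enumerate(self.guilds)} if self.guilds else {}
                rows, cols_i = [], []
                site_col = data["site_id"].astype(str).to_numpy()
                for r in range(n):
                    s = site_col[r]
                    if s not in si:
                        continue  # unseen site: zero random effect
                    gidx = gi.get(guild_col[r], 0) if guild_col is not None else 0
                    rows.append(r)
                    cols_i.append(si[s] * ng + gidx)
                parts.append(
                    sp.csr_matrix(
                        (np.ones(len(rows)), (rows, cols_i)), shape=(n, w)
                    )
                )
            else:  # pragma: no cover
                raise AssertionError(b.term)
        return sp.hstack(parts, format="csr")

    # -- penalty algebra -------------------------------------------------

    def total_penalty(self, lam: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.n_cols, self.n_cols))
        for pen in self.penalties:
            S[np.ix_(pen.cols, pen.cols)] += lam[pen.name] * pen.S
        return S

    def penalty_components(self) -> list[list[Penalty]]:
        """Group penalties whose column sets overlap (for pseudo-inverses)."""
        groups: list[dict] = []
        for pen in self.penalties:
            cs = set(pen.cols.tolist())
            hit = [g for g in groups if g["cols"] & cs]
            if hit:
                merged = hit[0]
                for g in hit[1:]:
                    merged["cols"] |= g["cols"]
                    merged["pens"] += g["pens"]
                    groups.remove(g)
                merged["cols"] |= cs
                merged["pens"].append(pen)
            else:
                groups.append({"cols": cs, "pens": [pen]})
        return [g["pens"] for g in groups]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "bases": {f: b.to_dict() for f, b in self.bases.items()},
            "blocks": [
                {"name": b.name, "term": b.term, "start": b.start,
                 "stop": b.stop, "guild": b.guild}
                for b in self.blocks
            ],
            "penalties": [
                {"name": p.name, "cols": p.cols.tolist(), "S": p.S.tolist()}
                for p in self.penalties
            ],
            "guilds": list(self.guilds),
            "sites": list(self.sites),
            "n_cols": self.n_cols,
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HGAMDesign":
        sd = dict(d["spec"])
        for key in ("guilds", "covers", "global_smooths", "guild_smooths",
                    "linear_terms"):
            sd[key] = tuple(sd[key])
        obj = cls(ModelSpec(**sd))
        obj.bases = {f: PenalizedBasis.from_dict(b) for f, b in d["bases"].items()}
        obj.blocks = [Block(**b) for b in d["blocks"]]
        obj.penalties = [
            Penalty(p["name"], np.asarray(p["cols"], int), np.asarray(p["S"]))
            for p in d["penalties"]
        ]
        obj.guilds = tuple(d["guilds"])
        obj.sites = tuple(d["sites"])
        obj.n_cols = d["n_cols"]
        obj.reference = dict(d["reference"])
        return obj


def assemble_design(data: pd.DataFrame, spec: ModelSpec) -> HGAMDesign:
    """Build the stacked design + penalty list for ``data`` under ``spec``."""
    return HGAMDesign.assemble(data, spec)


def _check_covariates(data: pd.DataFrame, covs) -> None:
    for c in covs:
        if c not in data:
            raise ValueError(f"missing covariate column {c!r}")
        vals = data[c].to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals.astype(float)))
        if len(bad):
            raise ValueError(
                f"non-finite values in covariate {c!r} at rows "
                f"{bad[:10].tolist()}"
            )


def _blockdiag(mats: list[np.ndarray]) -> np.ndarray:
    p = sum(m.shape[0] for m in mats)
    S = np.zeros((p, p))
    i = 0
    for m in mats:
        S[i : i + m.shape[0], i : i + m.shape[0]] = m
        i += m.shape[0]
    return S


def _reference_values(data: pd.DataFrame, spec: ModelSpec) -> dict[str, float]:
    ref = {}
    for col in ("temperature", "precipitation", "lat", "lon"):
        if col in data:
            ref[col] = float(data[col].mean())
    for col in spec.covers:
        if col in data:
            ref[col] = float(data[col].mean())
    return ref


# ---------------------------------------------------------------------------
# negative binomial family
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Sum of NB2 log-likelihood contributions (variance mu + mu^2/theta)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def estimate_theta(y: np.ndarray, mu: np.ndarray,
                   bounds=(np.log(1e-3), np.log(1e8))) -> float:
    """Profile ML estimate of the NB dispersion at fixed means."""
    res = minimize_scalar(
        lambda lt: -nb_loglik(y, mu, np.exp(lt)),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

LAM_MIN, LAM_MAX = 1e-7, 1e11


@dataclass
class HGAMFit:
    """A fitted hierarchical NB GAM."""

    design: HGAMDesign
    beta: np.ndarray
    V: np.ndarray
    lambdas: dict[str, float]
    theta: float
    edf_table: pd.DataFrame
    deviance: float
    loglik: float
    converged: bool
    n_outer: int
    log: list[str] = field(default_factory=list)

    # convenience delegates
    def predict(self, newdata, terms=None, offset=None, type="response"):
        return predict(self, newdata, terms=terms, offset=offset, type=type)

    def simulate(self, newdata, n_draws, rng=None, terms=None, offset=None,
                 type="response"):
        return simulate_posterior(
            self, newdata, n_draws, rng=rng, terms=terms, offset=offset,
            type=type,
        )

    def edf(self, term: str) -> float:
        t = self.edf_table
        return float(t.loc[t["term"] == term, "edf"].sum())

    # serialization
    def to_json(self, path) -> None:
        obj = {
            "design": self.design.to_dict(),
            "beta": self.beta.tolist(),
            "V": self.V.tolist(),
            "lambdas": self.lambdas,
            "theta": self.theta,
            "edf_table": self.edf_table.to_dict(orient="list"),
            "deviance": self.deviance,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_outer": self.n_outer,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HGAMFit":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            design=HGAMDesign.from_dict(obj["design"]),
            beta=np.asarray(obj["beta"]),
            V=np.asarray(obj["V"]),
            lambdas=obj["lambdas"],
            theta=obj["theta"],
            edf_table=pd.DataFrame(obj["edf_table"]),
            deviance=obj["deviance"],
            loglik=obj["loglik"],
            converged=obj["converged"],
            n_outer=obj["n_outer"],
        )


def log_exposure_offset(data: pd.DataFrame) -> np.ndarray:
    """Offset log(exposure_days / 7): a standard trap-week has offset 0."""
    if "exposure_days" not in data:
        return np.zeros(len(data))
    e = data["exposure_days"].to_numpy(float)
    if np.any(e <= 0):
        raise ValueError("exposure_days must be positive")
    return np.log(e / REFERENCE_EXPOSURE_DAYS)


def _penalized_deviance(X, y, offset, beta, S_tot, theta):
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    return nb_deviance(y, mu, theta) + float(beta @ S_tot @ beta), mu, eta


def _chol_solve_sym(A, B):
    jitter = 0.0
    scale = np.mean(np.diag(A)) or 1.0
    for _ in range(8):
        try:
            c = cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
            return cho_solve(c, B), c
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * scale)
    raise np.linalg.LinAlgError(
        "penalized normal equations not positive definite; "
        "check for rank-deficient design blocks"
    )


def _pirls(X, y, offset, theta, S_tot, beta0=None, max_iter=200, tol=1e-8):
    """Penalized IRLS for the NB log link; returns converged beta and state."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        # start from the intercept-ish fit: eta = log(mean)
        mu0 = np.clip(np.mean(y), 0.1, None)
        beta, mu, eta = beta, None, None
        eta = np.full(n, np.log(mu0)) + offset * 0.0
        mu = np.exp(np.clip(eta + offset, -30, 30))
    else:
        beta = beta0.copy()
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        eta = eta - offset  # keep eta as X beta below

    pendev = nb_deviance(y, mu, theta) + float(beta @ S_tot @ beta)
    converged = False
    for it in range(max_iter):
        w = np.clip(mu * theta / (theta + mu), 1e-10, None)
        z = (np.log(mu) - offset) + (y - mu) / mu
        WX = X.multiply(w[:, None]).tocsr()
        XtWX = (X.T @ WX).toarray()
        Xtwz = X.T @ (w * z)
        beta_new, _ = _chol_solve_sym(XtWX + S_tot, Xtwz)
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            pendev_new, mu_new, _ = _penalized_deviance(
                X, y, offset, cand, S_tot, theta
            )
            if pendev_new <= pendev + 1e-10 * (abs(pendev) + 1.0):
                break
            step /= 2.0
        beta = beta + step * (beta_new - beta)
        mu = mu_new
        rel = abs(pendev - pendev_new) / (abs(pendev_new) + 0.1)
        pendev = pendev_new
        if rel < tol:
            converged = True
            break
    w = np.clip(mu * theta / (theta + mu), 1e-10, None)
    XtWX = (X.T @ X.multiply(w[:, None]).tocsr()).toarray()
    return beta, mu, XtWX, converged, it + 1


def _pinv_psd(S, tol=1e-10):
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    wmax = max(w.max(), 1e-300)
    inv = np.where(w > tol * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return (V * inv) @ V.T


def _efs_update(design, lam, V, beta):
    """Extended Fellner-Schall multiplicative update of every lambda.

    new_lambda_j = lambda_j * [tr(S^- S_j) - tr((X'WX+S)^{-1} S_j)]
                              / (beta' S_j beta)
    computed componentwise over groups of penalties with overlapping columns.
    """
    new = dict(lam)
    for group in design._components:
        cols = np.unique(np.concatenate([p.cols for p in group]))
        pos = {c: i for i, c in enumerate(cols)}
        m = len(cols)
        S_c = np.zeros((m, m))
        embed = []
        for pen in group:
            idx = np.array([pos[c] for c in pen.cols])
            Se = np.zeros((m, m))
            Se[np.ix_(idx, idx)] = pen.S
            embed.append(Se)
            S_c += lam[pen.name] * Se
        S_inv = _pinv_psd(S_c)
        Vc = V[np.ix_(cols, cols)]
        bc = beta[cols]
        for pen, Se in zip(group, embed):
            a = float(np.sum(S_inv * Se))
            b = float(np.sum(Vc * Se))
            c = float(bc @ Se @ bc)
            num = max(a - b, 0.0)
            ratio = num / max(c, 1e-12)
            ratio = float(np.clip(ratio, np.exp(-4.0), np.exp(4.0)))
            new[pen.name] = float(np.clip(lam[pen.name] * ratio, LAM_MIN, LAM_MAX))
    return new


def fit(
    design: HGAMDesign,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    *,
    theta: float | None = None,
    lambdas: dict[str, float] | None = None,
    select: bool = True,
    max_outer: int = 30,
    outer_tol: float = 0.02,
) -> HGAMFit:
    """Fit the penalized NB model.

    Parameters
    ----------
    design
        Output of :func:`assemble_design` (training design cached inside).
    y
        Non-negative integer richness counts.
    offset
        Log-scale effort offset; default all zero.
    theta
        Fixed NB dispersion; default (or ``design.spec.theta``) estimated by
        profile likelihood inside the outer loop.
    lambdas
        Fixed smoothing parameters (one per penalty name); when given and
        ``select=False`` no outer optimisation happens.
    select
        Run the Fellner-Schall outer loop over smoothing parameters.
    """
    X = design.X
    if X is None:
        raise ValueError("design carries no cached training matrix")
    y = np.asarray(y, float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    n = len(y)
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")

    lam = {p.name: 1.0 for p in design.penalties}
    if lambdas:
        lam.update(lambdas)
    if theta is None:
        theta = design.spec.theta
    fix_theta = theta is not None
    if theta is None:
        mu0 = max(np.mean(y), 0.1)
        v0 = max(np.var(y), mu0 * 1.001)
        theta = float(np.clip(mu0**2 / (v0 - mu0), 0.05, 1e4))

    design._components = design.penalty_components()
    log: list[str] = []
    beta = None
    converged_outer = not (select and design.penalties)
    outer_used = 0
    edf_prev = None
    for outer in range(max_outer if select and design.penalties else 1):
        outer_used = outer + 1
        S_tot = design.total_penalty(lam)
        beta, mu, XtWX, conv_in, n_in = _pirls(
            X, y, offset, theta, S_tot, beta0=beta
        )
        if not fix_theta:
            theta_new = estimate_theta(y, mu)
            dtheta = abs(np.log(theta_new) - np.log(theta))
            theta = theta_new
        else:
            dtheta = 0.0
        if not (select and design.penalties):
            break
        Vmat, _ = _chol_solve_sym(XtWX + design.total_penalty(lam),
                                  np.eye(design.n_cols))
        lam_new = _efs_update(design, lam, Vmat, beta)
        dlam = max(
            abs(np.log(lam_new[k]) - np.log(lam[k])) for k in lam
        )
        # lambdas of fully shrunk terms drift geometrically without changing
        # the fit; convergence is judged on per-block EDF stability instead
        edf_i = np.sum(Vmat * XtWX.T, axis=1)
        edf_blocks = np.array(
            [edf_i[b.start : b.stop].sum() for b in design.blocks]
        )
        dedf = (
            np.max(np.abs(edf_blocks - edf_prev)) if edf_prev is not None
            else np.inf
        )
        edf_prev = edf_blocks
        log.append(
            f"outer {outer}: pirls_iters={n_in} max|dloglam|={dlam:.4f} "
            f"max|dedf|={dedf if np.isfinite(dedf) else -1:.4f} "
            f"theta={theta:.4g}"
        )
        lam = lam_new
        if (dlam < outer_tol or dedf < 0.02) and dtheta < 0.01:
            converged_outer = True
            break

    S_tot = design.total_penalty(lam)
    beta, mu, XtWX, conv_in, n_in = _pirls(X, y, offset, theta, S_tot, beta0=beta)
    if not fix_theta:
        theta = estimate_theta(y, mu)
        beta, mu, XtWX, conv_in, n_in = _pirls(
            X, y, offset, theta, S_tot, beta0=beta
        )
    V, _ = _chol_solve_sym(XtWX + S_tot, np.eye(design.n_cols))
    V = 0.5 * (V + V.T)

    edf_i = np.sum(V * XtWX.T, axis=1)
    rows = []
    for b in design.blocks:
        rows.append(
            {
                "block": b.name,
                "term": b.term,
                "guild": b.guild,
                "edf": float(edf_i[b.start : b.stop].sum()),
                "n_coefs": b.stop - b.start,
            }
        )
    edf_table = pd.DataFrame(rows)

    return HGAMFit(
        design=design,
        beta=beta,
        V=V,
        lambdas=lam,
        theta=float(theta),
        edf_table=edf_table,
        deviance=nb_deviance(y, mu, theta),
        loglik=nb_loglik(y, mu, theta),
        converged=bool(conv_in and converged_outer),
        n_outer=outer_used,
        log=log,
    )


def fit_hgam(data: pd.DataFrame, spec: ModelSpec | None = None, **kwargs) -> HGAMFit:
    """Convenience wrapper: assemble the design from a guild richness table
    (columns ``richness`` and ``exposure_days`` expected) and fit."""
    spec = spec or ModelSpec()
    design = assemble_design(data, spec)
    return fit(
        design,
        data["richness"].to_numpy(),
        log_exposure_offset(data),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# prediction and posterior simulation
# ---------------------------------------------------------------------------


def _resolve_offset(newdata, offset, n):
    if offset is None:
        if isinstance(newdata, pd.DataFrame) and "exposure_days" in newdata:
            return log_exposure_offset(newdata)
        return np.zeros(n)
    offset = np.asarray(offset, float)
    if offset.ndim == 0:
        return np.full(n, float(offset))
    return offset


def _effort_factor(newdata, offset, n):
    """Multiplicative response-scale effort, exact in exposure ratios."""
    if offset is None and isinstance(newdata, pd.DataFrame) \
            and "exposure_days" in newdata:
        e = newdata["exposure_days"].to_numpy(float)
        if np.any(e <= 0):
            raise ValueError("exposure_days must be positive")
        return e / REFERENCE_EXPOSURE_DAYS
    return np.exp(_resolve_offset(newdata, offset, n))


def extrapolation_flags(fit_or_design, newdata) -> np.ndarray:
    """True where a covariate lies outside its training range."""
    design = getattr(fit_or_design, "design", fit_or_design)
    flags = np.zeros(len(newdata), bool)
    for fam, basis in design.bases.items():
        st = basis._state
        if "knots" not in st or basis.spec.kind == "cyclic_cubic":
            continue
        covs = FAMILY_COVS[fam]
        if not all(c in newdata for c in covs):
            continue
        x = newdata[list(covs)].to_numpy(float)
        z = (x - st["shift"]) / st["scale"]
        lo = st["knots"].min(axis=0)
        hi = st["knots"].max(axis=0)
        flags |= np.any((z < lo) | (z > hi), axis=1)
    return flags


def predict(
    fit: HGAMFit,
    newdata: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
    offset: np.ndarray | float | None = None,
    type: str = "response",
) -> np.ndarray:
    """Expected richness (or linear predictor) for new covariate rows.

    ``terms`` selects a subset of logical terms (the intercept is always
    included), enabling partial-effect predictions with all non-focal terms
    set to zero.
    """
    X = fit.design.model_matrix(newdata, terms=terms)
    eta = X @ fit.beta
    if type == "link":
        return eta + _resolve_offset(newdata, offset, len(newdata))
    return np.exp(eta) * _effort_factor(newdata, offset, len(newdata))


def simulate_posterior(
    fit: HGAMFit,
    newdata: pd.DataFrame,
    n_draws: int,
    rng: np.random.Generator | int | None = None,
    terms: tuple[str, ...] | None = None,
    offset: np.ndarray | float | None = None,
    type: str = "response",
) -> np.ndarray:
    """Draws from the Gaussian coefficient posterior pushed through the model.

    Returns an (n_draws, n_rows) array on the requested scale.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = len(fit.beta)
    V = fit.V
    w, Q = np.linalg.eigh(0.5 * (V + V.T))
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise np.linalg.LinAlgError("posterior covariance is not PSD")
    L = Q * np.sqrt(np.clip(w, 0.0, None))
    B = fit.beta[:, None] + L @ rng.standard_normal((p, n_draws))
    X = fit.design.model_matrix(newdata, terms=terms)
    eta = (X @ B).T
    if type == "link":
        return eta + _resolve_offset(newdata, offset, len(newdata))
    return np.exp(eta) * _effort_factor(newdata, offset, len(newdata))
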