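"""Penalized regression-spline bases for the guild richness models.

Two basis families are provided:

* **Cyclic cubic regression splines** for within-year seasonal terms.  The
  basis is parameterised by function values at ``k`` equally spaced knots on
  the periodic week axis; value, first- and second-derivative continuity at
  the year seam hold by construction, and the wiggliness penalty is the exact
  integrated squared second derivative of the interpolating periodic cubic.

* **Thin-plate regression splines** (low-rank eigen-approximation of the full
  thin-plate smoother) for climate effects (1-D) and the spatial surface
  (2-D isotropic on standardised coordinates).  The polynomial null space
  (constant, linear) carries no wiggliness penalty; after the sum-to-zero
  identifiability constraint the remaining null directions are collected into
  a separate shrinkage penalty so that the double-penalty approach can remove
  a whole term.

Every basis records the transforms needed to rebuild its design columns for
new data (knots, eigenvectors, standardisation, constraint matrix), so that
prediction reuses exactly the training-time construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "SmoothSpec",
    "PenalizedBasis",
    "build_cyclic_basis",
    "build_thinplate_basis",
    "apply_constraint",
]

#: dimension of the unpenalized polynomial null space of a thin-plate spline
#: with penalty order m=2, by covariate dimension.
TPS_NULL_DIM = {1: 2, 2: 3}


@dataclass(frozen=True)
class SmoothSpec:
    """Specification of one smooth term.

    Parameters
    ----------
    kind
        ``"cyclic_cubic"``, ``"thinplate_1d"`` or ``"thinplate_2d"``.
    covariates
        Names of the one or two covariates the smooth acts on.
    k
        Basis dimension before the identifiability constraint.
    period
        Period of the cyclic basis (weeks); required for ``cyclic_cubic``.
    max_knots
        Cap on the number of thin-plate knots (knots are placed at covariate
        quantiles when the data exceed the cap).
    """

    kind: str
    covariates: tuple[str, ...]
    k: int = 6
    period: float | None = None
    max_knots: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("cyclic_cubic", "thinplate_1d", "thinplate_2d"):
            raise ValueError(f"unknown smooth kind {self.kind!r}")
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")
        ncov = 2 if self.kind == "thinplate_2d" else 1
        if len(self.covariates) != ncov:
            raise ValueError(
                f"{self.kind} smooth needs {ncov} covariate(s), "
                f"got {self.covariates!r}"
            )
        if self.kind == "cyclic_cubic" and self.period is None:
            raise ValueError("cyclic smooth requires a period")


@dataclass
class PenalizedBasis:
    """A constructed smooth-term basis with its penalties.

    Attributes
    ----------
    spec : SmoothSpec
    X : ndarray
        Constrained design block at the training data, shape (n, p).
    S_wiggle : ndarray
        Symmetric PSD wiggliness penalty, (p, p).
    S_null : ndarray
        Symmetric PSD penalty spanning the wiggliness null space (zero matrix
        when the constrained wiggliness penalty is full rank).
    constraint_applied : bool
        Whether the sum-to-zero reparameterisation has been applied.
    """

    spec: SmoothSpec
    X: np.ndarray
    S_wiggle: np.ndarray
    S_null: np.ndarray
    constraint_applied: bool = True
    # prediction-time state
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    # -- evaluation ------------------------------------------------------

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Constrained design block at new covariate values.

        ``x`` has shape (n,) for 1-D smooths or (n, 2) for the spatial smooth.
        """
        raw = self._evaluate_raw(x)
        Q = self._state.get("Q")
        return raw @ Q if Q is not None else raw

    def _evaluate_raw(self, x: np.ndarray) -> np.ndarray:
        st = self._state
        if self.spec.kind == "cyclic_cubic":
            return _cyclic_design(
                np.asarray(x, float).ravel(), st["knots"], st["F"], st["period"]
            )
        X2 = np.atleast_2d(np.asarray(x, float))
        if X2.shape[0] == 1 and X2.size > X2.shape[1]:  # a flat 1-D vector
            X2 = X2.T
        if self.spec.kind == "thinplate_1d" and X2.shape[1] != 1:
            X2 = X2.reshape(-1, 1)
        Z = (X2 - st["shift"]) / st["scale"]
        d = Z.shape[1]
        E = _tps_eta(_cdist(Z, st["knots"]), d)
        T = _tps_polys(Z)
        return np.hstack([E @ st["UZ"], T])

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "spec": {
                "kind": self.spec.kind,
                "covariates": list(self.spec.covariates),
                "k": self.spec.k,
                "period": self.spec.period,
                "max_knots": self.spec.max_knots,
            },
            "S_wiggle": self.S_wiggle.tolist(),
            "S_null": self.S_null.tolist(),
            "constraint_applied": self.constraint_applied,
            "state": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self._state.items()
            },
        }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedBasis":
        spec = SmoothSpec(
            kind=d["spec"]["kind"],
            covariates=tuple(d["spec"]["covariates"]),
            k=d["spec"]["k"],
            period=d["spec"]["period"],
            max_knots=d["spec"]["max_knots"],
        )
        state = {
            k: (np.asarray(v, float) if isinstance(v, list) else v)
            for k, v in d["state"].items()
        }
        basis = cls(
            spec=spec,
            X=np.zeros((0, np.asarray(d["S_wiggle"]).shape[0])),
            S_wiggle=np.asarray(d["S_wiggle"], float),
            S_null=np.asarray(d["S_null"], float),
            constraint_applied=d["constraint_applied"],
        )
        basis._state = state
        return basis


# ---------------------------------------------------------------------------
# cyclic cubic regression spline
# ---------------------------------------------------------------------------


def _cyclic_matrices(knots: np.ndarray, period: float):
    """B and D matrices of the periodic natural cubic spline.

    With function values beta at the k knots, the second derivatives at the
    knots are m = B^{-1} D beta and the curvature penalty is
    int f''(x)^2 dx = beta' D' B^{-1} D beta.
    """
    k = len(knots)
    h = np.diff(np.append(knots, knots[0] + period))
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for i in range(k):
        hm = h[i - 1]  # interval ending at knot i (wraps)
        hp = h[i]
        B[i, i] = (hm + hp) / 3.0
        B[i, (i + 1) % k] += hp / 6.0
        B[i, (i - 1) % k] += hm / 6.0
        D[i, i] = -(1.0 / hm + 1.0 / hp)
        D[i, (i + 1) % k] += 1.0 / hp
        D[i, (i - 1) % k] += 1.0 / hm
    return B, D, h


def _cyclic_design(x, knots, F, period):
    """Design rows of the periodic interpolating cubic at points x."""
    k = len(knots)
    lo = knots[0]
    h_all = np.diff(np.append(knots, lo + period))
    xw = lo + np.mod(x - lo, period)
    j = np.clip(np.searchsorted(knots, xw, side="right") - 1, 0, k - 1)
    x0 = knots[j]
    h = h_all[j]
    jp = (j + 1) % k
    A = (x0 + h - xw) / h
    Bc = (xw - x0) / h
    Cc = (A**3 - A) * h * h / 6.0
    Dd = (Bc**3 - Bc) * h * h / 6.0
    n = len(xw)
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += A
    X[rows, jp] += Bc
    X += Cc[:, None] * F[j, :] + Dd[:, None] * F[jp, :]
    return X


def build_cyclic_basis(
    x: np.ndarray, spec: SmoothSpec, constrain: bool = True
) -> PenalizedBasis:
    """Cyclic cubic regression spline basis with curvature penalty.

    Knots are equally spaced over one period starting at the minimum of the
    nominal range (week 1), the last knot wrapping onto the first.  The
    coefficient vector holds the function values at the knots.
    """
    x = np.asarray(x, float).ravel()
    period = float(spec.period)
    lo = 1.0  # weeks indexed 1..period
    knots = lo + np.arange(spec.k) * period / spec.k
    if spec.k > len(np.unique(knots)):
        raise ValueError("k exceeds the number of distinct knots")
    B, D, _ = _cyclic_matrices(knots, period)
    F = np.linalg.solve(B, D)
    S = D.T @ F
    S = 0.5 * (S + S.T)
    X = _cyclic_design(x, knots, F, period)
    basis = PenalizedBasis(
        spec=spec,
        X=X,
        S_wiggle=S,
        S_null=np.zeros_like(S),
        constraint_applied=False,
    )
    basis._state = {"knots": knots, "F": F, "period": period}
    return apply_constraint(basis) if constrain else basis


# ---------------------------------------------------------------------------
# thin plate regression spline (order m = 2)
# ---------------------------------------------------------------------------


def _cdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    diff = A[:, None, :] - B[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _tps_eta(r: np.ndarray, d: int) -> np.ndarray:
    """Thin-plate radial kernel for penalty order 2 in d dimensions."""
    if d == 1:
        return r**3 / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r) / (8.0 * np.pi)
    return np.where(r > 0, out, 0.0)


def _tps_polys(Z: np.ndarray) -> np.ndarray:
    """Polynomial null-space columns: constant plus linear terms."""
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


def _select_knots(Z: np.ndarray, max_knots: int) -> np.ndarray:
    uniq = np.unique(Z, axis=0)
    if len(uniq) <= max_knots:
        return uniq
    if Z.shape[1] == 1:
        qs = np.linspace(0, 1, max_knots)
        kn = np.quantile(uniq.ravel(), qs)
        return np.unique(kn).reshape(-1, 1)
    # 2-D: deterministic thinning of the lexicographically sorted unique rows
    idx = np.linspace(0, len(uniq) - 1, max_knots).round().astype(int)
    return uniq[np.unique(idx)]


def build_thinplate_basis(
    x: np.ndarray, spec: SmoothSpec, constrain: bool = True
) -> PenalizedBasis:
    """Low-rank thin-plate regression spline basis.

    The full thin-plate smoother over the knot set is eigen-truncated to the
    ``k`` leading (largest absolute eigenvalue) directions; the polynomial
    null space is retained exactly.  Covariates are standardised to zero mean
    and unit standard deviation before radial distances are computed, making
    the 2-D spatial smooth isotropic on the standardised plane.
    """
    X2 = np.atleast_2d(np.asarray(x, float))
    if X2.shape[0] == 1 and X2.size > X2.shape[1]:
        X2 = X2.T
    if spec.kind == "thinplate_1d" and X2.shape[1] != 1:
        X2 = X2.reshape(-1, 1)
    d = X2.shape[1]
    M = TPS_NULL_DIM[d]
    shift = X2.mean(axis=0)
    scale = X2.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X2 - shift) / scale
    knots = _select_knots(Z, spec.max_knots)
    if len(knots) < spec.k:
        raise ValueError(
            f"need at least k={spec.k} distinct covariate points, "
            f"got {len(knots)}"
        )
    E = _tps_eta(_cdist(knots, knots), d)
    T = _tps_polys(knots)
    w, U = np.linalg.eigh(E)
    order = np.argsort(-np.abs(w))[: spec.k]
    Uk = U[:, order]
    Dk = w[order]
    # impose the thin-plate side condition T' delta = 0 inside the truncated
    # space: delta = Uk Zc z with (T' Uk) Zc = 0
    Zc = null_space(T.T @ Uk)
    if Zc.shape[1] != spec.k - M:
        raise ValueError("degenerate thin-plate construction: rank defect")
    UZ = Uk @ Zc
    S_w = Zc.T @ (Dk[:, None] * Zc)
    S_w = 0.5 * (S_w + S_w.T)
    S_w = _clip_psd(S_w)
    S = np.zeros((spec.k, spec.k))
    S[: spec.k - M, : spec.k - M] = S_w
    Xdes = np.hstack([_tps_eta(_cdist(Z, knots), d) @ UZ, _tps_polys(Z)])
    basis = PenalizedBasis(
        spec=spec,
        X=Xdes,
        S_wiggle=S,
        S_null=np.zeros_like(S),
        constraint_applied=False,
    )
    basis._state = {"knots": knots, "UZ": UZ, "shift": shift, "scale": scale}
    return apply_constraint(basis) if constrain else basis


def _clip_psd(S: np.ndarray) -> np.ndarray:
    """Project a nearly-PSD symmetric matrix onto the PSD cone."""
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


# ---------------------------------------------------------------------------
# identifiability constraint
# ---------------------------------------------------------------------------


def apply_constraint(basis: PenalizedBasis) -> PenalizedBasis:
    """Reparameterise so the design columns sum to zero over the data.

    The constraint matrix (an orthonormal basis of the null space of the
    column-sum functional) is stored so that prediction-time design rows are
    transformed identically.  After the constraint, directions of the
    wiggliness penalty's null space are collected into ``S_null`` so the
    double-penalty selection can shrink the whole term.
    """
    if basis.constraint_applied:
        return basis
    C = basis.X.sum(axis=0, keepdims=True)
    nrm = np.linalg.norm(C)
    if nrm < 1e-12:  # already centred; drop nothing
        Q = np.eye(basis.X.shape[1])
    else:
        Q = null_space(C)
    Xc = basis.X @ Q
    Sw = Q.T @ basis.S_wiggle @ Q
    Sw = _clip_psd(0.5 * (Sw + Sw.T))
    # null-space shrinkage penalty
    w, V = np.linalg.eigh(Sw)
    tol = max(w.max(), 1.0) * 1e-9
    nullvecs = V[:, w < tol]
    S_null = nullvecs @ nullvecs.T if nullvecs.shape[1] else np.zeros_like(Sw)
    out = PenalizedBasis(
        spec=basis.spec,
        X=Xc,
        S_wiggle=Sw,
        S_null=S_null,
        constraint_applied=True,
    )
    out._state = dict(basis._state)
    out._state["Q"] = Q
    return out


def build_smooth(x: np.ndarray, spec: SmoothSpec, constrain: bool = True) -> PenalizedBasis:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "cyclic_cubic":
        return build_cyclic_basis(x, spec, constrain=constrain)
    return build_thinplate_basis(x, spec, constrain=constrain)
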