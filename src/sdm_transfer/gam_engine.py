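"""Binomial GAMs with low-rank penalized spline smooths and shrinkage selection.

Each covariate enters as a one-dimensional smooth built from a small cubic
B-spline basis with a curvature (integrated squared second-derivative) penalty.
A separate "null-space" penalty spans the functions the curvature penalty
cannot touch (the linear trend), so that with two smoothing parameters per
term a whole smooth can be shrunk to zero — the double-penalty approach to
term selection.  Smoothing parameters are chosen by minimizing the UBRE score

    UBRE(lambda) = D(lambda)/n + 2 * edf(lambda)/n - 1

with the binomial scale fixed at one, via coordinate descent on a log-lambda
grid.  Fitting at fixed penalties is by penalized iteratively reweighted
least squares (PIRLS).

The identifiability constraint (each smooth sums to zero over the training
records) is absorbed by reparameterization, so the constrained design columns
sum to zero exactly and the penalties transform with the basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.special import expit

from .errors import BasisError, MissingCovariateError, SDMTransferError

__all__ = [
    "SmoothSpec",
    "BasisExpansion",
    "FittedGAM",
    "build_basis",
    "fit_pirls",
    "select_smoothing",
    "predict",
    "partial_effect",
    "PartialEffectCurve",
]

# Smoothing-parameter search grid: log10(lambda) from -4 (effectively
# unpenalized) to 8 (term fully suppressed), 25 knots.
LOG10_LAMBDA_GRID = np.linspace(-4.0, 8.0, 25)
EDF_SHRUNK_TOLERANCE = 0.05
PIRLS_MAX_ITER = 200
PIRLS_REL_TOL = 1e-8
_PROB_CLIP = 1e-10
_RIDGE = 1e-9  # tiny ridge on the penalized normal equations, numerical only

_SPLINE_DEGREE = 3


@dataclass(frozen=True)
class SmoothSpec:
    """Specification of one univariate smooth term.

    ``basis_dim`` is the number of B-spline basis functions before the
    sum-to-zero constraint; the constrained term has ``basis_dim - 1``
    coefficients, capping its effective degrees of freedom at
    ``basis_dim - 1`` (4 for the default ``basis_dim=5``).
    ``penalty_order`` is the derivative order penalized (2 = curvature).
    """

    covariate: str
    basis_dim: int = 5
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.basis_dim < 3:
            raise ValueError(f"basis_dim must be >= 3, got {self.basis_dim}")
        if self.penalty_order not in (1, 2):
            raise ValueError("penalty_order must be 1 or 2")


def _knot_vector(x: np.ndarray, k: int) -> np.ndarray:
    """Clamped cubic knot vector giving exactly k basis functions.

    Interior knots are placed at quantiles of the distinct training values so
    the basis adapts to skewed covariates.
    """
    lo, hi = float(x.min()), float(x.max())
    n_interior = k - _SPLINE_DEGREE - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
        # keep interior knots strictly inside and strictly increasing
        interior = np.clip(interior, lo + 1e-8 * (hi - lo), hi - 1e-8 * (hi - lo))
        interior = np.maximum.accumulate(interior)
    else:
        interior = np.array([])
    return np.concatenate(
        [np.full(_SPLINE_DEGREE + 1, lo), interior, np.full(_SPLINE_DEGREE + 1, hi)]
    )


def _design_matrix(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.clip(x, t[0], t[-1])
    return BSpline.design_matrix(x, t, _SPLINE_DEGREE).toarray()


def _derivative_row(t: np.ndarray, x0: float, k: int) -> np.ndarray:
    """First-derivative values of every basis function at x0."""
    out = np.empty(k)
    for i in range(k):
        c = np.zeros(k)
        c[i] = 1.0
        out[i] = BSpline(t, c, _SPLINE_DEGREE).derivative()(x0)
    return out


def _curvature_penalty(t: np.ndarray, k: int, order: int) -> np.ndarray:
    """S_ij = integral of B_i^(order) * B_j^(order) over the knot span.

    For cubic splines the order-2 derivative is piecewise linear, so 2-point
    Gauss-Legendre per knot interval is exact; order-1 integrands are quartic,
    handled exactly by 3-point Gauss.
    """
    npts = 3
    nodes, weights = np.polynomial.legendre.leggauss(npts)
    breaks = np.unique(t)
    S = np.zeros((k, k))
    dmat = np.empty((0, k))
    xs = []
    ws = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        xs.append(0.5 * (b - a) * nodes + 0.5 * (a + b))
        ws.append(0.5 * (b - a) * weights)
    xs = np.concatenate(xs)
    ws = np.concatenate(ws)
    dmat = np.empty((xs.size, k))
    for i in range(k):
        c = np.zeros(k)
        c[i] = 1.0
        dmat[:, i] = BSpline(t, c, _SPLINE_DEGREE).derivative(order)(xs)
    S = dmat.T @ (dmat * ws[:, None])
    return 0.5 * (S + S.T)


def _greville(t: np.ndarray, k: int) -> np.ndarray:
    d = _SPLINE_DEGREE
    return np.array([t[i + 1 : i + d + 1].mean() for i in range(k)])


@dataclass
class BasisExpansion:
    """One smooth term's constrained design block, penalties and evaluator.

    ``design_columns`` is the n x (basis_dim - 1) training block whose columns
    sum to zero; ``penalty`` (S) is the curvature penalty and ``null_penalty``
    (S0) spans its null space, both expressed in the constrained coordinates.
    The object carries everything needed to evaluate the same (centered) basis
    at new covariate values, with linear extension beyond the training range.
    """

    spec: SmoothSpec
    knots: np.ndarray
    constraint: np.ndarray  # basis_dim x (basis_dim - 1) map absorbing sum-to-zero
    design_columns: np.ndarray
    penalty: np.ndarray
    null_penalty: np.ndarray
    x_min: float
    x_max: float
    _boundary_rows: np.ndarray = field(repr=False, default=None)
    _boundary_derivs: np.ndarray = field(repr=False, default=None)

    @property
    def n_coef(self) -> int:
        return self.constraint.shape[1]

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Constrained basis rows at new values, with an extrapolation mask.

        Beyond the training range the smooth is extended linearly from its
        boundary value and slope (silent clamping would hide how far a
        transferred model leaves its source covariate space).
        """
        x = np.asarray(x, dtype=float)
        lo_mask = x < self.x_min
        hi_mask = x > self.x_max
        inside = ~(lo_mask | hi_mask)
        rows = np.zeros((x.size, self.n_coef))
        if inside.any():
            rows[inside] = _design_matrix(x[inside], self.knots) @ self.constraint
        for mask, b_idx, bound in ((lo_mask, 0, self.x_min), (hi_mask, 1, self.x_max)):
            if mask.any():
                rows[mask] = (
                    self._boundary_rows[b_idx]
                    + (x[mask, None] - bound) * self._boundary_derivs[b_idx]
                )
        return rows, lo_mask | hi_mask

    def to_dict(self) -> dict:
        return {
            "spec": {
                "covariate": self.spec.covariate,
                "basis_dim": self.spec.basis_dim,
                "penalty_order": self.spec.penalty_order,
            },
            "knots": self.knots.tolist(),
            "constraint": self.constraint.tolist(),
            "penalty": self.penalty.tolist(),
            "null_penalty": self.null_penalty.tolist(),
            "x_min": self.x_min,
            "x_max": self.x_max,
            "boundary_rows": self._boundary_rows.tolist(),
            "boundary_derivs": self._boundary_derivs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisExpansion":
        return cls(
            spec=SmoothSpec(**d["spec"]),
            knots=np.asarray(d["knots"]),
            constraint=np.asarray(d["constraint"]),
            design_columns=np.empty((0, 0)),
            penalty=np.asarray(d["penalty"]),
            null_penalty=np.asarray(d["null_penalty"]),
            x_min=d["x_min"],
            x_max=d["x_max"],
            _boundary_rows=np.asarray(d["boundary_rows"]),
            _boundary_derivs=np.asarray(d["boundary_derivs"]),
        )


def build_basis(spec: SmoothSpec, values: np.ndarray) -> BasisExpansion:
    """Build the constrained penalized B-spline basis for one covariate."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise BasisError("covariate values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise BasisError(f"non-finite values in covariate {spec.covariate!r}")
    k = spec.basis_dim
    if np.unique(x).size < k:
        raise BasisError(
            f"covariate {spec.covariate!r} has fewer than basis_dim={k} distinct values"
        )
    t = _knot_vector(x, k)
    B = _design_matrix(x, t)

    # Absorb the sum-to-zero constraint 1'B beta = 0: Q spans null(1'B).
    col_sums = B.sum(axis=0)[None, :]
    Q = null_space(col_sums)  # k x (k-1)
    Bc = B @ Q

    S_raw = _curvature_penalty(t, k, spec.penalty_order)
    # Null space of the curvature penalty: polynomials of degree < order,
    # represented exactly in B-spline coefficients (1 -> ones, x -> Greville).
    if spec.penalty_order == 2:
        N = np.column_stack([np.ones(k), _greville(t, k)])
    else:
        N = np.ones((k, 1))
    N, _ = np.linalg.qr(N)
    S0_raw = N @ N.T

    S = Q.T @ S_raw @ Q
    S0 = Q.T @ S0_raw @ Q
    S = 0.5 * (S + S.T)
    S0 = 0.5 * (S0 + S0.T)
    # Normalize so a single lambda grid is comparable across covariate scales.
    nS = np.linalg.norm(S)
    if nS > 0:
        S = S / nS
    nS0 = np.linalg.norm(S0)
    if nS0 > 0:
        S0 = S0 / nS0

    lo, hi = float(x.min()), float(x.max())
    boundary_rows = np.vstack(
        [_design_matrix(np.array([lo]), t) @ Q, _design_matrix(np.array([hi]), t) @ Q]
    )
    boundary_derivs = np.vstack(
        [_derivative_row(t, lo, k) @ Q, _derivative_row(t, hi, k) @ Q]
    )
    return BasisExpansion(
        spec=spec,
        knots=t,
        constraint=Q,
        design_columns=Bc,
        penalty=S,
        null_penalty=S0,
        x_min=lo,
        x_max=hi,
        _boundary_rows=boundary_rows,
        _boundary_derivs=boundary_derivs,
    )


# ---------------------------------------------------------------------------
# Model fitting (PIRLS at fixed smoothing parameters)
# ---------------------------------------------------------------------------


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _PROB_CLIP, 1 - _PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _null_deviance(y: np.ndarray) -> float:
    p = y.mean()
    if p <= 0 or p >= 1:
        return 0.0
    n = y.size
    return float(-2.0 * (n * p * np.log(p) + n * (1 - p) * np.log(1 - p)))


@dataclass
class FittedGAM:
    """A fitted binomial additive model.

    Holds the fitted coefficients, the per-term smoothing parameters
    ``(lambda, lambda0)`` (curvature and null-space shrinkage), the
    trace-based effective degrees of freedom per term, training deviances and
    the UBRE score, plus the Bayesian posterior covariance of the
    coefficients used for pointwise confidence bands.
    """

    terms: list[SmoothSpec]
    bases: list[BasisExpansion]
    coefficients: np.ndarray
    smoothing_params: list[tuple[float, float]]
    edf: dict[str, float]
    edf_total: float
    deviance: float
    null_deviance: float
    ubre: float
    n_train: int
    converged: bool
    cov_beta: np.ndarray
    term_slices: dict[str, slice]
    search_warning: bool = False

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def adjusted_r2(self) -> float:
        """Deviance-based analogue of an adjusted R^2.

        Penalizes the deviance explained by the effective model size:
        1 - (D / (n - edf)) / (D_null / (n - 1)).
        """
        n = self.n_train
        if self.null_deviance <= 0 or n - self.edf_total <= 0:
            return float("nan")
        return 1.0 - (self.deviance / (n - self.edf_total)) / (
            self.null_deviance / (n - 1)
        )

    @property
    def shrunk_terms(self) -> list[str]:
        """Covariates whose smooth was shrunk to (effectively) zero."""
        return [c for c, e in self.edf.items() if e < EDF_SHRUNK_TOLERANCE]

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bases": [b.to_dict() for b in self.bases],
            "coefficients": self.coefficients.tolist(),
            "smoothing_params": [list(sp) for sp in self.smoothing_params],
            "edf": self.edf,
            "edf_total": self.edf_total,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "ubre": self.ubre,
            "n_train": self.n_train,
            "converged": self.converged,
            "cov_beta": self.cov_beta.tolist(),
            "search_warning": self.search_warning,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGAM":
        bases = [BasisExpansion.from_dict(bd) for bd in d["bases"]]
        terms = [b.spec for b in bases]
        slices = {}
        pos = 1
        for b in bases:
            slices[b.spec.covariate] = slice(pos, pos + b.n_coef)
            pos += b.n_coef
        return cls(
            terms=terms,
            bases=bases,
            coefficients=np.asarray(d["coefficients"]),
            smoothing_params=[tuple(sp) for sp in d["smoothing_params"]],
            edf=dict(d["edf"]),
            edf_total=d["edf_total"],
            deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            ubre=d["ubre"],
            n_train=d["n_train"],
            converged=d["converged"],
            cov_beta=np.asarray(d["cov_beta"]),
            term_slices=slices,
            search_warning=d.get("search_warning", False),
        )

    @classmethod
    def from_json(cls, path) -> "FittedGAM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _assemble_design(
    records: pd.DataFrame, terms: list[SmoothSpec]
) -> tuple[np.ndarray, np.ndarray, list[BasisExpansion], dict[str, slice]]:
    if "response" not in records.columns:
        raise SDMTransferError("records must contain a 'response' column")
    y = records["response"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise SDMTransferError("response must be binary (0/1)")
    bases = []
    blocks = [np.ones((len(records), 1))]
    slices = {}
    pos = 1
    for spec in terms:
        if spec.covariate not in records.columns:
            raise MissingCovariateError(spec.covariate, "model fitting")
        b = build_basis(spec, records[spec.covariate].to_numpy(dtype=float))
        bases.append(b)
        blocks.append(b.design_columns)
        slices[spec.covariate] = slice(pos, pos + b.n_coef)
        pos += b.n_coef
    X = np.hstack(blocks)
    return X, y, bases, slices


def _embedded_penalties(
    bases: list[BasisExpansion], slices: dict[str, slice], p: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for b in bases:
        sl = slices[b.spec.covariate]
        S = np.zeros((p, p))
        S0 = np.zeros((p, p))
        S[sl, sl] = b.penalty
        S0[sl, sl] = b.null_penalty
        out.append((S, S0))
    return out


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool, np.ndarray, np.ndarray]:
    """Penalized IRLS for the binomial/logit model.

    Returns (beta, deviance, converged, XtWX, A_inv) where A = XtWX + P.
    Uses step-halving on the penalized deviance for stability.
    """
    n, p = X.shape
    ridge = _RIDGE * np.eye(p)
    if beta0 is None:
        mu = (y + 0.5) / 2.0
        eta = np.log(mu / (1 - mu))
        beta = np.zeros(p)
        beta[0] = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
        eta = X @ beta
        mu = expit(eta)
    else:
        beta = beta0.copy()
        eta = X @ beta
        mu = expit(eta)
    mu = np.clip(mu, _PROB_CLIP, 1 - _PROB_CLIP)
    pdev = _binomial_deviance(y, mu) + float(beta @ P @ beta)
    converged = False
    XtWX = None
    for _ in range(PIRLS_MAX_ITER):
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + P + ridge
        rhs = Xw.T @ z
        try:
            beta_new = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, rhs, rcond=None)[0]
        # step halving on the penalized deviance
        step = beta_new - beta
        frac = 1.0
        for _halving in range(30):
            cand = beta + frac * step
            eta_c = X @ cand
            mu_c = np.clip(expit(eta_c), _PROB_CLIP, 1 - _PROB_CLIP)
            pdev_c = _binomial_deviance(y, mu_c) + float(cand @ P @ cand)
            if np.isfinite(pdev_c) and pdev_c <= pdev + 1e-12:
                break
            frac *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        if abs(pdev - pdev_c) < PIRLS_REL_TOL * (abs(pdev_c) + 0.1):
            pdev = pdev_c
            converged = True
            break
        pdev = pdev_c
    # final weights/influence at the solution
    w = mu * (1 - mu)
    XtWX = X.T @ (X * w[:, None])
    A = XtWX + P + ridge
    A_inv = np.linalg.inv(A)
    dev = _binomial_deviance(y, mu)
    return beta, dev, converged, XtWX, A_inv


def _make_fit(
    X, y, bases, slices, lambdas, beta0=None
) -> FittedGAM:
    p = X.shape[1]
    pens = _embedded_penalties(bases, slices, p)
    P = np.zeros((p, p))
    for (lam, lam0), (S, S0) in zip(lambdas, pens):
        P += lam * S + lam0 * S0
    beta, dev, converged, XtWX, A_inv = _pirls(X, y, P, beta0)
    H = A_inv @ XtWX  # influence map on coefficients
    edf = {}
    for b in bases:
        sl = slices[b.spec.covariate]
        edf[b.spec.covariate] = float(np.trace(H[sl, sl]))
    edf_total = float(np.trace(H))
    n = y.size
    ubre = dev / n + 2.0 * edf_total / n - 1.0
    return FittedGAM(
        terms=[b.spec for b in bases],
        bases=bases,
        coefficients=beta,
        smoothing_params=[tuple(l) for l in lambdas],
        edf=edf,
        edf_total=edf_total,
        deviance=dev,
        null_deviance=_null_deviance(y),
        ubre=ubre,
        n_train=n,
        converged=converged,
        cov_beta=A_inv,
        term_slices=slices,
    )


def fit_pirls(
    records: pd.DataFrame,
    terms: list[SmoothSpec],
    smoothing_params: list[tuple[float, float]],
) -> FittedGAM:
    """Fit at fixed per-term (lambda, lambda0); see module docstring."""
    if len(smoothing_params) != len(terms):
        raise ValueError("need one (lambda, lambda0) pair per term")
    X, y, bases, slices = _assemble_design(records, terms)
    return _make_fit(X, y, bases, slices, smoothing_params)


def select_smoothing(
    records: pd.DataFrame,
    terms: list[SmoothSpec],
    *,
    grid: np.ndarray | None = None,
    max_sweeps: int = 3,
) -> FittedGAM:
    """Choose per-term (lambda, lambda0) minimizing UBRE by coordinate descent.

    Each of the 2 * n_terms log10-smoothing-parameters is swept over the grid
    in turn, warm-starting PIRLS from the incumbent fit; sweeps repeat until
    no parameter moves (at most ``max_sweeps``), followed by one local
    refinement pass at half the grid spacing.  If the best fit found did not
    converge, it is returned with ``search_warning=True`` rather than hidden.
    """
    if grid is None:
        grid = LOG10_LAMBDA_GRID
    X, y, bases, slices = _assemble_design(records, terms)
    nt = len(terms)
    logs = np.zeros(2 * nt)  # start all lambdas at 1
    best = _make_fit(X, y, bases, slices, _pairs(logs, nt))
    for _ in range(max_sweeps):
        moved = False
        for j in range(2 * nt):
            cur = logs[j]
            for g in grid:
                if g == cur:
                    continue
                trial = logs.copy()
                trial[j] = g
                fit = _make_fit(
                    X, y, bases, slices, _pairs(trial, nt), beta0=best.coefficients
                )
                if fit.ubre < best.ubre - 1e-12:
                    best = fit
                    logs = trial
                    moved = True
        if not moved:
            break
    # local refinement at half the grid step
    step = (grid[1] - grid[0]) / 2.0 if grid.size > 1 else 0.25
    for j in range(2 * nt):
        for g in (logs[j] - step, logs[j] + step):
            trial = logs.copy()
            trial[j] = g
            fit = _make_fit(
                X, y, bases, slices, _pairs(trial, nt), beta0=best.coefficients
            )
            if fit.ubre < best.ubre - 1e-12:
                best = fit
                logs = trial
    if not best.converged:
        best.search_warning = True
    return best


def _pairs(logs: np.ndarray, nt: int) -> list[tuple[float, float]]:
    lams = 10.0 ** logs
    return [(lams[2 * i], lams[2 * i + 1]) for i in range(nt)]


# ---------------------------------------------------------------------------
# Prediction and partial effects
# ---------------------------------------------------------------------------


def _model_rows(
    model: FittedGAM, records: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    n = len(records)
    p = model.coefficients.size
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    extrap = np.zeros(n, dtype=bool)
    for b in model.bases:
        cov = b.spec.covariate
        if cov not in records.columns:
            raise MissingCovariateError(cov, "prediction")
        rows, mask = b.evaluate(records[cov].to_numpy(dtype=float))
        X[:, model.term_slices[cov]] = rows
        extrap |= mask
    return X, extrap


def predict(
    model: FittedGAM, records: pd.DataFrame, *, return_extrapolation: bool = False
):
    """Predicted presence probabilities for new records.

    Covariate values outside a smooth's training range are handled by linear
    extension of that smooth beyond its boundary; with
    ``return_extrapolation=True`` the per-record extrapolation mask is
    returned alongside the probabilities so transfers can report how many
    predictions left the source covariate space.
    """
    X, extrap = _model_rows(model, records)
    probs = expit(X @ model.coefficients)
    if return_extrapolation:
        return probs, extrap
    return probs


@dataclass
class PartialEffectCurve:
    covariate: str
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    edf: float


def partial_effect(
    model: FittedGAM, covariate: str, grid: np.ndarray
) -> PartialEffectCurve:
    """Centered smooth of one covariate with a pointwise 95% Bayesian band."""
    if covariate not in model.term_slices:
        raise MissingCovariateError(covariate, "partial effect")
    b = next(bb for bb in model.bases if bb.spec.covariate == covariate)
    rows, _ = b.evaluate(np.asarray(grid, dtype=float))
    sl = model.term_slices[covariate]
    beta = model.coefficients[sl]
    est = rows @ beta
    V = model.cov_beta[sl, sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, V, rows), 0.0))
    return PartialEffectCurve(
        covariate=covariate,
        grid=np.asarray(grid, dtype=float),
        estimate=est,
        lower=est - 1.96 * se,
        upper=est + 1.96 * se,
        edf=model.edf[covariate],
    )
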