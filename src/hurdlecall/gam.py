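"""Penalized-spline additive submodels and the composite hurdle base-caller.

The per-flow parameters of the hurdle mixture are modeled additively:

    logit(pi)   = beta_0  + sum_j f_j(x_j)      (binomial submodel)
    log(lambda) = gamma_0 + sum_j g_j(y_j)      (zero-truncated weighted
                                                 Poisson submodel)

with each smooth f_j, g_j a centered cubic B-spline (10 basis functions,
knots at covariate quantiles, second-order difference penalty).  Both
submodels are fitted by penalized iteratively reweighted least squares
(IRLS) with step-halving, which makes the penalized deviance monotone
non-increasing across iterations.  The smoothing parameter is shared
across the smooths of a submodel and selected by approximate GCV on a
log-spaced grid.  The global dispersion parameter ``theta`` of the
weighted Poisson component is estimated by profile likelihood over a grid
with golden-section refinement.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) so they
compose with sklearn tooling.  :class:`HurdleBaseCaller` is the composite
model: it consumes a flow table, builds features, fits both submodels plus
``theta``, and predicts per-flow HPL probability vectors.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator

from . import flow_model
from .features import FeatureConfig, build_features

DEFAULT_PENALTY_GRID: tuple[float, ...] = (1e-4, 1e-2, 1.0, 1e2, 1e4)
DEFAULT_THETA_GRID: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
ETA_POISSON_BOUNDS = (-10.0, 5.0)
ETA_BINOMIAL_BOUND = 30.0
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------


class SmoothTerm:
    """A centered cubic B-spline basis for one covariate.

    Knots sit at quantiles of the distinct training values; the basis is
    column-centered (training means) for identifiability with a separate
    intercept, and extended linearly beyond the knot range.  A covariate
    with too few distinct values degrades to a centered linear term with
    zero penalty.
    """

    def __init__(self, name: str, n_basis: int = 10, degree: int = 3, penalty_order: int = 2):
        self.name = name
        self.n_basis = n_basis
        self.degree = degree
        self.penalty_order = penalty_order
        self.is_linear_ = False

    def fit(self, x: np.ndarray) -> "SmoothTerm":
        x = np.asarray(x, dtype=float)
        xu = np.unique(x)
        n_interior = self.n_basis - self.degree - 1
        if xu.size < max(self.degree + 2, n_interior + 2):
            if xu.size < 2:
                warnings.warn(
                    f"covariate {self.name!r} is constant; degraded to a "
                    "(vanishing) linear term with zero penalty"
                )
            else:
                warnings.warn(
                    f"covariate {self.name!r} has {xu.size} distinct values; "
                    "degraded to a linear term with zero penalty"
                )
            self.is_linear_ = True
            self.center_ = float(x.mean())
            self.n_cols_ = 1
            return self
        lo, hi = float(xu[0]), float(xu[-1])
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.unique(np.quantile(xu, qs))
        interior = interior[(interior > lo) & (interior < hi)]
        t = np.r_[[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        k = len(t) - self.degree - 1
        self.knots_ = t
        self.lo_, self.hi_ = lo, hi
        self.n_cols_ = k
        self._spl = BSpline(t, np.eye(k), self.degree)
        self._dspl = self._spl.derivative()
        self.centers_ = self._raw(x).mean(axis=0)
        return self

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo_, self.hi_)
        B = self._spl(xc)
        below = x < self.lo_
        above = x > self.hi_
        if below.any():
            B[below] += np.outer(x[below] - self.lo_, self._dspl(self.lo_))
        if above.any():
            B[above] += np.outer(x[above] - self.hi_, self._dspl(self.hi_))
        return B

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.is_linear_:
            return (x - self.center_)[:, None]
        return self._raw(x) - self.centers_

    def penalty(self) -> np.ndarray:
        """Difference penalty of the configured order, divided by Greville
        abscissa spacings so its null space is exactly {1, x} (order 2):
        at infinite smoothing the smooth collapses to a straight line in
        the covariate even with non-uniform knots."""
        if self.is_linear_:
            return np.zeros((1, 1))
        k = self.degree
        t = self.knots_
        xi = np.array([t[i + 1 : i + 1 + k].mean() for i in range(self.n_cols_)])
        D = np.eye(self.n_cols_)
        a = xi
        for _ in range(self.penalty_order):
            D = (D[1:] - D[:-1]) / (a[1:] - a[:-1])[:, None]
            a = 0.5 * (a[1:] + a[:-1])
        return D.T @ D

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "n_basis": self.n_basis,
            "degree": self.degree,
            "penalty_order": self.penalty_order,
            "is_linear": self.is_linear_,
        }
        if self.is_linear_:
            d["center"] = self.center_
        else:
            d["knots"] = self.knots_.tolist()
            d["centers"] = self.centers_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothTerm":
        term = cls(d["name"], d["n_basis"], d["degree"], d["penalty_order"])
        term.is_linear_ = bool(d["is_linear"])
        if term.is_linear_:
            term.center_ = float(d["center"])
            term.n_cols_ = 1
        else:
            t = np.asarray(d["knots"], dtype=float)
            term.knots_ = t
            term.lo_, term.hi_ = float(t[0]), float(t[-1])
            term.n_cols_ = len(t) - term.degree - 1
            term._spl = BSpline(t, np.eye(term.n_cols_), term.degree)
            term._dspl = term._spl.derivative()
            term.centers_ = np.asarray(d["centers"], dtype=float)
        return term


def spline_basis(x: np.ndarray, term: SmoothTerm) -> tuple[np.ndarray, np.ndarray]:
    """Fit ``term`` on ``x`` and return (centered basis matrix, penalty)."""
    term.fit(np.asarray(x, dtype=float))
    return term.transform(np.asarray(x, dtype=float)), term.penalty()


# ---------------------------------------------------------------------------
# Penalized IRLS additive models
# ---------------------------------------------------------------------------


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


class _AdditiveGAM(BaseEstimator):
    """Shared penalized-IRLS machinery for both submodels."""

    def __init__(
        self,
        n_basis: int = 10,
        degree: int = 3,
        penalty_order: int = 2,
        penalty: float | None = None,
        penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
        max_iter: int = 100,
        tol: float = 1e-6,
        ridge: float = 1e-10,
    ):
        self.n_basis = n_basis
        self.degree = degree
        self.penalty_order = penalty_order
        self.penalty = penalty
        self.penalty_grid = penalty_grid
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    # subclass contract -----------------------------------------------------
    def _loglik(self, eta: np.ndarray, y: np.ndarray) -> float:
        raise NotImplementedError

    def _score_weight(self, eta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-observation score d(ll)/d(eta) and curvature weight -d2(ll)/d(eta)2."""
        raise NotImplementedError

    def _clip_eta(self, eta: np.ndarray) -> np.ndarray:
        return eta

    def _init_intercept(self, y: np.ndarray) -> float:
        raise NotImplementedError

    # design ---------------------------------------------------------------
    def _build_design(self, X) -> None:
        M = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        else:
            names = [f"x{j}" for j in range(M.shape[1])]
        self.term_names_ = names
        self.terms_ = []
        blocks = []
        for j, name in enumerate(names):
            term = SmoothTerm(name, self.n_basis, self.degree, self.penalty_order)
            term.fit(M[:, j])
            self.terms_.append(term)
            blocks.append(term.penalty())
        p = 1 + sum(t.n_cols_ for t in self.terms_)
        S = np.zeros((p, p))
        ofs = 1
        for t, b in zip(self.terms_, blocks):
            S[ofs : ofs + t.n_cols_, ofs : ofs + t.n_cols_] = b
            ofs += t.n_cols_
        self._S = S

    def _design_matrix(self, X) -> np.ndarray:
        M = _as_matrix(X)
        if M.shape[1] != len(self.terms_):
            raise ValueError(
                f"expected {len(self.terms_)} covariate columns, got {M.shape[1]}"
            )
        cols = [np.ones((M.shape[0], 1))]
        for j, term in enumerate(self.terms_):
            cols.append(term.transform(M[:, j]))
        return np.hstack(cols)

    # solver ---------------------------------------------------------------
    def _penalized_loglik(self, M, y, coef, P) -> float:
        eta = self._clip_eta(M @ coef)
        return self._loglik(eta, y) - 0.5 * float(coef @ P @ coef)

    def _solve(self, A: np.ndarray, b: np.ndarray) -> np.ndarray:
        try:
            return cho_solve(cho_factor(A), b)
        except LinAlgError:
            return np.linalg.lstsq(A, b, rcond=None)[0]

    def _irls(self, M, y, lam_pen, coef0=None):
        if coef0 is None and getattr(self, "_warm", None) is not None:
            if len(self._warm) == M.shape[1]:
                coef0 = np.asarray(self._warm, dtype=float)
        n, p = M.shape
        P = lam_pen * self._S + self.ridge * np.eye(p)
        if coef0 is None:
            coef = np.zeros(p)
            coef[0] = self._init_intercept(y)
        else:
            coef = coef0.copy()
        pl = self._penalized_loglik(M, y, coef, P)
        path = [-2.0 * pl]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = self._clip_eta(M @ coef)
            g, w = self._score_weight(eta, y)
            w = np.clip(w, 1e-10, 1e10)
            z = eta + g / w
            A = M.T @ (w[:, None] * M) + P
            b = M.T @ (w * z)
            new = self._solve(A, b)
            pl_new = self._penalized_loglik(M, y, new, P)
            # step-halving keeps the penalized deviance non-increasing
            halvings = 0
            while (not np.isfinite(pl_new) or pl_new < pl) and halvings < 30:
                new = 0.5 * (new + coef)
                pl_new = self._penalized_loglik(M, y, new, P)
                halvings += 1
            if not np.isfinite(pl_new) or pl_new < pl:
                break
            rel = abs(pl_new - pl) / (abs(pl_new) + 0.1)
            coef, pl = new, pl_new
            path.append(-2.0 * pl)
            if rel < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"{type(self).__name__}: IRLS did not converge in {it} iterations"
            )
        if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 1e4:
            # quasi-separation: ridge fallback
            warnings.warn(
                f"{type(self).__name__}: unstable coefficients (separation?); "
                "refitting with an extra ridge of 1e-6"
            )
            P2 = P + 1e-6 * np.eye(p)
            coef = np.zeros(p)
            coef[0] = self._init_intercept(y)
            pl = self._penalized_loglik(M, y, coef, P2)
            path = [-2.0 * pl]
            for it in range(1, self.max_iter + 1):
                eta = self._clip_eta(M @ coef)
                g, w = self._score_weight(eta, y)
                w = np.clip(w, 1e-10, 1e10)
                new = self._solve(M.T @ (w[:, None] * M) + P2, M.T @ (w * (eta + g / w)))
                pl_new = self._penalized_loglik(M, y, new, P2)
                halvings = 0
                while (not np.isfinite(pl_new) or pl_new < pl) and halvings < 30:
                    new = 0.5 * (new + coef)
                    pl_new = self._penalized_loglik(M, y, new, P2)
                    halvings += 1
                if not np.isfinite(pl_new) or pl_new < pl:
                    break
                rel = abs(pl_new - pl) / (abs(pl_new) + 0.1)
                coef, pl = new, pl_new
                path.append(-2.0 * pl)
                if rel < self.tol:
                    converged = True
                    break
        return coef, pl, path, converged, it

    def _edf_and_deviance(self, M, y, coef, lam_pen) -> tuple[float, float]:
        eta = self._clip_eta(M @ coef)
        _, w = self._score_weight(eta, y)
        w = np.clip(w, 1e-10, 1e10)
        p = M.shape[1]
        XtWX = M.T @ (w[:, None] * M)
        A = XtWX + lam_pen * self._S + self.ridge * np.eye(p)
        try:
            edf = float(np.trace(cho_solve(cho_factor(A), XtWX)))
        except LinAlgError:
            edf = float(np.trace(np.linalg.lstsq(A, XtWX, rcond=None)[0]))
        dev = -2.0 * self._loglik(eta, y)
        return edf, dev

    # public API ------------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self._build_design(X)
        M = self._design_matrix(X)
        n = M.shape[0]
        if self.penalty is not None:
            grid = [float(self.penalty)]
        else:
            grid = [float(v) for v in self.penalty_grid]
        best = None
        coef_ws = None
        gcv_path = []
        for lam_pen in grid:
            coef, pl, path, conv, iters = self._irls(M, y, lam_pen, coef0=coef_ws)
            coef_ws = coef
            edf, dev = self._edf_and_deviance(M, y, coef, lam_pen)
            gcv = n * dev / max(n - edf, 1.0) ** 2
            gcv_path.append((lam_pen, gcv, edf))
            if best is None or gcv < best[0]:
                best = (gcv, lam_pen, coef, pl, path, conv, iters, edf)
        _, lam_pen, coef, pl, path, conv, iters, edf = best
        self.penalty_ = lam_pen
        self.gcv_path_ = gcv_path
        self.coef_ = coef
        self.intercept_ = float(coef[0])
        self.penalized_loglik_ = float(pl)
        self.deviance_path_ = np.asarray(path)
        self.converged_ = bool(conv)
        self.n_iter_ = int(iters)
        self.edf_ = float(edf)
        eta = self._clip_eta(M @ coef)
        self.loglik_ = float(self._loglik(eta, y))
        return self

    def predict_linear(self, X) -> np.ndarray:
        return self._clip_eta(self._design_matrix(X) @ self.coef_)

    # serialization ---------------------------------------------------------
    def _state_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "terms": [t.to_dict() for t in self.terms_],
            "term_names": self.term_names_,
            "coef": self.coef_.tolist(),
            "penalty_": self.penalty_,
            "penalized_loglik": self.penalized_loglik_,
            "loglik": self.loglik_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "edf": self.edf_,
        }

    def _load_state(self, d: dict) -> None:
        params = dict(d["params"])
        for key in ("penalty_grid",):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        self.set_params(**params)
        self.terms_ = [SmoothTerm.from_dict(t) for t in d["terms"]]
        self.term_names_ = list(d["term_names"])
        p = 1 + sum(t.n_cols_ for t in self.terms_)
        S = np.zeros((p, p))
        ofs = 1
        for t in self.terms_:
            S[ofs : ofs + t.n_cols_, ofs : ofs + t.n_cols_] = t.penalty()
            ofs += t.n_cols_
        self._S = S
        self.coef_ = np.asarray(d["coef"], dtype=float)
        self.intercept_ = float(self.coef_[0])
        self.penalty_ = d["penalty_"]
        self.penalized_loglik_ = d["penalized_loglik"]
        self.loglik_ = d["loglik"]
        self.converged_ = d["converged"]
        self.n_iter_ = d["n_iter"]
        self.edf_ = d["edf"]


class LogisticGAM(_AdditiveGAM):
    """Penalized logistic additive model for the hurdle probability pi."""

    link = "logit"

    def _loglik(self, eta, y):
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def _score_weight(self, eta, y):
        mu = 1.0 / (1.0 + np.exp(-eta))
        return y - mu, mu * (1.0 - mu)

    def _clip_eta(self, eta):
        return np.clip(eta, -ETA_BINOMIAL_BOUND, ETA_BINOMIAL_BOUND)

    def _init_intercept(self, y):
        m = min(max(float(np.mean(y)), 1e-6), 1.0 - 1e-6)
        return float(np.log(m / (1.0 - m)))

    def predict_proba_positive(self, X) -> np.ndarray:
        """P(positive flow) per row."""
        return 1.0 / (1.0 + np.exp(-self.predict_linear(X)))


class TruncatedWeightedPoissonGAM(_AdditiveGAM):
    """Penalized additive model for log(lambda) under the ZTWP likelihood.

    ``theta`` is held fixed during a fit (profile estimation loops over
    it).  The score and curvature in eta = log(lambda) are obtained by
    central numerical differences of the exact ZTWP log-density.
    """

    link = "log"
    _fd_step = 1e-4

    def __init__(
        self,
        theta: float = 0.0,
        n_basis: int = 10,
        degree: int = 3,
        penalty_order: int = 2,
        penalty: float | None = None,
        penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
        max_iter: int = 100,
        tol: float = 1e-6,
        ridge: float = 1e-10,
    ):
        super().__init__(n_basis, degree, penalty_order, penalty, penalty_grid, max_iter, tol, ridge)
        self.theta = theta

    def _clip_eta(self, eta):
        return np.clip(eta, *ETA_POISSON_BOUNDS)

    def _loglik(self, eta, y):
        return float(np.sum(flow_model.zt_log_pmf(y, np.exp(eta), self.theta)))

    def _score_weight(self, eta, y):
        h = self._fd_step
        lp = flow_model.zt_log_pmf(y, np.exp(eta + h), self.theta)
        l0 = flow_model.zt_log_pmf(y, np.exp(eta), self.theta)
        lm = flow_model.zt_log_pmf(y, np.exp(eta - h), self.theta)
        score = (lp - lm) / (2.0 * h)
        curv = (lp - 2.0 * l0 + lm) / h**2
        return score, -curv

    def _init_intercept(self, y):
        return float(np.log(max(float(np.mean(y)), 1e-3)))

    def fit(self, X, y):
        y = np.asarray(y)
        if np.any(y < 1):
            raise ValueError("zero-truncated submodel requires all counts >= 1")
        super().fit(X, y)
        eta = self.predict_linear(X)
        self.eta_clip_active_ = bool(
            np.any(eta <= ETA_POISSON_BOUNDS[0] + 1e-9)
            or np.any(eta >= ETA_POISSON_BOUNDS[1] - 1e-9)
        )
        if self.eta_clip_active_:
            warnings.warn(
                "log(lambda) hit its clipping bounds at the optimum; rates at "
                "the boundary are saturated"
            )
        return self

    def predict_rate(self, X) -> np.ndarray:
        """lambda per row."""
        return np.exp(self.predict_linear(X))


def fit_binomial_gam(X, z, **kwargs) -> LogisticGAM:
    """Fit the logistic submodel for P(HPL > 0); requires both classes."""
    z = np.asarray(z).astype(float)
    if z.min() == z.max():
        raise ValueError(
            "binomial hurdle component needs both zero and positive flows"
        )
    return LogisticGAM(**kwargs).fit(X, z)


def ztwp_loglik(counts, lam, theta: float) -> float:
    """Sum of log f_ZTWP(count_i; lam_i, theta) over flows."""
    counts = np.asarray(counts)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), counts.shape)
    return float(np.sum(flow_model.zt_log_pmf(counts, lam, theta)))


def fit_ztwp_gam(X, counts, theta: float, **kwargs) -> TruncatedWeightedPoissonGAM:
    """Fit the zero-truncated weighted Poisson submodel at fixed theta."""
    return TruncatedWeightedPoissonGAM(theta=theta, **kwargs).fit(X, counts)


# ---------------------------------------------------------------------------
# Profile estimation of theta
# ---------------------------------------------------------------------------


def estimate_theta(
    X,
    counts,
    penalty: float | None = None,
    grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    refine_tol: float = 1e-3,
    **kwargs,
) -> tuple[float, pd.DataFrame, TruncatedWeightedPoissonGAM]:
    """Profile-likelihood estimate of the dispersion parameter theta.

    Refits the ZTWP submodel for each theta on the grid (warm-started),
    records the penalized log-likelihood, and refines the grid argmax by
    golden-section search between its neighbors (tolerance ``refine_tol``
    in log theta).  Returns ``(theta_hat, profile table, fitted model at
    theta_hat)``.
    """
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("theta grid must be non-empty")
    counts = np.asarray(counts)
    fits: dict[float, TruncatedWeightedPoissonGAM] = {}
    rows = []
    coef_ws = None

    def fit_at(theta: float) -> TruncatedWeightedPoissonGAM:
        nonlocal coef_ws
        model = TruncatedWeightedPoissonGAM(theta=theta, penalty=penalty, **kwargs)
        if coef_ws is not None:
            model._warm = coef_ws
        model.fit(X, counts)
        coef_ws = model.coef_
        fits[theta] = model
        return model

    for theta in grid:
        m = fit_at(theta)
        rows.append({"theta": theta, "penalized_loglik": m.penalized_loglik_})
    profile = pd.DataFrame(rows)
    pls = profile["penalized_loglik"].to_numpy()
    if pls.max() - pls.min() < 1e-6:
        warnings.warn("theta profile is flat; returning the smallest grid value")
        theta_hat = grid[0]
        return theta_hat, profile, fits[theta_hat]
    if len(grid) == 1:
        return grid[0], profile, fits[grid[0]]
    i = int(np.argmax(pls))
    if i == 0:
        return grid[0], profile, fits[grid[0]]
    lo = grid[i - 1]
    if i + 1 < len(grid):
        hi = grid[i + 1]
    else:
        # profile still rising at the top of the grid: expand the bracket
        # geometrically until the likelihood turns over
        hi = grid[i]
        best = pls[i]
        for _ in range(8):
            cand = hi * 2.0
            pl_cand = fit_at(cand).penalized_loglik_
            if pl_cand < best:
                hi = cand
                break
            lo, hi, best = hi, cand, pl_cand
        else:
            warnings.warn("theta profile still rising after bracket expansion")
    if lo <= 0:
        # bracket touches the theta=0 boundary; search on [grid[i]/4, hi] in log
        lo = max(grid[i] / 4.0, 1e-4)
    a, b = np.log(lo), np.log(hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = fit_at(float(np.exp(c))).penalized_loglik_
    fd = fit_at(float(np.exp(d))).penalized_loglik_
    while b - a > refine_tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fit_at(float(np.exp(c))).penalized_loglik_
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fit_at(float(np.exp(d))).penalized_loglik_
    fit_at(float(np.exp(0.5 * (a + b))))
    theta_hat = max(fits, key=lambda t: fits[t].penalized_loglik_)
    return theta_hat, profile, fits[theta_hat]


# ---------------------------------------------------------------------------
# Composite hurdle base-caller
# ---------------------------------------------------------------------------


class HurdleBaseCaller(BaseEstimator):
    """Hurdle Poisson base-calling model over a flow table.

    ``fit`` consumes a flow table (``read_id``, ``flow_index``,
    ``flowgram``, ``raw_intensity`` and, for training, ``ref_hpl``),
    builds the configured features, fits the logistic submodel on the
    zero/positive indicator, the zero-truncated weighted Poisson submodel
    on the positive counts, and estimates the global dispersion ``theta``
    by profile likelihood.  ``predict_proba`` returns the per-flow
    probability vector over HPL 0..n_max; ``predict`` calls the argmax
    HPL (ties toward the smaller length).

    Parameters
    ----------
    feature_config : FeatureConfig, optional
        Predictor sets and signal options; defaults to the package
        defaults.
    n_basis : int
        B-spline basis dimension per smooth.
    penalty_grid : tuple of float
        GCV grid for the shared smoothing parameter of each submodel.
    theta_grid : tuple of float
        Profile grid for the dispersion parameter.
    n_max : int, optional
        HPL range of reported probability vectors; defaults to
        ``max(training ref HPL) + 3`` with a floor of 12.
    min_positive : int
        Minimal number of positive training flows required.
    """

    def __init__(
        self,
        feature_config: FeatureConfig | None = None,
        n_basis: int = 10,
        penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
        theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID,
        n_max: int | None = None,
        min_positive: int = 50,
        max_iter: int = 100,
        tol: float = 1e-6,
    ):
        self.feature_config = feature_config
        self.n_basis = n_basis
        self.penalty_grid = penalty_grid
        self.theta_grid = theta_grid
        self.n_max = n_max
        self.min_positive = min_positive
        self.max_iter = max_iter
        self.tol = tol

    def _config(self) -> FeatureConfig:
        return self.feature_config or FeatureConfig()

    def fit(self, flows: pd.DataFrame, y=None) -> "HurdleBaseCaller":
        config = self._config()
        if y is None:
            if "ref_hpl" not in flows.columns:
                raise ValueError(
                    "training requires reference HPLs: pass y or a 'ref_hpl' column"
                )
            y = flows["ref_hpl"]
        y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)) or np.any(y < 0):
            raise ValueError("reference HPLs must be finite and >= 0 for every training flow")
        y = y.astype(int)
        feats = build_features(flows, config)
        z = (y > 0).astype(float)
        if z.min() == z.max():
            raise ValueError(
                "binomial hurdle component needs both zero and positive flows "
                "in the training data"
            )
        pos = y > 0
        if int(pos.sum()) < self.min_positive:
            raise ValueError(
                f"need at least {self.min_positive} positive flows to fit the "
                f"count submodel, got {int(pos.sum())}"
            )
        common = dict(n_basis=self.n_basis, max_iter=self.max_iter, tol=self.tol)
        self.binomial_ = LogisticGAM(penalty_grid=self.penalty_grid, **common).fit(
            feats[list(config.binomial_terms)], z
        )
        Xp = feats.loc[pos, list(config.poisson_terms)]
        counts = y[pos]
        # one alternation: pick the smoothing penalty at a mid-grid theta,
        # profile theta at that penalty, then reselect the penalty at theta_hat
        theta0 = sorted(self.theta_grid)[len(self.theta_grid) // 2]
        pre = TruncatedWeightedPoissonGAM(
            theta=theta0, penalty_grid=self.penalty_grid, **common
        ).fit(Xp, counts)
        self.theta_, self.theta_profile_, _ = estimate_theta(
            Xp, counts, penalty=pre.penalty_, grid=self.theta_grid, **common
        )
        self.poisson_ = TruncatedWeightedPoissonGAM(
            theta=self.theta_, penalty_grid=self.penalty_grid, **common
        )
        self.poisson_._warm = pre.coef_
        self.poisson_.fit(Xp, counts)
        self.n_max_ = self.n_max if self.n_max is not None else max(int(y.max()) + 3, 12)
        self.feature_config_ = config
        self.feature_ranges_ = {
            c: (float(feats[c].min()), float(feats[c].max()))
            for c in set(config.binomial_terms) | set(config.poisson_terms)
        }
        self.training_summary_ = {
            "n_flows": int(len(y)),
            "n_reads": int(flows["read_id"].nunique()),
            "n_positive": int(pos.sum()),
            "max_ref_hpl": int(y.max()),
        }
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "binomial_"):
            raise ValueError("model is not fitted")

    def _features(self, flows: pd.DataFrame, feature_config=None) -> pd.DataFrame:
        self._check_fitted()
        if feature_config is not None and feature_config != self.feature_config_:
            raise ValueError(
                "feature configuration differs from the one used in training; "
                "refit or pass the training configuration"
            )
        return build_features(flows, self.feature_config_)

    def predict_proba(self, flows: pd.DataFrame, feature_config=None) -> np.ndarray:
        """Per-flow probability matrix over HPL 0..n_max (rows renormalized)."""
        feats = self._features(flows, feature_config)
        config = self.feature_config_
        pi = self.binomial_.predict_proba_positive(feats[list(config.binomial_terms)])
        lam = self.poisson_.predict_rate(feats[list(config.poisson_terms)])
        probs = flow_model.hurdle_pmf_matrix(pi, lam, self.theta_, self.n_max_)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, flows: pd.DataFrame) -> np.ndarray:
        """Called HPL per flow: argmax probability, ties toward smaller HPL."""
        return np.argmax(self.predict_proba(flows), axis=1)

    def extrapolation_flags(self, flows: pd.DataFrame) -> np.ndarray:
        """True for flows whose covariates fall beyond 3x the training span."""
        feats = self._features(flows)
        flagged = np.zeros(len(feats), dtype=bool)
        for c, (lo, hi) in self.feature_ranges_.items():
            span = max(hi - lo, 1e-12)
            x = feats[c].to_numpy(dtype=float)
            flagged |= (x < lo - 3.0 * span) | (x > hi + 3.0 * span)
        return flagged

    # serialization ---------------------------------------------------------
    def to_json(self) -> str:
        self._check_fitted()
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": {
                "n_basis": self.n_basis,
                "penalty_grid": list(self.penalty_grid),
                "theta_grid": list(self.theta_grid),
                "n_max": self.n_max,
                "min_positive": self.min_positive,
                "max_iter": self.max_iter,
                "tol": self.tol,
            },
            "feature_config": self.feature_config_.to_dict(),
            "binomial": self.binomial_._state_dict(),
            "poisson": self.poisson_._state_dict(),
            "theta": self.theta_,
            "n_max_": self.n_max_,
            "feature_ranges": {k: list(v) for k, v in self.feature_ranges_.items()},
            "training_summary": self.training_summary_,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "HurdleBaseCaller":
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('format_version')!r}"
            )
        params = dict(doc["params"])
        params["penalty_grid"] = tuple(params["penalty_grid"])
        params["theta_grid"] = tuple(params["theta_grid"])
        model = cls(feature_config=FeatureConfig.from_dict(doc["feature_config"]), **params)
        model.feature_config_ = model.feature_config
        model.binomial_ = LogisticGAM()
        model.binomial_._load_state(doc["binomial"])
        model.poisson_ = TruncatedWeightedPoissonGAM()
        model.poisson_._load_state(doc["poisson"])
        model.theta_ = float(doc["theta"])
        model.n_max_ = int(doc["n_max_"])
        model.feature_ranges_ = {k: tuple(v) for k, v in doc["feature_ranges"].items()}
        model.training_summary_ = doc["training_summary"]
        return model


def fit_hurdle_model(
    flows: pd.DataFrame,
    feature_config: FeatureConfig | None = None,
    **kwargs,
) -> HurdleBaseCaller:
    """Fit the full hurdle base-calling model on a training flow table."""
    return HurdleBaseCaller(feature_config=feature_config, **kwargs).fit(flows)
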