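"""Age-conditional percentile curves for a bounded biomarker, three ways.

Three estimators produce the percentile curves used for aging-type rating and
reference-curve construction:

``LMSCentileModel``
    An LMS-type location-scale-shape model: the response is logit-transformed
    (plus a fixed positive shift so the working variable is strictly positive)
    and modelled with the Box-Cox Cole-Green distribution whose three parameter
    curves lambda(age), mu(age), sigma(age) are penalized B-spline smooths,
    fitted by penalized maximum likelihood with coordinate-wise backfitting.
    Being fully distributional, it also yields individual centiles F(y | age).

``LinearQuantileRegressor``
    Per-quantile straight lines minimizing the pinball (check) loss, solved
    exactly as a linear program.

``SplineQuantileRegressor``
    Per-quantile cubic B-spline curves minimizing pinball loss plus an L1
    penalty on second divided differences of the coefficients (null space =
    straight lines), again one exact linear program per quantile.  No
    extrapolation beyond the training age range.

Predicted quantile curves are monotone-rearranged across the quantile levels
at every age so they never cross, and clipped to [0, 1] for bounded responses.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog, minimize
from scipy.special import expit, logit, ndtr, ndtri
from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_TAUS",
    "pinball_loss",
    "LinearQuantileRegressor",
    "SplineQuantileRegressor",
    "LMSCentileModel",
    "fit_lqr",
    "fit_nqr",
    "fit_lms",
    "predict_quantiles",
    "individual_centile",
    "ConvergenceError",
    "UnsupportedOperationError",
]

#: the five percentile levels spaced roughly 1 Gaussian SD apart
DEFAULT_TAUS = (0.03, 0.15, 0.50, 0.85, 0.97)


class ConvergenceError(RuntimeError):
    """Penalized-likelihood backfitting failed to converge; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace or [])


class UnsupportedOperationError(TypeError):
    """Operation not defined for this model class."""


def pinball_loss(y, q, tau: float) -> float:
    """Mean check loss: mean of (tau - 1{y < q}) * (y - q); >= 0, 0 iff y == q."""
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if y.shape != q.shape:
        raise ValueError("y and q must have equal length")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (0, 1)")
    r = y - q
    return float(np.mean(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def _validate_taus(taus) -> np.ndarray:
    t = np.asarray(taus, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("taus must be a non-empty 1-d sequence")
    if np.any((t <= 0) | (t >= 1)) or np.any(np.diff(t) <= 0):
        raise ValueError("taus must be strictly increasing within (0, 1)")
    return t


# ---------------------------------------------------------------------------
# B-spline machinery shared by the spline quantile model and the LMS smooths
# ---------------------------------------------------------------------------

def _spline_knots(lo: float, hi: float, n_basis: int, degree: int = 3) -> np.ndarray:
    if n_basis < degree + 1:
        raise ValueError(f"basis size must be at least degree + 1 = {degree + 1}")
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design_matrix(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(x, knots, degree).toarray()


def _greville(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    n_basis = len(knots) - degree - 1
    return np.array([knots[i + 1 : i + degree + 1].mean() for i in range(n_basis)])


def _second_diff_matrix(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Second divided differences at the Greville sites.

    Rows annihilate coefficient vectors sampled from any linear function, so a
    penalty built on this matrix shrinks the spline toward a straight line.
    """
    g = _greville(knots, degree)
    k = len(g)
    D = np.zeros((max(k - 2, 0), k))
    for i in range(k - 2):
        a = 1.0 / (g[i + 1] - g[i])
        c = 1.0 / (g[i + 2] - g[i + 1])
        D[i, i : i + 3] = (a, -(a + c), c)
    return D


def _solve_quantile_lp(B: np.ndarray, y: np.ndarray, tau: float,
                       penalty: float = 0.0, D: np.ndarray | None = None) -> np.ndarray:
    """Exact LP solution of sum-pinball + penalty * sum |D c| over coefficients c."""
    n, k = B.shape
    m = D.shape[0] if (penalty > 0 and D is not None and D.shape[0] > 0) else 0
    cost = np.concatenate([
        np.zeros(k), np.full(n, tau), np.full(n, 1.0 - tau),
        np.full(2 * m, float(penalty)),
    ])
    rows = [sparse.hstack([
        sparse.csr_matrix(B), sparse.eye(n), -sparse.eye(n),
        sparse.csr_matrix((n, 2 * m)),
    ])]
    b_eq = [y]
    if m:
        rows.append(sparse.hstack([
            sparse.csr_matrix(D), sparse.csr_matrix((m, 2 * n)),
            -sparse.eye(m), sparse.eye(m),
        ]))
        b_eq.append(np.zeros(m))
    A_eq = sparse.vstack(rows, format="csr")
    bounds = [(None, None)] * k + [(0, None)] * (2 * n + 2 * m)
    res = linprog(cost, A_eq=A_eq, b_eq=np.concatenate(b_eq), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:k]


# ---------------------------------------------------------------------------
# shared estimator surface
# ---------------------------------------------------------------------------

class _CentileModelBase(BaseEstimator):
    """Shared prediction surface: per-age quantile matrices, rearranged & clipped."""

    algorithm: str = ""

    def _check_fitted(self):
        if not hasattr(self, "age_range_"):
            raise ValueError(f"{type(self).__name__} instance is not fitted yet")

    def _raw_quantiles(self, ages: np.ndarray, taus: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_quantiles(self, ages, taus=None) -> np.ndarray:
        """Quantile matrix (len(ages) x len(taus)), non-crossing and clipped.

        Monotone rearrangement (sorting across the quantile levels at each
        age) guarantees the returned curves never cross; for bounded
        responses values are clipped to [0, 1].
        """
        self._check_fitted()
        taus = _validate_taus(self.taus if taus is None else taus)
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        Q = self._raw_quantiles(ages, taus)
        Q = np.sort(Q, axis=1)
        if getattr(self, "bounded_response", True):
            Q = np.clip(Q, 0.0, 1.0)
        return Q

    def _record_coverage(self, age: np.ndarray, y: np.ndarray):
        taus = np.asarray(self.taus, dtype=float)
        Q = self._raw_quantiles(age, taus)
        self.coverage_ = {
            float(t): float(np.mean(y < Q[:, j])) for j, t in enumerate(taus)
        }


def _validate_xy(age, y, *, bounded: bool, min_n: int):
    age = np.asarray(age, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if age.shape != y.shape:
        raise ValueError("age and y must have equal length")
    if len(y) < min_n:
        raise ValueError(f"at least {min_n} observations required")
    if bounded and np.any((y < 0) | (y > 1)):
        raise ValueError("response values must lie in [0, 1]")
    return age, y


class LinearQuantileRegressor(_CentileModelBase):
    """Straight-line quantile curves, one exact LP per quantile level.

    With ``intercept_only=True`` the slope is dropped and each fitted value is
    the empirical tau-quantile (the sample median at tau = 0.5).
    """

    algorithm = "LQR"

    def __init__(self, taus=DEFAULT_TAUS, intercept_only: bool = False,
                 bounded_response: bool = True):
        self.taus = taus
        self.intercept_only = intercept_only
        self.bounded_response = bounded_response

    def fit(self, age, y) -> "LinearQuantileRegressor":
        taus = _validate_taus(self.taus)
        age, y = _validate_xy(age, y, bounded=self.bounded_response, min_n=2)
        if not self.intercept_only and np.ptp(age) == 0:
            raise ValueError(
                "all ages identical: slope unidentifiable; refit with intercept_only=True"
            )
        B = np.ones((len(age), 1)) if self.intercept_only else np.column_stack(
            [np.ones(len(age)), age])
        self.coef_ = {}
        for t in taus:
            c = _solve_quantile_lp(B, y, float(t))
            self.coef_[float(t)] = (float(c[0]), 0.0 if self.intercept_only else float(c[1]))
        self.age_range_ = (float(age.min()), float(age.max()))
        self._record_coverage(age, y)
        return self

    def _raw_quantiles(self, ages, taus):
        Q = np.empty((len(ages), len(taus)))
        for j, t in enumerate(taus):
            if float(t) not in self.coef_:
                raise ValueError(f"tau {t} was not fitted")
            b0, b1 = self.coef_[float(t)]
            Q[:, j] = b0 + b1 * ages  # linear extrapolation beyond the data
        return Q

    def to_dict(self) -> dict:
        return {
            "kind": "centile_model", "algorithm": "LQR",
            "taus": [float(t) for t in self.taus],
            "intercept_only": bool(self.intercept_only),
            "bounded_response": bool(self.bounded_response),
            "coef": {str(t): list(v) for t, v in self.coef_.items()},
            "age_range": list(self.age_range_),
            "coverage": {str(t): v for t, v in self.coverage_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearQuantileRegressor":
        m = cls(taus=tuple(d["taus"]), intercept_only=d["intercept_only"],
                bounded_response=d["bounded_response"])
        m.coef_ = {float(t): tuple(v) for t, v in d["coef"].items()}
        m.age_range_ = tuple(d["age_range"])
        m.coverage_ = {float(t): v for t, v in d["coverage"].items()}
        return m


class SplineQuantileRegressor(_CentileModelBase):
    """Penalized cubic B-spline quantile curves (exact LP per quantile level).

    ``penalty=None`` selects a shared penalty weight by a Schwarz-type
    criterion on the median fit over a log-spaced grid.  Evaluation outside
    the training age range raises: the spline basis does not extrapolate.
    """

    algorithm = "NQR"

    def __init__(self, taus=DEFAULT_TAUS, penalty: float | None = None,
                 basis_size: int = 8, degree: int = 3, bounded_response: bool = True):
        self.taus = taus
        self.penalty = penalty
        self.basis_size = basis_size
        self.degree = degree
        self.bounded_response = bounded_response

    def _sic(self, B, y, tau, lam, D) -> float:
        c = _solve_quantile_lp(B, y, tau, lam, D)
        r = y - B @ c
        loss = pinball_loss(y, B @ c, tau)
        df = int(np.sum(np.abs(r) < 1e-8 * max(1.0, np.std(y))))
        n = len(y)
        return n * np.log(max(loss, 1e-300)) + 0.5 * df * np.log(n)

    def fit(self, age, y) -> "SplineQuantileRegressor":
        taus = _validate_taus(self.taus)
        if self.basis_size < 4:
            raise ValueError("basis_size must be at least 4")
        age, y = _validate_xy(age, y, bounded=self.bounded_response, min_n=self.basis_size)
        self.knots_ = _spline_knots(float(age.min()), float(age.max()),
                                    self.basis_size, self.degree)
        B = _design_matrix(age, self.knots_, self.degree)
        D = _second_diff_matrix(self.knots_, self.degree)
        if self.penalty is None:
            grid = np.logspace(-2, 3, 6)
            sics = [self._sic(B, y, 0.5, lam, D) for lam in grid]
            self.penalty_ = float(grid[int(np.argmin(sics))])
        else:
            if self.penalty < 0:
                raise ValueError("penalty must be non-negative")
            self.penalty_ = float(self.penalty)
        self.coef_ = {float(t): _solve_quantile_lp(B, y, float(t), self.penalty_, D)
                      for t in taus}
        self.age_range_ = (float(age.min()), float(age.max()))
        self._record_coverage(age, y)
        return self

    def _raw_quantiles(self, ages, taus):
        lo, hi = self.age_range_
        if np.any((ages < lo - 1e-9) | (ages > hi + 1e-9)):
            raise ValueError(
                f"age outside the fitted range [{lo:.1f}, {hi:.1f}]: the spline "
                "quantile model does not extrapolate"
            )
        B = _design_matrix(ages, self.knots_, self.degree)
        Q = np.empty((len(ages), len(taus)))
        for j, t in enumerate(taus):
            if float(t) not in self.coef_:
                raise ValueError(f"tau {t} was not fitted")
            Q[:, j] = B @ self.coef_[float(t)]
        return Q

    def to_dict(self) -> dict:
        return {
            "kind": "centile_model", "algorithm": "NQR",
            "taus": [float(t) for t in self.taus],
            "penalty": self.penalty_, "basis_size": int(self.basis_size),
            "degree": int(self.degree),
            "bounded_response": bool(self.bounded_response),
            "knots": self.knots_.tolist(),
            "coef": {str(t): v.tolist() for t, v in self.coef_.items()},
            "age_range": list(self.age_range_),
            "coverage": {str(t): v for t, v in self.coverage_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineQuantileRegressor":
        m = cls(taus=tuple(d["taus"]), penalty=d["penalty"], basis_size=d["basis_size"],
                degree=d["degree"], bounded_response=d["bounded_response"])
        m.penalty_ = float(d["penalty"])
        m.knots_ = np.asarray(d["knots"], dtype=float)
        m.coef_ = {float(t): np.asarray(v, dtype=float) for t, v in d["coef"].items()}
        m.age_range_ = tuple(d["age_range"])
        m.coverage_ = {float(t): v for t, v in d["coverage"].items()}
        return m


# ---------------------------------------------------------------------------
# LMS / Box-Cox Cole-Green model on the shifted-logit scale
# ---------------------------------------------------------------------------

def _bccg_z(t, lam, mu, sigma):
    L = np.log(t / mu)
    small = np.abs(lam) < 1e-8
    with np.errstate(over="ignore"):
        z_gen = (np.exp(np.where(small, 0.0, lam) * L) - 1.0) / np.where(
            small, 1.0, lam * sigma)
    return np.where(small, L / sigma, z_gen)


def _bccg_loglik_grads(t, lam, mu, sigma):
    """Per-observation log-likelihood and gradients wrt (lambda, log mu, log sigma)."""
    L = np.log(t / mu)
    z = _bccg_z(t, lam, mu, sigma)
    ll = (lam - 1.0) * np.log(t) - lam * np.log(mu) - np.log(sigma) - 0.5 * z**2
    small = np.abs(lam) < 1e-8
    with np.errstate(over="ignore"):
        r = np.exp(np.where(small, 0.0, lam) * L)  # (t/mu)^lambda
    d_eta_mu = -lam + z * r / sigma
    d_eta_sigma = z**2 - 1.0
    lam_safe = np.where(small, 1.0, lam)
    d_lam_gen = L - z * (L * r / (lam_safe * sigma) - z / lam_safe)
    d_lam_zero = L - (L**3) / (2.0 * sigma**2)
    d_lam = np.where(small, d_lam_zero, d_lam_gen)
    return ll, d_lam, d_eta_mu, d_eta_sigma


class LMSCentileModel(_CentileModelBase):
    """LMS (Box-Cox Cole-Green) centile model for a response on (0, 1).

    The response is mapped to a strictly positive working variable
    ``t = logit(clip(y, eps, 1-eps)) + shift`` and modelled as BCCG with
    B-spline smooths of the skewness lambda(age) (identity link), the median
    mu(age) (log link) and the coefficient of variation sigma(age) (log link).
    Fitting maximizes the penalized likelihood by backfitting the three
    coefficient blocks (L-BFGS-B inner steps, quadratic second-difference
    penalties) until the relative change drops below ``tol``.

    Quantiles invert the fitted distribution and back-transform; beyond the
    training age range the parameter curves are frozen at their boundary
    values.  ``centile`` returns the conditional CDF value F(y | age).
    """

    algorithm = "LMS"
    bounded_response = True

    def __init__(self, taus=DEFAULT_TAUS, mu_df: int = 6, sigma_df: int = 4,
                 lambda_df: int = 1, smoothing=(1.0, 1.0, 0.0), eps: float = 1e-4,
                 shift: float = 12.0, tol: float = 1e-6, max_iter: int = 200):
        self.taus = taus
        self.mu_df = mu_df
        self.sigma_df = sigma_df
        self.lambda_df = lambda_df
        self.smoothing = smoothing
        self.eps = eps
        self.shift = shift
        self.tol = tol
        self.max_iter = max_iter

    # -- working transform ---------------------------------------------------
    def _to_working(self, y):
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("response values must lie in [0, 1]")
        return logit(np.clip(y, self.eps, 1.0 - self.eps)) + self.shift

    def _from_working(self, t):
        return expit(np.asarray(t, dtype=float) - self.shift)

    def _basis(self, which: str, ages: np.ndarray) -> np.ndarray:
        df = {"lambda": self.lambda_df, "mu": self.mu_df, "sigma": self.sigma_df}[which]
        if df == 1:
            return np.ones((len(ages), 1))
        return _design_matrix(ages, self.knots_[which], 3)

    def _curves(self, ages: np.ndarray):
        lo, hi = self.age_range_
        a = np.clip(np.asarray(ages, dtype=float), lo, hi)  # frozen extrapolation
        lam = self._basis("lambda", a) @ self.coef_["lambda"]
        mu = np.exp(self._basis("mu", a) @ self.coef_["mu"])
        sigma = np.exp(self._basis("sigma", a) @ self.coef_["sigma"])
        return lam, mu, sigma

    def fit(self, age, y) -> "LMSCentileModel":
        _validate_taus(self.taus)
        age, y = _validate_xy(age, y, bounded=True, min_n=20)
        t = self._to_working(y)
        self.age_range_ = (float(age.min()), float(age.max()))
        lo, hi = self.age_range_

        self.knots_ = {}
        for which, df in (("lambda", self.lambda_df), ("mu", self.mu_df),
                          ("sigma", self.sigma_df)):
            if df > 1:
                self.knots_[which] = _spline_knots(lo, hi, df, 3)
        bases = {w: self._basis(w, age) for w in ("lambda", "mu", "sigma")}
        pens = {}
        for w, s in zip(("mu", "sigma", "lambda"),
                        (self.smoothing[0], self.smoothing[1], self.smoothing[2])):
            k = bases[w].shape[1]
            if k > 2 and s > 0:
                D = _second_diff_matrix(self.knots_[w], 3)
                pens[w] = s * (D.T @ D)
            else:
                pens[w] = np.zeros((k, k))

        # starting values: lambda = 1; mu from a ridge fit of log t; sigma from
        # the residual spread (B-spline bases sum to one, so equal coefficients
        # give constant curves)
        logt = np.log(t)
        Bm = bases["mu"]
        cm = np.linalg.solve(Bm.T @ Bm + pens["mu"] + 1e-8 * np.eye(Bm.shape[1]),
                             Bm.T @ logt)
        resid_sd = float(np.std(logt - Bm @ cm, ddof=1))
        coef = {
            "lambda": np.ones(bases["lambda"].shape[1]),
            "mu": cm,
            "sigma": np.full(bases["sigma"].shape[1], np.log(max(resid_sd, 1e-3))),
        }
        bounds = {
            "lambda": [(-4.0, 4.0)] * len(coef["lambda"]),
            "mu": [(np.log(1e-2), np.log(1e3))] * len(coef["mu"]),
            "sigma": [(-8.0, 2.0)] * len(coef["sigma"]),
        }

        def pen_loglik(c):
            lam = bases["lambda"] @ c["lambda"]
            mu = np.exp(bases["mu"] @ c["mu"])
            sigma = np.exp(bases["sigma"] @ c["sigma"])
            ll, *_ = _bccg_loglik_grads(t, lam, mu, sigma)
            pen = sum(c[w] @ pens[w] @ c[w] for w in c)
            return float(np.sum(ll) - 0.5 * pen)

        def step(which):
            others = {w: coef[w] for w in coef}

            def negobj(cw):
                others[which] = cw
                lam = bases["lambda"] @ others["lambda"]
                mu = np.exp(bases["mu"] @ others["mu"])
                sigma = np.exp(bases["sigma"] @ others["sigma"])
                ll, d_lam, d_emu, d_esig = _bccg_loglik_grads(t, lam, mu, sigma)
                grad_per_obs = {"lambda": d_lam, "mu": d_emu, "sigma": d_esig}[which]
                g = bases[which].T @ grad_per_obs - pens[which] @ cw
                f = np.sum(ll) - 0.5 * sum(others[w] @ pens[w] @ others[w] for w in others)
                return -f, -g

            res = minimize(negobj, coef[which], jac=True, method="L-BFGS-B",
                           bounds=bounds[which],
                           options={"maxiter": 60, "ftol": 1e-12})
            coef[which] = res.x

        trace = [pen_loglik(coef)]
        converged = False
        for _ in range(self.max_iter):
            for which in ("mu", "sigma", "lambda"):
                step(which)
            trace.append(pen_loglik(coef))
            denom = abs(trace[-2]) + 1e-12
            if abs(trace[-1] - trace[-2]) / denom < self.tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"backfitting did not converge in {self.max_iter} iterations", trace)

        self.coef_ = coef
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace) - 1
        self._record_coverage(age, y)
        return self

    def _raw_quantiles(self, ages, taus):
        lam, mu, sigma = self._curves(ages)
        Q = np.empty((len(ages), len(taus)))
        for j, tau in enumerate(taus):
            z = ndtri(float(tau))
            small = np.abs(lam) < 1e-8
            lam_safe = np.where(small, 1.0, lam)
            base = np.maximum(1.0 + lam_safe * sigma * z, 1e-12)
            with np.errstate(over="ignore"):
                t_gen = mu * base ** (1.0 / lam_safe)
            t_q = np.where(small, mu * np.exp(sigma * z), t_gen)
            Q[:, j] = self._from_working(t_q)
        return Q

    def centile(self, age, y):
        """Conditional CDF value F(y | age) of the fitted distribution."""
        self._check_fitted()
        age = np.atleast_1d(np.asarray(age, dtype=float))
        y_arr = np.atleast_1d(np.asarray(y, dtype=float))
        if np.any((y_arr <= 0) | (y_arr >= 1)):
            raise ValueError("y must lie strictly inside (0, 1) for centile lookup")
        lam, mu, sigma = self._curves(age)
        t = self._to_working(y_arr)
        z = _bccg_z(t, lam, mu, sigma)
        out = ndtr(z)
        return float(out[0]) if np.isscalar(y) and out.size == 1 else out

    def to_dict(self) -> dict:
        return {
            "kind": "centile_model", "algorithm": "LMS",
            "taus": [float(t) for t in self.taus],
            "mu_df": self.mu_df, "sigma_df": self.sigma_df, "lambda_df": self.lambda_df,
            "smoothing": list(self.smoothing), "eps": self.eps, "shift": self.shift,
            "age_range": list(self.age_range_),
            "knots": {w: k.tolist() for w, k in self.knots_.items()},
            "coef": {w: c.tolist() for w, c in self.coef_.items()},
            "coverage": {str(t): v for t, v in self.coverage_.items()},
            "n_iter": self.n_iter_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMSCentileModel":
        m = cls(taus=tuple(d["taus"]), mu_df=d["mu_df"], sigma_df=d["sigma_df"],
                lambda_df=d["lambda_df"], smoothing=tuple(d["smoothing"]),
                eps=d["eps"], shift=d["shift"])
        m.age_range_ = tuple(d["age_range"])
        m.knots_ = {w: np.asarray(k, dtype=float) for w, k in d["knots"].items()}
        m.coef_ = {w: np.asarray(c, dtype=float) for w, c in d["coef"].items()}
        m.coverage_ = {float(t): v for t, v in d["coverage"].items()}
        m.n_iter_ = d["n_iter"]
        return m


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_lqr(age, y, taus=DEFAULT_TAUS, **kwargs) -> LinearQuantileRegressor:
    return LinearQuantileRegressor(taus=taus, **kwargs).fit(age, y)


def fit_nqr(age, y, taus=DEFAULT_TAUS, penalty=None, basis_size=8,
            **kwargs) -> SplineQuantileRegressor:
    return SplineQuantileRegressor(taus=taus, penalty=penalty,
                                   basis_size=basis_size, **kwargs).fit(age, y)


def fit_lms(age, y, taus=DEFAULT_TAUS, smoothing=(1.0, 1.0, 0.0),
            **kwargs) -> LMSCentileModel:
    return LMSCentileModel(taus=taus, smoothing=smoothing, **kwargs).fit(age, y)


def predict_quantiles(model: _CentileModelBase, ages, taus=None) -> np.ndarray:
    return model.predict_quantiles(ages, taus)


def individual_centile(model, age, y):
    """F(y | age) from a distributional (LMS) model.

    Quantile-only models (LQR/NQR) yield category ratings, not centiles.
    """
    if not isinstance(model, LMSCentileModel):
        raise UnsupportedOperationError(
            "individual centiles require the distributional LMS model; "
            f"{type(model).__name__} provides percentile curves only"
        )
    return model.centile(age, y)
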