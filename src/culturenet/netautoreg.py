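"""Maximum-likelihood network-disturbances autoregression.

The model is the Gaussian linear autoregression with autocorrelated
disturbances,

    y = X beta + eps,      eps = W eps + nu,      nu ~ N(0, sigma^2 I),

where W = sum_k rho_k W_k combines one to four a-priori weight matrices.
Equivalently (I - W) eps = nu, so

    y ~ N(X beta, sigma^2 A^{-1} A^{-T}),      A = I - sum_k rho_k W_k.

rho_k measures how strongly the outcome's residual variation patterns on
network k: rho = 0 recovers ordinary least squares, positive rho means
connected nodes are similar, negative means they are dissimilar. The rho are
unbounded: the Gaussian density uses ln|det(A)|, which is well defined
wherever A is nonsingular, so estimates beyond the first spectral bound
(|rho| > 1 on a row-normalized matrix, rho > 1/lambda_max on a dense
affinity) are legitimate and do occur — they inflate the correlations the
network predicts. Only exactly singular A is outside the family.

beta and sigma^2 are profiled out analytically; rho is optimized numerically
(per-matrix profile scans spanning several spectral ranges choose starting
points, then Nelder-Mead refines the best ones; candidates where A is
numerically singular are rejected). Standard errors come from the inverse
numerical Hessian of the negative full log-likelihood at the optimum;
p-values are two-sided normal z-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .weights import WeightMatrix

LOGLIK_TOL = 1e-8  # convergence tolerance on the concentrated log-likelihood

_LOG2PI = float(np.log(2.0 * np.pi))


class StabilityDomainError(ValueError):
    """I - W is (numerically) singular at the requested rho."""


class DegenerateDesignError(ValueError):
    """Singular transformed design or constant outcome."""


@dataclass(frozen=True)
class DisturbanceModel:
    """An outcome vector, a design matrix and the weight matrices to fit.

    The design is typically a lone intercept column; ``w_list`` may be empty,
    in which case the model is an ordinary Gaussian intercept(-plus-X) model.
    """

    y: np.ndarray
    X: np.ndarray
    w_list: tuple[WeightMatrix, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        n = y.size
        if n < 3:
            raise DegenerateDesignError("need at least 3 observations")
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise DegenerateDesignError("design rows do not match outcome length")
        for w in self.w_list:
            if w.values.shape != (n, n):
                raise DegenerateDesignError(
                    f"weight matrix {w.label!r} is {w.values.shape}, expected {(n, n)}"
                )
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "w_list", tuple(self.w_list))

    @classmethod
    def intercept_only(cls, y: np.ndarray, w_list: tuple[WeightMatrix, ...] = ()) -> "DisturbanceModel":
        y = np.asarray(y, dtype=float).ravel()
        return cls(y=y, X=np.ones((y.size, 1)), w_list=w_list)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w.label for w in self.w_list)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates for a disturbances model.

    ``k_params`` counts every free parameter (regression coefficients,
    sigma^2, and one rho per weight matrix), so BIC gaps are reproducible.
    """

    beta: np.ndarray
    sigma2: float
    rho: np.ndarray
    rho_se: np.ndarray
    rho_p: np.ndarray
    loglik: float
    bic: float
    n: int
    k_params: int
    converged: bool
    labels: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "beta": [float(b) for b in np.atleast_1d(self.beta)],
            "sigma2": float(self.sigma2),
            "rho": {lab: float(r) for lab, r in zip(self.labels, self.rho)},
            "rho_se": {lab: float(s) for lab, s in zip(self.labels, self.rho_se)},
            "rho_p": {lab: float(p) for lab, p in zip(self.labels, self.rho_p)},
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n": int(self.n),
            "k_params": int(self.k_params),
            "converged": bool(self.converged),
        }
        return json.dumps(payload, sort_keys=False)


def _disturbance_operator(model: DisturbanceModel, rho: np.ndarray) -> np.ndarray:
    A = np.eye(model.n)
    with np.errstate(over="ignore", invalid="ignore"):
        for r, w in zip(rho, model.w_list):
            A -= r * w.values
    if not np.isfinite(A).all():
        raise StabilityDomainError(f"non-finite operator at rho = {np.asarray(rho).tolist()}")
    return A


def _profile(model: DisturbanceModel, rho: np.ndarray):
    """Profile beta and sigma^2 at fixed rho.

    Returns (beta_hat, sigma2_hat, logdet_A) or raises on an invalid rho.
    """
    A = _disturbance_operator(model, rho)
    sign, logdet = np.linalg.slogdet(A)
    if sign == 0 or not np.isfinite(logdet):
        raise StabilityDomainError(f"I - W singular at rho = {np.asarray(rho).tolist()}")
    with np.errstate(over="ignore", invalid="ignore"):
        yt = A @ model.y
        Xt = A @ model.X
        XtX = Xt.T @ Xt
        if not (np.isfinite(XtX).all() and np.isfinite(yt).all()):
            raise DegenerateDesignError("transformed system overflows")
        try:
            c_factor = linalg.cho_factor(XtX, check_finite=False)
            beta = linalg.cho_solve(c_factor, Xt.T @ yt, check_finite=False)
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            raise DegenerateDesignError("transformed design is singular") from None
        resid = yt - Xt @ beta
        sigma2 = float(resid @ resid) / model.n
    if not np.isfinite(sigma2):
        raise DegenerateDesignError("residual variance overflows")
    return beta, sigma2, float(logdet)


def concentrated_loglik(model: DisturbanceModel, rho: np.ndarray | float = ()) -> float:
    """Log-likelihood maximized over beta and sigma^2 at fixed rho.

    With A = I - sum rho_k W_k, beta profiled by least squares of Ay on AX and
    sigma^2 by the mean squared residual, the concentrated value is

        -(n/2) ln(2 pi sigma2_hat) + ln|det(A)| - n/2.

    At rho = 0 this is exactly the OLS Gaussian log-likelihood. The density
    uses |det(A)| (the model covariance sigma^2 A^-1 A^-T is positive
    definite for any nonsingular A), so rho is unbounded.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if rho.size != len(model.w_list):
        raise ValueError(f"rho has length {rho.size}, model has {len(model.w_list)} matrices")
    _, sigma2, logdet = _profile(model, rho)
    if sigma2 <= 0:
        raise DegenerateDesignError("zero residual variance (constant outcome?)")
    n = model.n
    return -0.5 * n * (_LOG2PI + np.log(sigma2)) + logdet - 0.5 * n


def full_loglik(model: DisturbanceModel, beta: np.ndarray, sigma2: float,
                rho: np.ndarray) -> float:
    """Unconcentrated log-likelihood at arbitrary (beta, sigma2, rho)."""
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    A = _disturbance_operator(model, rho)
    sign, logdet = np.linalg.slogdet(A)
    if sign == 0 or not np.isfinite(logdet) or sigma2 <= 0:
        return -np.inf
    n = model.n
    with np.errstate(over="ignore", invalid="ignore"):
        resid = A @ (model.y - model.X @ np.atleast_1d(beta))
        val = (-0.5 * n * (_LOG2PI + np.log(sigma2)) + logdet
               - 0.5 * float(resid @ resid) / sigma2)
    return val if np.isfinite(val) else -np.inf


def bic(fit: FitResult) -> float:
    """Bayesian Information Criterion, -2 loglik + k ln(n); lower preferred."""
    return -2.0 * fit.loglik + fit.k_params * np.log(fit.n)


#: profile scans cover rho*lambda_max in this many spectral widths
PHI_SCAN_RANGE = 3.0
PHI_SCAN_POINTS = 25


def _spectral_scale(w: WeightMatrix) -> float:
    """Largest |real eigenvalue| of a weight matrix (1 for row-normalized).

    Cached on the (frozen) WeightMatrix instance, since sweeps refit the same
    matrices dozens of times per bin.
    """
    cached = getattr(w, "_spectral_scale", None)
    if cached is not None:
        return cached
    lam = np.linalg.eigvals(w.values)
    real = np.abs(lam.real[np.abs(lam.imag) < 1e-9])
    scale = float(real.max()) if real.size else 1.0
    object.__setattr__(w, "_spectral_scale", scale)
    return scale


def fit(model: DisturbanceModel) -> FitResult:
    """Fit the disturbances model by maximum likelihood.

    Because the likelihood surface can be multimodal (log-singularities of
    ln|det| split the rho axis into ridges), each matrix's rho axis is first
    scanned on a grid spanning several spectral ranges (rho*lambda_max in
    [-3, 3]); Nelder-Mead then refines from rho = 0 and from the best scan
    point, and the better optimum wins. Non-convergence is flagged on the
    result, not raised.
    """
    if np.ptp(model.y) == 0:
        raise DegenerateDesignError("outcome is constant; model not estimable")

    k = len(model.w_list)
    n = model.n
    p = model.X.shape[1]
    k_params = p + 1 + k  # beta's + sigma^2 + rho's

    def neg_conc(rho_vec: np.ndarray) -> float:
        try:
            return -concentrated_loglik(model, rho_vec)
        except (StabilityDomainError, DegenerateDesignError):
            return np.inf

    if k == 0:
        rho_hat = np.zeros(0)
        converged = True
    else:
        scales = np.array([_spectral_scale(w) for w in model.w_list])
        # per-axis profile scan with the other rho's held at 0
        axis_best = np.zeros(k)
        for j in range(k):
            grid = np.linspace(-PHI_SCAN_RANGE, PHI_SCAN_RANGE, PHI_SCAN_POINTS) / scales[j]
            cand = np.zeros((grid.size, k))
            cand[:, j] = grid
            vals = np.array([neg_conc(c) for c in cand])
            axis_best[j] = grid[int(np.argmin(vals))]
        starts = [np.zeros(k), axis_best]
        if k > 1:
            # single best axis alone, others at 0
            lone = np.zeros(k)
            j_star = int(np.argmax(np.abs(axis_best) * scales))
            lone[j_star] = axis_best[j_star]
            starts.append(lone)
        # dedupe coincident starts (e.g. all scans flat at 0)
        uniq: list[np.ndarray] = []
        for s in starts:
            if not any(np.allclose(s, u) for u in uniq):
                uniq.append(s)
        best = None
        for x0 in uniq:
            res = optimize.minimize(
                neg_conc, x0=x0, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": LOGLIK_TOL,
                         "maxiter": 2000, "maxfev": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        rho_hat = np.atleast_1d(best.x)
        converged = bool(best.success) and np.isfinite(best.fun)

    try:
        beta_hat, sigma2_hat, _ = _profile(model, rho_hat)
        loglik = concentrated_loglik(model, rho_hat)
    except (StabilityDomainError, DegenerateDesignError):
        return FitResult(
            beta=np.full(p, np.nan), sigma2=np.nan, rho=rho_hat,
            rho_se=np.full(k, np.nan), rho_p=np.full(k, np.nan),
            loglik=-np.inf, bic=np.inf, n=n, k_params=k_params,
            converged=False, labels=model.labels,
        )

    rho_se = np.full(k, np.nan)
    rho_p = np.full(k, np.nan)
    if k > 0 and converged:
        theta = np.concatenate([beta_hat, [sigma2_hat], rho_hat])

        def neg_full(t: np.ndarray) -> float:
            ll = full_loglik(model, t[:p], t[p], t[p + 1:])
            return np.inf if not np.isfinite(ll) else -ll

        try:
            H = approx_hess(theta, neg_full)
            cov = np.linalg.inv(H)
            diag = np.diag(cov)[p + 1:]
            with np.errstate(invalid="ignore"):
                se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
                z = rho_hat / se
            rho_se = se
            rho_p = 2.0 * stats.norm.sf(np.abs(z))
        except np.linalg.LinAlgError:
            pass

    result = FitResult(
        beta=beta_hat, sigma2=sigma2_hat, rho=rho_hat,
        rho_se=rho_se, rho_p=rho_p,
        loglik=float(loglik), bic=np.nan, n=n, k_params=k_params,
        converged=converged, labels=model.labels,
    )
    object.__setattr__(result, "bic", bic(result))
    return result
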