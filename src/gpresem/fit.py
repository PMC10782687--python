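"""Maximum-likelihood estimation of recursive path models.

The fitting problem: given a sample covariance matrix ``S`` over ``p``
observed variables and a compiled path model with implied covariance
``Sigma(theta) = (I-A)^-1 S_par (I-A)^-T``, minimise the ML discrepancy

    F(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

The model chi-square is ``(N-1) * F_min``; standard errors come from the
inverse expected-information matrix
``I_jk = (N-1)/2 * tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k)`` and critical
ratios are estimate/SE.  Because observed variables may live on wildly
different scales (an absorbance variance of 1e-7 next to a concentration
variance of 12), the optimisation is carried out in a correlation-scaled
metric and the solution mapped back; ``F`` is invariant under this
per-variable rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .model import PathModel, RAMMatrices, to_ram

__all__ = [
    "SampleMoments",
    "FitResult",
    "NonPositiveDefiniteError",
    "ConvergenceError",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "standardize",
    "recursive_ml_start",
    "MLPathAnalysis",
]


class NonPositiveDefiniteError(ValueError):
    """A covariance matrix that must be positive definite is not."""


class ConvergenceError(RuntimeError):
    """The discrepancy minimiser failed to reach the convergence criteria."""


@dataclass(frozen=True)
class SampleMoments:
    """A sample covariance matrix with its sample size.

    Parameters
    ----------
    S : (p, p) ndarray
        Symmetric positive-definite covariance matrix.
    n : int
        Number of observations (regenerants).
    variable_names : tuple of str
        Names aligned with the rows/columns of ``S``.
    divisor : {"n", "n-1"}
        Which divisor produced ``S`` (ML/biased vs unbiased).  Recorded for
        bookkeeping and unit conversion; the fit uses ``S`` as given.
    """

    S: np.ndarray
    n: int
    variable_names: tuple[str, ...]
    divisor: str = "n-1"

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if len(self.variable_names) != S.shape[0]:
            raise ValueError("variable_names must match the order of S")
        if self.divisor not in ("n", "n-1"):
            raise ValueError("divisor must be 'n' or 'n-1'")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        _assert_pd(S, "sample covariance S")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    def to_divisor(self, divisor: str) -> "SampleMoments":
        """Return the same moments under the other divisor convention."""
        if divisor == self.divisor:
            return self
        factor = (self.n - 1) / self.n if divisor == "n" else self.n / (self.n - 1)
        return SampleMoments(self.S * factor, self.n, self.variable_names, divisor)

    def reorder(self, names) -> "SampleMoments":
        idx = [self.variable_names.index(v) for v in names]
        return SampleMoments(self.S[np.ix_(idx, idx)], self.n, tuple(names), self.divisor)

    @classmethod
    def from_data(cls, X, variable_names=None, divisor: str = "n-1") -> "SampleMoments":
        """Compute moments from a samples-by-variables table."""
        if isinstance(X, pd.DataFrame):
            variable_names = tuple(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if variable_names is None:
            variable_names = tuple(f"x{i}" for i in range(X.shape[1]))
        ddof = 1 if divisor == "n-1" else 0
        S = np.cov(X, rowvar=False, ddof=ddof)
        return cls(S, n, variable_names, divisor)


def _assert_pd(S: np.ndarray, what: str) -> None:
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        ev = np.linalg.eigvalsh(S)
        raise NonPositiveDefiniteError(
            f"{what} is not positive definite (smallest eigenvalue {ev[0]:.3e})"
        ) from None


@dataclass
class FitResult:
    """Estimates and diagnostics from an ML fit of a path model."""

    model: PathModel
    moments: SampleMoments
    ram: RAMMatrices
    theta: np.ndarray
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    critical_ratios: dict[str, float]
    standardized: dict[str, float]
    f_min: float
    chi_square: float
    df: int
    implied_sigma: np.ndarray
    converged: bool
    n_iterations: int
    gradient_norm: float
    heywood: bool = False

    @property
    def p_value(self) -> float:
        from scipy import stats

        if self.df == 0:
            return float("nan")
        return float(stats.chi2.sf(self.chi_square, self.df))

    @property
    def q(self) -> int:
        return self.ram.q

    def implied_sd(self) -> dict[str, float]:
        sd = np.sqrt(np.diag(self.implied_sigma))
        return dict(zip(self.model.variables, sd))

    def summary(self) -> pd.DataFrame:
        """Path-coefficient table: estimate, SE, critical ratio, beta."""
        rows = []
        for lab in self.ram.labels():
            rows.append(
                {
                    "parameter": lab,
                    "estimate": self.estimates[lab],
                    "se": self.standard_errors[lab],
                    "critical_ratio": self.critical_ratios[lab],
                    "standardized": self.standardized.get(lab, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def implied_covariance(ram: RAMMatrices, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance ``(I-A)^-1 S_par (I-A)^-T``."""
    A, S_par = ram.fill(theta)
    eye = np.eye(ram.p)
    B = np.linalg.solve(eye - A, eye)
    sigma = B @ S_par @ B.T
    return 0.5 * (sigma + sigma.T)


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy ``ln|Sigma| - ln|S| + tr(S Sigma^-1) - p``."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if S.shape != sigma.shape:
        raise ValueError("S and Sigma must have the same shape")
    _assert_pd(S, "S")
    _assert_pd(sigma, "Sigma")
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    return float(logdet_m - logdet_s + np.trace(np.linalg.solve(sigma, S)) - p)


def recursive_ml_start(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Deterministic starting values in the model's free-parameter order.

    Path coefficients from per-equation least squares on the direct parents,
    residual variances from the corresponding conditional variances, and
    exogenous (co)variances from the sample values.  For a recursive model
    with uncorrelated residuals and an unconstrained exogenous block this is
    already the ML solution (the likelihood factorises along the DAG), so
    the optimiser's job reduces to verification/polish; for other patterns
    it is just a good start.
    """
    ram = to_ram(model)
    pos = {v: i for i, v in enumerate(model.variables)}
    path_val: dict[str, float] = {}
    resid_val: dict[str, float] = {}
    for v in model.endogenous:
        parents = model.parents(v)
        pi = [pos[x] for x in parents]
        ti = pos[v]
        Spp = S[np.ix_(pi, pi)]
        Spt = S[np.ix_(pi, [ti])]
        b = np.linalg.solve(Spp, Spt).ravel()
        labels = model.path_labels()
        for x, bx in zip(parents, b):
            path_val[labels[(x, v)]] = bx
        explained = float((Spt.T @ np.linalg.solve(Spp, Spt))[0, 0]) if pi else 0.0
        resid_val[model.residual_labels[v]] = float(S[ti, ti]) - explained
    theta = np.empty(ram.q)
    for k, (mat, i, j, lab) in enumerate(ram.free_map):
        if mat == "A":
            theta[k] = path_val[lab]
        elif i == j:
            theta[k] = resid_val.get(lab, S[i, i])
        else:
            theta[k] = S[i, j]
    return theta


def _dsigma(ram: RAMMatrices, B: np.ndarray, sigma: np.ndarray, k: int) -> np.ndarray:
    """Derivative of the implied covariance w.r.t. free parameter ``k``."""
    mat, i, j, _ = ram.free_map[k]
    if mat == "A":
        # d(I-A)^-1/dA_ij = B E_ij B  =>  dSigma = B E_ij Sigma + transpose
        M = np.outer(B[:, i], sigma[j, :])
        return M + M.T
    if i == j:
        return np.outer(B[:, i], B[:, i])
    M = np.outer(B[:, i], B[:, j])
    return M + M.T


def _grad_and_info(
    ram: RAMMatrices, theta: np.ndarray, S: np.ndarray, want_info: bool
) -> tuple[float, np.ndarray, np.ndarray | None, np.ndarray]:
    """F, its gradient, optionally 0.5*tr(...) expected information, Sigma."""
    A, S_par = ram.fill(theta)
    eye = np.eye(ram.p)
    B = np.linalg.solve(eye - A, eye)
    sigma = B @ S_par @ B.T
    sigma = 0.5 * (sigma + sigma.T)
    sign, logdet_m = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros(ram.q), None, sigma
    sigma_inv = np.linalg.inv(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    F = logdet_m - logdet_s + float(np.trace(sigma_inv @ S)) - ram.p
    W = sigma_inv - sigma_inv @ S @ sigma_inv  # dF/dSigma (up to symmetry)
    grad = np.empty(ram.q)
    derivs = []
    for k in range(ram.q):
        dS = _dsigma(ram, B, sigma, k)
        derivs.append(dS)
        grad[k] = float(np.sum(W * dS))
    info = None
    if want_info:
        T = [sigma_inv @ d for d in derivs]
        info = np.empty((ram.q, ram.q))
        for a in range(ram.q):
            for b in range(a, ram.q):
                info[a, b] = info[b, a] = 0.5 * float(np.sum(T[a] * T[b].T))
    return F, grad, info, sigma


def fit_ml(
    model: PathModel,
    moments: SampleMoments,
    theta0: np.ndarray | None = None,
    max_iter: int = 500,
    f_tol: float = 1e-10,
    g_tol: float = 1e-8,
) -> FitResult:
    """Fit a path model to sample moments by maximum likelihood.

    Parameters
    ----------
    model, moments
        Model and sample covariance (the moment order is aligned to the
        model's variable order automatically).
    theta0 : ndarray, optional
        Starting values in free-parameter order; defaults to
        :func:`recursive_ml_start`.
    max_iter, f_tol, g_tol
        Fisher-scoring iteration cap and convergence criteria
        (``|dF| < f_tol`` or gradient infinity-norm ``< g_tol``).

    Returns
    -------
    FitResult
        With a ``heywood`` flag (negative residual variance at the optimum)
        instead of an exception for improper solutions.
    """
    if set(model.variables) - set(moments.variable_names):
        missing = sorted(set(model.variables) - set(moments.variable_names))
        raise ValueError(f"moments do not cover model variables: {missing}")
    moments = moments.reorder(model.variables)
    ram = to_ram(model)
    if ram.df < 0:
        raise ValueError(f"model is over-parameterised: df = {ram.df} < 0")

    # correlation-metric rescaling for numerical conditioning
    d = np.sqrt(np.diag(moments.S))
    S_sc = moments.S / np.outer(d, d)
    scale = np.empty(ram.q)  # theta_original = scale * theta_scaled
    for k, (mat, i, j, _) in enumerate(ram.free_map):
        scale[k] = d[i] / d[j] if mat == "A" else d[i] * d[j]

    if theta0 is None:
        theta = recursive_ml_start(model, S_sc)
    else:
        theta = np.asarray(theta0, dtype=float) / scale

    # Fisher scoring with step-halving; quasi-Newton fallback
    F, grad, info, sigma = _grad_and_info(ram, theta, S_sc, want_info=True)
    n_iter = 0
    converged = np.linalg.norm(grad, np.inf) < g_tol
    for n_iter in range(1, max_iter + 1):
        if converged:
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(ram.q), grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(30):
            F_new, grad_new, info_new, sigma_new = _grad_and_info(
                ram, theta - t * step, S_sc, want_info=True
            )
            if F_new <= F:
                break
            t *= 0.5
        else:
            break
        delta = F - F_new
        theta = theta - t * step
        F, grad, info, sigma = F_new, grad_new, info_new, sigma_new
        if delta < f_tol or np.linalg.norm(grad, np.inf) < g_tol:
            converged = True
    if not converged and np.linalg.norm(grad, np.inf) >= g_tol:
        res = optimize.minimize(
            lambda th: _grad_and_info(ram, th, S_sc, want_info=False)[:2],
            theta,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": g_tol / 10},
        )
        theta = res.x
        F, grad, info, sigma = _grad_and_info(ram, theta, S_sc, want_info=True)
        n_iter += res.nit
        converged = np.linalg.norm(grad, np.inf) < max(g_tol, 1e-6)
    if not converged:
        raise ConvergenceError(
            f"no convergence after {n_iter} iterations "
            f"(gradient infinity-norm {np.linalg.norm(grad, np.inf):.3e})"
        )

    n = moments.n
    se_scaled = _standard_errors(info, n)
    theta_orig = theta * scale
    se_orig = se_scaled * scale
    sigma_orig = sigma * np.outer(d, d)

    labels = ram.labels()
    estimates = dict(zip(labels, theta_orig))
    ses = dict(zip(labels, se_orig))
    crs = {
        lab: (estimates[lab] / ses[lab]) if ses[lab] > 0 else float("nan") for lab in labels
    }
    heywood = has_negative_variance(ram, theta_orig)
    if heywood:
        warnings.warn("improper solution: negative variance estimate (Heywood case)")

    result = FitResult(
        model=model,
        moments=moments,
        ram=ram,
        theta=theta_orig,
        estimates=estimates,
        standard_errors=ses,
        critical_ratios=crs,
        standardized={},
        f_min=float(F),
        chi_square=float((n - 1) * F),
        df=ram.df,
        implied_sigma=sigma_orig,
        converged=converged,
        n_iterations=n_iter,
        gradient_norm=float(np.linalg.norm(grad, np.inf)),
        heywood=heywood,
    )
    result.standardized = standardize(result)
    return result


def has_negative_variance(ram: RAMMatrices, theta: np.ndarray) -> bool:
    """True when any variance entry of the parameter vector is negative
    (an improper, "Heywood", solution)."""
    return any(
        theta[k] < 0
        for k, (mat, i, j, _) in enumerate(ram.free_map)
        if mat == "S" and i == j
    )


def _standard_errors(info: np.ndarray, n: int) -> np.ndarray:
    """SEs from the expected information ``(n-1)/2 tr(...)``; ``info`` holds
    the 0.5*tr factor, so scale by (n-1)."""
    full = (n - 1) * info
    try:
        cov = np.linalg.inv(full)
        diag = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        diag = np.full(info.shape[0], np.nan)
    diag[diag < 0] = np.nan
    return np.sqrt(diag)


def standardize(fit: FitResult) -> dict[str, float]:
    """Standardised solution from the implied (not sample) covariance.

    Paths: ``beta = b * sd(source) / sd(target)``; covariances become
    correlations; variances are scaled by the implied variance of their
    variable (residuals thus report the unexplained variance proportion,
    exogenous variances standardise to 1).
    """
    if not fit.converged:
        raise ValueError("cannot standardise an unconverged fit")
    sd = np.sqrt(np.diag(fit.implied_sigma))
    if np.any(sd <= 0):
        bad = [v for v, s in zip(fit.model.variables, sd) if s <= 0]
        raise ZeroDivisionError(f"zero implied variance for {bad}")
    out: dict[str, float] = {}
    for k, (mat, i, j, lab) in enumerate(fit.ram.free_map):
        b = fit.theta[k]
        if mat == "A":
            out[lab] = b * sd[j] / sd[i]
        else:
            out[lab] = b / (sd[i] * sd[j])
    return out


class MLPathAnalysis(BaseEstimator):
    """Scikit-learn style estimator for ML path analysis.

    Parameters
    ----------
    model : PathModel
        The path diagram to fit.
    divisor : {"n", "n-1"}, default "n"
        Covariance divisor used when fitting from raw data ("n" is the ML
        convention).
    max_iter, f_tol, g_tol
        Passed to :func:`fit_ml`.

    Attributes (after ``fit``)
    --------------------------
    estimates_, standard_errors_, critical_ratios_, standardized_ : dict
        Per-parameter values keyed by label.
    chi_square_, df_, f_min_, p_value_ : float
        Overall fit statistics (``chi_square_ = (N-1) * F_min``).
    implied_covariance_ : ndarray
        Fitted covariance matrix in the model's variable order.
    result_ : FitResult
        The full result object.

    Examples
    --------
    >>> from gpresem import triticale_gpre_model, MLPathAnalysis
    >>> est = MLPathAnalysis(model=triticale_gpre_model())
    >>> # est.fit(df)  # df: rows = regenerants, columns = model variables
    """

    def __init__(self, model=None, divisor: str = "n", max_iter: int = 500,
                 f_tol: float = 1e-10, g_tol: float = 1e-8):
        self.model = model
        self.divisor = divisor
        self.max_iter = max_iter
        self.f_tol = f_tol
        self.g_tol = g_tol

    def _fit_result(self, moments: SampleMoments) -> "MLPathAnalysis":
        if self.model is None:
            raise ValueError("model must be set before fitting")
        res = fit_ml(self.model, moments, max_iter=self.max_iter,
                     f_tol=self.f_tol, g_tol=self.g_tol)
        self.result_ = res
        self.estimates_ = res.estimates
        self.standard_errors_ = res.standard_errors
        self.critical_ratios_ = res.critical_ratios
        self.standardized_ = res.standardized
        self.chi_square_ = res.chi_square
        self.df_ = res.df
        self.f_min_ = res.f_min
        self.p_value_ = res.p_value
        self.implied_covariance_ = res.implied_sigma
        self.n_iter_ = res.n_iterations
        self.converged_ = res.converged
        return self

    def fit(self, X, y=None):
        """Fit from a samples-by-variables table (DataFrame or array).

        Array input must follow the model's variable order; DataFrame
        columns are matched by name.
        """
        if isinstance(X, pd.DataFrame):
            X = X[list(self.model.variables)]
            moments = SampleMoments.from_data(X, divisor="n-1" if self.divisor == "n-1" else "n")
        else:
            moments = SampleMoments.from_data(
                np.asarray(X, dtype=float),
                variable_names=self.model.variables,
                divisor="n-1" if self.divisor == "n-1" else "n",
            )
        return self._fit_result(moments)

    def fit_moments(self, moments: SampleMoments):
        """Fit directly from a :class:`SampleMoments` object."""
        return self._fit_result(moments)

    def score(self, X=None, y=None) -> float:
        """Negative minimised discrepancy (higher is better)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        return -self.f_min_
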