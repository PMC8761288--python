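"""Conway-Maxwell-Poisson (CMP) distribution and regression.

The CMP distribution generalizes the Poisson with a dispersion exponent on
the factorial term:

    P(Y = k) = lambda^k / (k!)^nu / Z(lambda, nu),
    Z(lambda, nu) = sum_{j>=0} lambda^j / (j!)^nu,

``nu = 1`` recovers the Poisson; ``nu < 1`` is over-dispersed, ``nu > 1``
under-dispersed.  The regression model uses a log link for the rate,
``lambda_i = exp(x_i @ beta + offset_i)``, with a common dispersion
estimated on the log scale.  It is the imputation model for the number of
episodes a subject experienced before entering follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp
from statsmodels.base.model import GenericLikelihoodModel

__all__ = [
    "cmp_log_norm",
    "cmp_pmf",
    "cmp_sample",
    "cmp_fit",
    "CMPRegression",
    "CMPModel",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Raised when count data cannot identify the CMP regression."""


def _check_params(lam, nu) -> None:
    if np.any(np.asarray(lam) <= 0) or np.any(np.asarray(nu) <= 0):
        raise ValueError("CMP parameters lambda and nu must be positive")


def _truncation_point(log_lam: float, nu: float, tol: float) -> int:
    """Index beyond which the CMP series tail is below ``tol`` (relative).

    Terms decay faster than geometrically once j exceeds the mode
    lambda^(1/nu); walk in doubling blocks until the geometric tail bound
    ratio lam/(j+1)^nu certifies convergence.
    """
    mode = float(np.exp(log_lam / nu))
    j = max(32, int(np.ceil(mode + 10.0 * np.sqrt(mode + 1.0))))
    while True:
        # ratio of consecutive terms at j: lam / (j+1)^nu
        log_ratio = log_lam - nu * np.log(j + 1.0)
        if log_ratio < np.log(0.5):  # tail < 2 * term_j
            # term_j relative to the mode term bounds the relative tail
            log_term_j = j * log_lam - nu * gammaln(j + 1.0)
            log_term_mode = mode * log_lam - nu * gammaln(mode + 1.0)
            if log_term_j - log_term_mode < np.log(tol) - 1.0:
                return j
        j *= 2
        if j > 10_000_000:  # pragma: no cover
            raise RuntimeError("CMP series failed to converge")


def cmp_log_norm(lam: float, nu: float, tol: float = 1e-10) -> float:
    """Log normalizing constant ``log Z(lambda, nu)`` of the CMP pmf.

    The series is truncated once a geometric tail bound certifies a
    relative error below ``tol``.  When the series mode ``lam**(1/nu)``
    is too large to sum directly (> 1e6 terms) the saddlepoint
    approximation ``log Z ~ nu lam^{1/nu} - (nu-1)/(2 nu) log lam
    - (nu-1)/2 log(2 pi) - log(nu)/2`` is used instead; its relative
    error is O(lam^{-1/nu}) and thus negligible exactly in that regime.
    """
    _check_params(lam, nu)
    if tol <= 0:
        raise ValueError("tol must be positive")
    log_lam = float(np.log(lam))
    if np.exp(log_lam / nu) > 1e6:
        return float(
            nu * np.exp(log_lam / nu)
            - (nu - 1.0) / (2.0 * nu) * log_lam
            - (nu - 1.0) / 2.0 * np.log(2.0 * np.pi)
            - 0.5 * np.log(nu)
        )
    J = _truncation_point(log_lam, nu, tol)
    j = np.arange(J + 1, dtype=float)
    return float(logsumexp(j * log_lam - nu * gammaln(j + 1.0)))


def _log_norm_vector(log_lam: np.ndarray, nu: float, tol: float = 1e-12) -> np.ndarray:
    """Vectorized log Z over an array of log-rates (shared dispersion)."""
    J = _truncation_point(float(np.max(log_lam)), nu, tol)
    j = np.arange(J + 1, dtype=float)
    terms = np.multiply.outer(np.asarray(log_lam, dtype=float), j)
    terms -= nu * gammaln(j + 1.0)
    return logsumexp(terms, axis=-1)


def cmp_pmf(k, lam: float, nu: float, tol: float = 1e-10):
    """CMP probability mass ``P(Y = k)``; ``k`` may be an integer array."""
    _check_params(lam, nu)
    k = np.asarray(k)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
        raise ValueError("k must be a non-negative integer")
    log_z = cmp_log_norm(lam, nu, tol)
    kf = k.astype(float)
    out = np.exp(kf * np.log(lam) - nu * gammaln(kf + 1.0) - log_z)
    return out if out.shape else float(out)


def cmp_sample(lam, nu: float, rng: np.random.Generator, size: int | None = None,
               max_support: int | None = None):
    """Draw CMP variates by inversion of the truncated cdf.

    ``lam`` may be a scalar (with ``size`` draws) or an array of per-draw
    rates sharing the dispersion ``nu``.  ``max_support`` hard-truncates
    the support (and renormalizes); useful when parameters drawn from an
    estimation posterior can wander into regions where the series mode is
    astronomically large (or, for nu -> 0 with lam >= 1, divergent).
    """
    lam = np.asarray(lam, dtype=float)
    _check_params(lam, nu)
    scalar_lam = lam.ndim == 0
    if scalar_lam:
        lam = lam[None]
    log_lam = np.log(lam)
    if max_support is not None:
        J = int(max_support)
    else:
        J = _truncation_point(float(np.max(log_lam)), nu, 1e-12)
    j = np.arange(J + 1, dtype=float)
    log_terms = np.multiply.outer(log_lam, j) - nu * gammaln(j + 1.0)
    log_cum = np.logaddexp.accumulate(log_terms, axis=-1)
    cdf = np.exp(log_cum - log_cum[..., -1:])
    if scalar_lam:
        u = rng.uniform(size=size if size is not None else ())
        draws = np.searchsorted(cdf[0], np.atleast_1d(u), side="right")
        return int(draws[0]) if size is None else draws.astype(np.int64)
    if size is not None and size != len(lam):
        raise ValueError("size must match the length of the rate array")
    u = rng.uniform(size=len(lam))
    draws = (cdf < u[:, None]).sum(axis=1)
    return draws.astype(np.int64)


class CMPRegression(GenericLikelihoodModel):
    """CMP regression with log link and common log-scale dispersion.

    Parameter vector: ``(beta_1, ..., beta_p, log_nu)``.  The likelihood
    is maximized quasi-Newton (BFGS) warm-started at the Poisson GLM
    solution with ``log_nu = 0``; the covariance of the full parameter
    vector (dispersion included) comes from the inverse numerical Hessian
    at the optimum.
    """

    def __init__(self, endog, exog, offset=None, fixed_nu=None, **kwargs):
        endog = np.asarray(endog)
        if np.any(endog < 0):
            raise ValueError("counts must be non-negative")
        if np.all(endog == 0):
            raise DegenerateDataError("all counts are zero; CMP rate is not identified")
        self.offset = np.zeros(len(endog)) if offset is None else np.asarray(offset, float)
        self.fixed_nu = fixed_nu
        super().__init__(endog, exog, **kwargs)
        if fixed_nu is None:
            # last parameter is the log-dispersion, not a slope
            self.k_extra = 1
            self.exog_names.append("log_nu")

    def loglike(self, params):
        if self.fixed_nu is not None:
            beta, log_nu = params, np.log(self.fixed_nu)
        else:
            beta, log_nu = params[:-1], params[-1]
        nu = np.exp(np.clip(log_nu, -10.0, 10.0))
        log_lam = np.clip(self.exog @ beta + self.offset, -500.0, 30.0)
        # retreat barrier: keep the optimizer out of the region where the
        # series mode lam^(1/nu) is unsummable (nu -> 0 with lam >= 1)
        if np.max(log_lam) / nu > np.log(1e7):
            return -1e12 * (1.0 + np.max(log_lam) / nu)
        y = self.endog
        ll = y * log_lam - nu * gammaln(y + 1.0) - _log_norm_vector(log_lam, nu)
        return float(np.sum(ll))

    def fit(self, start_params=None, maxiter=500, disp=0, **kwargs):
        if start_params is None:
            glm = sm.GLM(
                self.endog, self.exog, family=sm.families.Poisson(), offset=self.offset
            ).fit()
            start_params = glm.params if self.fixed_nu is not None \
                else np.r_[glm.params, 0.0]
        import warnings

        with warnings.catch_warnings():
            # statsmodels warns that df_resid ignores k_extra; inference
            # here uses the full-parameter covariance, not df_resid
            warnings.filterwarnings("ignore", message="df_resid differs")
            return super().fit(
                start_params=start_params, method="bfgs", maxiter=maxiter,
                disp=disp, **kwargs
            )


@dataclass
class CMPModel:
    """A fitted CMP regression, as consumed by the imputation engine.

    ``params`` stacks the rate coefficients and the log-dispersion;
    ``cov_params`` is the corresponding covariance (posterior-variance
    surrogate for the Bayesian imputation draws).
    """

    params: np.ndarray
    cov_params: np.ndarray
    converged: bool
    param_names: list[str]

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def log_dispersion(self) -> float:
        return float(self.params[-1])

    @property
    def dispersion(self) -> float:
        return float(np.exp(self.params[-1]))

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "converged": bool(self.converged),
            "param_names": list(self.param_names),
        }


def cmp_fit(counts, design, offset=None) -> CMPModel:
    """Fit the CMP regression of ``counts`` on ``design`` with an offset.

    Non-convergence is flagged on the result, not raised; degenerate data
    (all counts zero) raises :class:`DegenerateDataError`.
    """
    model = CMPRegression(counts, np.asarray(design, float), offset=offset)
    res = model.fit()
    cov = np.asarray(res.cov_params())
    converged = bool(res.mle_retvals.get("converged", False)) and np.all(np.isfinite(cov))
    if not np.all(np.isfinite(cov)):
        cov = np.zeros_like(cov)
    return CMPModel(
        params=np.asarray(res.params, dtype=float),
        cov_params=cov,
        converged=converged,
        param_names=list(model.exog_names),
    )
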