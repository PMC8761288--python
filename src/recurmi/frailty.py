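"""Stratified proportional-hazards models with shared gamma frailty.

Supports start-stop (counting-process) data with delayed entry, stratified
baseline hazards, Efron or Breslow handling of ties, and a shared
per-subject gamma frailty with mean 1 and variance theta.

Estimation follows the standard penalized-partial-likelihood / EM scheme:
for fixed theta, alternate Newton steps on beta (with log-frailties as
offsets) with the closed-form gamma update

    nu_i = (d_i + 1/theta) / (Lambda_i + 1/theta),

where d_i is the subject's event count and Lambda_i the accumulated
(frailty-free) cumulative hazard; theta is then profiled on the
observed-data marginal likelihood obtained by integrating the gamma
frailty out analytically.  Standard errors of beta come from the penalized
information with the frailty block absorbed via its (diagonal) Schur
complement, so the uncertainty in the estimated frailties propagates into
the reported SEs.

Model presets
-------------
``SPECIFIC_CP`` / ``SPECIFIC_GT``
    counting-process / gap-time layout, baseline stratified by the
    (possibly imputed) episode number crossed with prior-risk status,
    gamma frailty: the specific-hazard frailty models.
``COMMON``
    counting-process layout, baseline stratified by prior-risk status
    only (no event dependence), gamma frailty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import norm

from .simulate import covariate_columns

__all__ = [
    "ModelSpec",
    "FitResult",
    "CoxFrailtyModel",
    "fit_model",
    "partial_loglik",
    "wald_ci",
    "SPECIFIC_CP",
    "SPECIFIC_GT",
    "COMMON",
    "MODEL_PRESETS",
    "make_strata",
]

logger = logging.getLogger(__name__)

STRATA_RULES = ("episode_by_priorrisk", "priorrisk_only", "episode_only", "none")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one survival model.

    ``strata_rule`` decides the baseline-hazard strata: episode number
    crossed with prior-risk status (the specific-hazard proposal),
    prior-risk status only (common baseline per subpopulation), episode
    number only (classic PWP), or a single stratum.  ``episode_col``
    selects which episode index defines the strata ("episode" for the
    observed index, "stratum_episode" after imputation, "true_episode"
    for the oracle fits on simulated data).
    """

    layout: str = "counting_process"
    strata_rule: str = "episode_by_priorrisk"
    frailty: str = "gamma"
    theta: float | None = None  # None = profile-estimated
    ties: str = "efron"
    episode_col: str = "episode"
    k_max: int = 3

    def __post_init__(self) -> None:
        if self.layout not in ("counting_process", "gap_time"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.strata_rule not in STRATA_RULES:
            raise ValueError(f"unknown strata rule {self.strata_rule!r}")
        if self.frailty not in ("gamma", "none"):
            raise ValueError(f"unknown frailty {self.frailty!r}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {self.ties!r}")


SPECIFIC_CP = ModelSpec("counting_process", "episode_by_priorrisk", "gamma")
SPECIFIC_GT = ModelSpec("gap_time", "episode_by_priorrisk", "gamma")
COMMON = ModelSpec("counting_process", "priorrisk_only", "gamma")

#: Named model presets accepted by the pipeline and the CLI.
MODEL_PRESETS: dict[str, ModelSpec] = {
    "specific-cp": SPECIFIC_CP,
    "specific-gt": SPECIFIC_GT,
    "common": COMMON,
    "conditional-cp": ModelSpec("counting_process", "episode_only", "gamma"),
    "conditional-gt": ModelSpec("gap_time", "episode_only", "gamma"),
    "shared": ModelSpec("counting_process", "none", "gamma"),
    # oracle fits on simulated data: stratify by the true episode number
    "known-cp": ModelSpec("counting_process", "episode_only", "gamma",
                          episode_col="true_episode"),
    "known-gt": ModelSpec("gap_time", "episode_only", "gamma",
                          episode_col="true_episode"),
}


def make_strata(df: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Stratum labels for each row of an episode table under ``spec``.

    Episode numbers are capped at ``k_max`` (the baseline hazard is taken
    constant from the k_max-th episode on).
    """
    if spec.strata_rule == "none":
        return pd.Series("all", index=df.index)
    parts = []
    if spec.strata_rule in ("episode_by_priorrisk", "episode_only"):
        if spec.episode_col not in df.columns:
            raise ValueError(f"column {spec.episode_col!r} required for strata")
        k = np.minimum(df[spec.episode_col].to_numpy(int), spec.k_max)
        parts.append(pd.Series([f"k{v}" for v in k], index=df.index))
    if spec.strata_rule in ("episode_by_priorrisk", "priorrisk_only"):
        parts.append(pd.Series([f"r{int(v)}" for v in df["risk_before"]], index=df.index))
    out = parts[0]
    for p in parts[1:]:
        out = out + ":" + p
    return out


class _CoxEngine:
    """Vectorized stratified Cox machinery on preprocessed start-stop data.

    All sort orders, risk-set search positions and tied-event groupings
    are computed once; likelihood/score/information evaluations for new
    linear predictors are then O(n log-free) array passes, which keeps the
    frailty EM and theta profiling cheap enough for simulation studies.
    """

    def __init__(self, start, stop, status, X, subject_idx, strata_codes, ties="efron"):
        self.start = np.asarray(start, float)
        self.stop = np.asarray(stop, float)
        self.status = np.asarray(status, int)
        self.X = np.asarray(X, float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.subj = np.asarray(subject_idx, int)
        self.n_subjects = int(self.subj.max()) + 1 if len(self.subj) else 0
        self.p = self.X.shape[1]
        self.ties = ties
        self.d_subject = np.bincount(self.subj, weights=self.status,
                                     minlength=self.n_subjects)
        self.n_events = int(self.status.sum())

        self.strata = []
        for s in np.unique(strata_codes):
            rows = np.flatnonzero(strata_codes == s)
            st = self._prep_stratum(rows)
            if st is not None:
                self.strata.append(st)

    def _prep_stratum(self, rows):
        start, stop, status = self.start[rows], self.stop[rows], self.status[rows]
        ev = rows[status == 1]
        if len(ev) == 0:
            return None
        ev_times_all = self.stop[ev]
        order = np.argsort(ev_times_all, kind="stable")
        ev_sorted = ev[order]
        times, first_idx, counts = np.unique(ev_times_all[order],
                                             return_index=True, return_counts=True)
        o_stop = rows[np.argsort(stop, kind="stable")]
        o_start = rows[np.argsort(start, kind="stable")]
        st = {
            "rows": rows,
            "o_stop": o_stop,                  # rows sorted by stop asc
            "o_start": o_start,                # rows sorted by start asc
            "ev_sorted": ev_sorted,            # event rows sorted by time
            "grp_first": first_idx,            # tied-group boundaries in ev_sorted
            "d": counts.astype(float),         # tied-event counts per time
            "times": times,
            # position of each event time among sorted stops/starts:
            # suffix sums from these indices give sums over {stop >= t} / {start >= t}
            "pos_stop": np.searchsorted(self.stop[o_stop], times, side="left"),
            "pos_start": np.searchsorted(self.start[o_start], times, side="left"),
            # per-row span of event times in (start, stop]: prefix-sum indices
            "row_hi": np.searchsorted(times, stop, side="right"),
            "row_lo": np.searchsorted(times, start, side="right"),
            "max_d": int(counts.max()),
        }
        return st

    @staticmethod
    def _suffix(values):
        """Suffix sums with a trailing zero: out[i] = sum(values[i:])."""
        out = np.zeros((len(values) + 1,) + values.shape[1:])
        out[:-1] = np.cumsum(values[::-1], axis=0)[::-1]
        return out

    def risk_sums(self, st, W):
        """Sums of the columns of W over the risk set of each event time."""
        suf_stop = self._suffix(W[st["o_stop"]])
        suf_start = self._suffix(W[st["o_start"]])
        return suf_stop[st["pos_stop"]] - suf_start[st["pos_start"]]

    def loglik(self, eta, derivatives=True):
        """Partial log-likelihood; optionally score & information for beta.

        Returns (ll, grad, info) with grad/info None when derivatives is
        False.  ``eta`` is the full linear predictor (covariates plus any
        frailty offsets) per row.
        """
        w = np.exp(eta)
        p = self.p
        # stacked columns: w, w*x_a, w*x_a*x_b (upper triangle)
        cols = [w] + [w * self.X[:, a] for a in range(p)]
        iu = [(a, b) for a in range(p) for b in range(a, p)]
        if derivatives:
            cols += [w * self.X[:, a] * self.X[:, b] for a, b in iu]
        W = np.column_stack(cols)

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for st in self.strata:
            S = self.risk_sums(st, W)
            S0 = S[:, 0]
            S1 = S[:, 1:1 + p]
            ev = st["ev_sorted"]
            ll += float(np.sum(eta[ev]))
            d = st["d"]
            if self.ties == "breslow" or st["max_d"] == 1:
                ll -= float(np.sum(d * np.log(S0)))
                if derivatives:
                    S2 = self._unpack(S[:, 1 + p:], iu, p)
                    grad += self.X[ev].sum(axis=0) - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
                    sbar = S1 / S0[:, None]
                    info += np.einsum("g,gab->ab", d, S2 / S0[:, None, None]
                                      - sbar[:, :, None] * sbar[:, None, :])
            else:
                ll_, g_, i_ = self._efron_terms(st, W, S, iu, derivatives)
                ll += ll_
                if derivatives:
                    grad += self.X[ev].sum(axis=0) + g_
                    info += i_
        if not derivatives:
            return ll, None, None
        return ll, grad, info

    @staticmethod
    def _unpack(flat, iu, p):
        out = np.empty((flat.shape[0], p, p))
        for i, (a, b) in enumerate(iu):
            out[:, a, b] = flat[:, i]
            out[:, b, a] = flat[:, i]
        return out

    def _efron_terms(self, st, W, S, iu, derivatives):
        """Efron tie-corrected contributions for one stratum."""
        p = self.p
        d = st["d"]
        G = len(d)
        # tied-group sums of the W columns over event rows
        tied = np.add.reduceat(W[st["ev_sorted"]], st["grp_first"], axis=0)
        s0t, s1t = tied[:, 0], tied[:, 1:1 + p]
        S0, S1 = S[:, 0], S[:, 1:1 + p]
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        if derivatives:
            S2 = self._unpack(S[:, 1 + p:], iu, p)
            s2t = self._unpack(tied[:, 1 + p:], iu, p)
        for l in range(st["max_d"]):
            m = d > l
            f = (l / d[m])[:, None]
            D0 = S0[m] - f[:, 0] * s0t[m]
            ll -= float(np.sum(np.log(D0)))
            if derivatives:
                D1 = S1[m] - f * s1t[m]
                D2 = S2[m] - f[:, :, None] * s2t[m]
                bar = D1 / D0[:, None]
                grad -= bar.sum(axis=0)
                info += np.einsum("gab->ab", D2 / D0[:, None, None]
                                  - bar[:, :, None] * bar[:, None, :])
        return ll, grad, info

    def cumhaz_spans(self, eta):
        """Per-row cumulative-hazard spans and risk-set helper spans.

        Returns (span1, span2, span3) where for each row
        span1 = sum_{t in (start, stop]} dLambda0(t),
        span2 = sum d_t / S0(t)^2,  span3 = sum d_t S1(t) / S0(t)^2
        (Breslow forms; used for frailty updates and the penalized-
        information correction).
        """
        w = np.exp(eta)
        p = self.p
        W = np.column_stack([w] + [w * self.X[:, a] for a in range(p)])
        n = len(eta)
        span1 = np.zeros(n)
        span2 = np.zeros(n)
        span3 = np.zeros((n, p))
        for st in self.strata:
            S = self.risk_sums(st, W)
            S0, S1 = S[:, 0], S[:, 1:1 + p]
            d = st["d"]
            g1 = np.concatenate([[0.0], np.cumsum(d / S0)])
            g2 = np.concatenate([[0.0], np.cumsum(d / S0 ** 2)])
            g3 = np.concatenate([np.zeros((1, p)),
                                 np.cumsum(d[:, None] * S1 / S0[:, None] ** 2, axis=0)])
            rows, hi, lo = st["rows"], st["row_hi"], st["row_lo"]
            span1[rows] = g1[hi] - g1[lo]
            span2[rows] = g2[hi] - g2[lo]
            span3[rows] = g3[hi] - g3[lo]
        return span1, span2, span3

    def newton_beta(self, beta, omega_rows, tol=1e-9, max_iter=25):
        """Maximize the partial likelihood over beta with fixed offsets."""
        beta = beta.copy()
        ll, grad, info = self.loglik(self.X @ beta + omega_rows)
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(info + 1e-12 * np.eye(self.p), grad)
            except np.linalg.LinAlgError:  # pragma: no cover
                step = grad
            # step-halving safeguard
            for _ in range(30):
                cand = beta + step
                ll_new, g_new, i_new = self.loglik(self.X @ cand + omega_rows)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            moved = abs(ll_new - ll)
            beta, ll, grad, info = cand, ll_new, g_new, i_new
            if moved < tol and float(np.abs(grad).max()) < 1e-6:
                break
        return beta, ll, grad, info


@dataclass
class FitResult:
    """Results of one frailty PH fit.

    ``params``/``bse`` are the covariate log-hazard-ratios and their
    standard errors (penalized information, frailty block absorbed);
    ``theta`` is the estimated frailty variance and ``frailty`` the
    per-subject empirical Bayes frailties (mean ~ 1).  ``loglik`` is the
    observed-data marginal log-likelihood at the optimum.
    """

    params: pd.Series
    bse: pd.Series
    theta: float
    frailty: pd.Series
    loglik: float
    converged: bool
    n_subjects: int
    n_events: int
    spec: ModelSpec | None = None
    cov_params: np.ndarray | None = field(default=None, repr=False)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        return wald_ci(self, level)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Stratified PH frailty model",
            f"  subjects: {self.n_subjects}   events: {self.n_events}",
            f"  frailty variance theta: {self.theta:.4f}"
            f"   marginal loglik: {self.loglik:.3f}",
            f"  converged: {self.converged}",
            "",
            f"{'':>8}  {'coef':>9} {'se':>8} {'z':>7} {'p':>8} "
            f"{'[0.025':>8} {'0.975]':>8}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>8}  {self.params[name]:>9.4f} {self.bse[name]:>8.4f} "
                f"{self.zvalues[name]:>7.2f} {self.pvalues[name]:>8.4f} "
                f"{ci.loc[name, 'lower']:>8.4f} {ci.loc[name, 'upper']:>8.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
                "theta": self.theta,
                "converged": self.converged,
            }
        )


def wald_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Normal-theory confidence intervals ``beta +- z * SE``."""
    z = norm.ppf(0.5 + level / 2.0)
    lo = fit.params - z * fit.bse
    hi = fit.params + z * fit.bse
    return pd.DataFrame({"lower": lo, "upper": hi})


class CoxFrailtyModel:
    """Stratified PH model with optional shared gamma frailty.

    Statsmodels-style: construct from an episode table (start-stop rows)
    and a :class:`ModelSpec`; :meth:`fit` returns a :class:`FitResult`.

    The table must carry id, start, stop, status, covariate columns
    x1..xp, and the columns the strata rule needs (episode / risk_before).
    Strata that contain no events are dropped with a logged warning (they
    contribute nothing to the partial likelihood).
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec = SPECIFIC_CP,
                 covariates: list[str] | None = None):
        expected = spec.layout
        layout = table.attrs.get("layout")
        if layout is not None and layout != expected:
            raise ValueError(
                f"model expects {expected} layout but the table is {layout}"
            )
        self.spec = spec
        self.covariates = covariates or covariate_columns(table)
        if not self.covariates:
            raise ValueError("no covariate columns found (expected x1, x2, ...)")
        df = table
        if (df["stop"].to_numpy() <= df["start"].to_numpy()).any():
            raise ValueError("every row must satisfy start < stop")
        if int(df["status"].sum()) == 0:
            raise ValueError("no events in the data")

        strata = make_strata(df, spec)
        ev_per_stratum = df["status"].groupby(strata).sum()
        dead = ev_per_stratum.index[ev_per_stratum == 0]
        if len(dead):
            logger.warning("dropping event-free strata: %s", list(dead))
            keep = ~strata.isin(dead)
            df = df.loc[keep]
            strata = strata.loc[keep]

        self.table = df
        ids = df["id"].to_numpy()
        uniq, subj_idx = np.unique(ids, return_inverse=True)
        self.subject_ids = uniq
        codes = pd.factorize(strata)[0]
        self.engine = _CoxEngine(
            df["start"].to_numpy(), df["stop"].to_numpy(), df["status"].to_numpy(),
            df[self.covariates].to_numpy(), subj_idx, codes, ties=spec.ties,
        )

    # -- frailty machinery -------------------------------------------------

    def _em_fixed_theta(self, theta, beta, log_nu, inner_tol=1e-6, max_iter=50):
        """EM at fixed theta; returns updated (beta, log_nu, spans, ll_cox)."""
        eng = self.engine
        for _ in range(max_iter):
            omega_rows = log_nu[eng.subj]
            beta, ll, _, _ = eng.newton_beta(beta, omega_rows)
            eta = eng.X @ beta + omega_rows
            span1, _, _ = eng.cumhaz_spans(eta)
            lam_free = np.exp(eng.X @ beta) * span1  # frailty-free row cumhaz
            Lam = np.bincount(eng.subj, weights=lam_free, minlength=eng.n_subjects)
            new_nu = (eng.d_subject + 1.0 / theta) / (Lam + 1.0 / theta)
            new_log = np.log(new_nu)
            delta = float(np.abs(new_log - log_nu).max())
            log_nu = new_log
            if delta < inner_tol:
                break
        return beta, log_nu, Lam

    def _marginal_loglik(self, theta, beta, log_nu, Lam):
        """Observed-data marginal log-likelihood with the frailty integrated out."""
        eng = self.engine
        d = eng.d_subject
        pen = np.sum(
            gammaln(d + 1.0 / theta) - gammaln(1.0 / theta)
            + d * np.log(theta) - (d + 1.0 / theta) * np.log1p(theta * Lam)
        )
        # baseline * covariate part: Breslow hazard mass at event times
        eta = eng.X @ beta + log_nu[eng.subj]
        w = np.exp(eta)
        base = 0.0
        for st in self.engine.strata:
            S0 = self.engine.risk_sums(st, w[:, None])[:, 0]
            d_g = st["d"]
            base += float(np.sum(d_g * np.log(d_g / S0)))
            base += float(np.sum((self.engine.X @ beta)[st["ev_sorted"]]))
        return float(pen + base)

    def _cox_loglik_nofrailty(self):
        eng = self.engine
        beta = np.zeros(eng.p)
        beta, ll, grad, info = eng.newton_beta(beta, np.zeros(len(eng.X)))
        return beta, ll, info

    def _beta_covariance(self, beta, log_nu, theta):
        """Penalized information with the frailty block Schur-complemented.

        The omega-omega block is taken diagonal (the sparse approximation
        used by standard frailty software); with theta = 0 the plain
        inverse information is returned.
        """
        eng = self.engine
        omega_rows = log_nu[eng.subj]
        eta = eng.X @ beta + omega_rows
        _, _, info = eng.loglik(eta)
        if theta <= 0:
            return np.linalg.inv(info)
        w = np.exp(eta)
        span1, span2, span3 = eng.cumhaz_spans(eta)
        nu = np.exp(log_nu)
        # I_omega_omega diagonal: sum_t d w_i/S0 - sum_t d w_i^2/S0^2 + nu/theta
        lam_w = np.bincount(eng.subj, weights=w * span1, minlength=eng.n_subjects)
        corr = np.bincount(eng.subj, weights=w ** 2 * span2, minlength=eng.n_subjects)
        D = lam_w - corr + nu / theta
        # I_beta_omega columns per subject
        B = np.zeros((eng.p, eng.n_subjects))
        for a in range(eng.p):
            col = w * (eng.X[:, a] * span1 - span3[:, a])
            B[a] = np.bincount(eng.subj, weights=col, minlength=eng.n_subjects)
        D = np.maximum(D, 1e-10)
        info_adj = info - (B / D) @ B.T
        cov = np.linalg.inv(info_adj)
        if np.any(np.diag(cov) <= 0):
            # the diagonal omega-block approximation can over-subtract for
            # extreme theta; fall back to the unadjusted information
            return np.linalg.inv(info)
        return cov

    # -- public fitting API ------------------------------------------------

    def fit(self, theta_max: float = 8.0, outer_tol: float = 0.02) -> FitResult:
        """Fit the model; profile the frailty variance unless fixed.

        ``outer_tol`` is the absolute tolerance on log-theta in the outer
        profile search; the default locates theta to ~2%, ample relative
        to its sampling noise.
        """
        eng = self.engine
        spec = self.spec
        names = list(self.covariates)

        if spec.frailty == "none" or (spec.theta is not None and spec.theta == 0.0):
            beta0, log_nu0, ll0 = self._plain_cox()
            return self._finish(beta0, log_nu0, theta=0.0, loglik=ll0)

        state = {"beta": np.zeros(eng.p), "log_nu": np.zeros(eng.n_subjects)}

        def profile(log_theta):
            theta = float(np.exp(log_theta))
            beta, log_nu, Lam = self._em_fixed_theta(theta, state["beta"], state["log_nu"])
            state["beta"], state["log_nu"] = beta, log_nu
            return -self._marginal_loglik(theta, beta, log_nu, Lam), (beta, log_nu, Lam)

        if spec.theta is not None:
            theta = float(spec.theta)
            nll, (beta, log_nu, Lam) = profile(np.log(theta))
            return self._finish(beta, log_nu, theta=theta, loglik=-nll)

        lo, hi = np.log(1e-3), np.log(theta_max)
        res = optimize.minimize_scalar(
            lambda u: profile(u)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": outer_tol, "maxiter": 40},
        )
        theta = float(np.exp(res.x))
        nll, (beta, log_nu, Lam) = profile(res.x)
        # boundary check: does the no-frailty limit do at least as well?
        nll0, _ = profile(np.log(1e-4))
        if theta <= 2e-3 or nll0 <= nll + 1e-8:
            beta0, log_nu0, ll0 = self._plain_cox()
            return self._finish(beta0, log_nu0, theta=0.0, loglik=ll0)
        return self._finish(beta, log_nu, theta=theta, loglik=-nll,
                            converged=bool(res.success))

    def _plain_cox(self):
        beta, ll, info = self._cox_loglik_nofrailty()
        # marginal loglik at theta -> 0 on the same scale as the frailty fits
        log_nu = np.zeros(self.engine.n_subjects)
        span1, _, _ = self.engine.cumhaz_spans(self.engine.X @ beta)
        Lam = np.bincount(self.engine.subj,
                          weights=np.exp(self.engine.X @ beta) * span1,
                          minlength=self.engine.n_subjects)
        ll_m = self._marginal_loglik(1e-8, beta, log_nu, Lam)
        return beta, log_nu, ll_m

    def _finish(self, beta, log_nu, theta, loglik, converged=True):
        cov = self._beta_covariance(beta, log_nu, theta)
        bse = np.sqrt(np.diag(cov))
        names = list(self.covariates)
        return FitResult(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            theta=float(theta),
            frailty=pd.Series(np.exp(log_nu), index=self.subject_ids),
            loglik=float(loglik),
            converged=bool(converged),
            n_subjects=self.engine.n_subjects,
            n_events=self.engine.n_events,
            spec=self.spec,
            cov_params=cov,
        )


def fit_model(table: pd.DataFrame, spec: ModelSpec | str,
              covariates: list[str] | None = None) -> FitResult:
    """Fit a preset or explicit :class:`ModelSpec` to an episode table."""
    if isinstance(spec, str):
        try:
            spec = MODEL_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown model {spec!r}; options: {sorted(MODEL_PRESETS)}"
            ) from None
    return CoxFrailtyModel(table, spec, covariates=covariates).fit()


def partial_loglik(table: pd.DataFrame, beta, frailty_offsets=None,
                   spec: ModelSpec | None = None,
                   covariates: list[str] | None = None) -> float:
    """Stratified partial log-likelihood at ``beta`` with given frailty offsets.

    ``frailty_offsets`` maps subject id -> log-frailty (defaults to 0).
    A row enters the risk set of an event at time t in its stratum iff
    start < t <= stop; ties are handled per ``spec.ties`` (Efron default).
    """
    if spec is None:
        rule = "episode_only" if "episode" in table.columns else "none"
        spec = ModelSpec(layout=table.attrs.get("layout", "counting_process"),
                         strata_rule=rule, frailty="none")
    model = CoxFrailtyModel(table, spec, covariates=covariates)
    beta = np.atleast_1d(np.asarray(beta, float))
    omega = np.zeros(model.engine.n_subjects)
    if frailty_offsets is not None:
        for j, sid in enumerate(model.subject_ids):
            omega[j] = frailty_offsets.get(sid, 0.0)
    eta = model.engine.X @ beta + omega[model.engine.subj]
    ll, _, _ = model.engine.loglik(eta, derivatives=False)
    return float(ll)
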