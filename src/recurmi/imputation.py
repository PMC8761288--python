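"""Multiple imputation of the unknown number of prior episodes.

For subjects at risk before follow-up starts, the number of episodes they
experienced before t = 0 is unknown (left-censored episode history).  It
is multiply imputed with a three-step Bayesian procedure:

1. fit a CMP regression of the observed in-study event count on the
   analysis covariates with log observed follow-up time as offset, and
   take the estimates ``beta_hat`` with covariance ``V(beta_hat)`` as a
   posterior summary;
2. draw perturbed parameters ``beta* ~ N(beta_hat, V(beta_hat))`` (the
   log-dispersion is part of the drawn vector, so estimation uncertainty
   in the dispersion propagates too);
3. draw each prior-risk subject's prior count from the CMP distribution
   with rate ``exp(x_i @ beta* + log(prior time at risk))``.

Repeating steps 2-3 m times (default 5) yields m completed cohorts whose
fits are later pooled by Rubin's rules.  Observed intervals, covariates
and event statuses are never touched: only the latent count, and hence
the episode-stratum labels, differ between imputations.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compoisson import CMPModel, cmp_fit, cmp_sample
from .simulate import SubjectRecord, build_risk_intervals

__all__ = [
    "ImputationConfig",
    "ImputedCohort",
    "fit_imputation_model",
    "draw_parameters",
    "impute_cohort",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the multiple-imputation step.

    ``m`` completed data sets are generated (m >= 2; 5 by default,
    following the usual small-m advice); ``k_max`` caps the episode
    number used in the stratum labels (the baseline hazard is treated as
    constant from episode ``k_max`` on).
    """

    m: int = 5
    seed: int = 0
    k_max: int = 3

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("at least 2 imputations are required")


@dataclass
class ImputedCohort:
    """m completed copies of a cohort differing only in imputed k0.

    ``k0_draws`` has one row per subject and one column per imputation;
    rows of non-prior-risk subjects are identically zero.
    """

    subjects: list[SubjectRecord]
    k0_draws: np.ndarray  # (n_subjects, m)
    model: CMPModel
    config: ImputationConfig

    @property
    def m(self) -> int:
        return self.k0_draws.shape[1]

    def cohort(self, j: int) -> list[SubjectRecord]:
        """The j-th completed cohort (0-based), with imputed ``k0``."""
        out = []
        for s, k0 in zip(self.subjects, self.k0_draws[:, j]):
            c = copy.copy(s)
            c.k0 = int(k0)
            out.append(c)
        return out

    def tables(self, layout: str):
        """Yield the m completed episode tables in the given layout.

        Each table carries a ``stratum_episode`` column,
        ``min(k0 + observed episode index, k_max)``, which the
        specific-hazard models cross with prior-risk status.
        """
        for j in range(self.m):
            df = build_risk_intervals(self.cohort(j), layout)
            df["stratum_episode"] = np.minimum(
                df["true_episode"].to_numpy(int), self.config.k_max
            )
            df.attrs["imputation"] = j
            yield df

    def to_frame(self, layout: str) -> pd.DataFrame:
        """All m completed tables stacked with an ``imputation`` column."""
        frames = []
        for j, df in enumerate(self.tables(layout)):
            df = df.copy()
            df.insert(0, "imputation", j)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out.attrs["layout"] = layout
        return out


def _design(subjects: list[SubjectRecord]) -> np.ndarray:
    X = np.array([s.covariates for s in subjects], dtype=float)
    return np.column_stack([np.ones(len(subjects)), X])


def fit_imputation_model(subjects: list[SubjectRecord]) -> CMPModel:
    """Step 1: CMP regression of observed event counts on the covariates.

    The response is each subject's in-study event count with log observed
    time at risk as offset, so the fitted coefficients are log event-rate
    effects transferable to the (pre-study) exposure window.
    """
    if not subjects:
        raise ValueError("empty cohort")
    counts = np.array([s.n_events for s in subjects])
    times = np.array([s.observed_time for s in subjects], dtype=float)
    usable = times > 0
    if not usable.all():  # pragma: no cover - simulator never emits these
        warnings.warn("dropping subjects with zero observed time from imputation fit")
    counts, times = counts[usable], times[usable]
    X = _design(subjects)[usable]
    return cmp_fit(counts, X, offset=np.log(times))


def draw_parameters(model: CMPModel, rng: np.random.Generator) -> np.ndarray:
    """Step 2: one draw ``beta* ~ N(beta_hat, V(beta_hat))``.

    A non-positive-semidefinite covariance (numerical artifact of the
    inverse Hessian) is repaired by flooring its eigenvalues at zero,
    with a warning.
    """
    cov = np.asarray(model.cov_params, float)
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        warnings.warn("imputation-model covariance repaired by eigenvalue flooring")
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal(len(evals))
    return model.params + evecs @ (np.sqrt(evals) * z)


def impute_cohort(
    subjects: list[SubjectRecord],
    model: CMPModel,
    cfg: ImputationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ImputedCohort:
    """Step 3, m times: draw prior counts for the prior-risk subjects.

    For each imputation a fresh parameter draw ``beta*`` is taken and
    each prior-risk subject's ``k0`` is sampled from
    ``CMP(exp(x_i beta* + log prior_time), nu*)``.  Subjects not at prior
    risk keep ``k0 = 0`` in every copy.
    """
    cfg = cfg or ImputationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(subjects)
    draws = np.zeros((n, cfg.m), dtype=int)
    prior_idx = [i for i, s in enumerate(subjects) if s.prior_risk]
    if prior_idx:
        Xp = _design([subjects[i] for i in prior_idx])
        log_t = np.log(np.array([subjects[i].prior_time for i in prior_idx]))
        for j in range(cfg.m):
            star = draw_parameters(model, rng)
            beta_star, log_nu_star = star[:-1], star[-1]
            nu_star = float(np.exp(np.clip(log_nu_star, -10.0, 10.0)))
            lam = np.exp(np.clip(Xp @ beta_star + log_t, -500.0, 25.0))
            # support cap: only min(k0 + episode, k_max) ever enters the
            # strata, so truncating extreme posterior draws is inert
            draws[prior_idx, j] = cmp_sample(lam, nu_star, rng, max_support=1000)
    return ImputedCohort(subjects=subjects, k0_draws=draws, model=model,
                         config=cfg)
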