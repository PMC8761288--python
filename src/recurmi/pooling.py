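"""Rubin's rules for combining fits across multiply imputed data sets.

Point estimates are averaged; the total variance adds the within-
imputation variance W (mean squared SE) and the between-imputation
variance B inflated by (1 + 1/m).  Degrees of freedom use the
Barnard-Rubin small-sample formula, appropriate for the modest cohort
sizes (n >= 250) this package targets; confidence intervals and Wald
tests use the t distribution with those df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .frailty import FitResult

__all__ = ["PooledResult", "rubin_pool"]


@dataclass
class PooledResult:
    """Pooled inference over m imputation-specific fits."""

    params: pd.Series
    within: pd.Series
    between: pd.Series
    total: pd.Series
    df: pd.Series
    m: int
    theta_mean: float
    converged: bool

    @property
    def bse(self) -> pd.Series:
        return np.sqrt(self.total)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * t_dist.sf(np.abs(self.tvalues), self.df), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        q = t_dist.ppf(0.5 + level / 2.0, self.df)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Rubin-pooled inference over {self.m} imputations",
            f"  mean frailty variance theta: {self.theta_mean:.4f}",
            f"  all fits converged: {self.converged}",
            "",
            f"{'':>8}  {'coef':>9} {'se':>8} {'t':>7} {'df':>8} {'p':>8} "
            f"{'[0.025':>8} {'0.975]':>8}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>8}  {self.params[name]:>9.4f} {self.bse[name]:>8.4f} "
                f"{self.tvalues[name]:>7.2f} {self.df[name]:>8.1f} "
                f"{self.pvalues[name]:>8.4f} "
                f"{ci.loc[name, 'lower']:>8.4f} {ci.loc[name, 'upper']:>8.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "W": self.within,
                "B": self.between,
                "df": self.df,
                "p": self.pvalues,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
            }
        )


def rubin_pool(fits: list[FitResult], df_com: float | None = None) -> PooledResult:
    """Combine m >= 2 fits by Rubin's rules.

    ``df_com`` is the complete-data degrees of freedom entering the
    Barnard-Rubin adjustment; it defaults to (number of events - number
    of coefficients) of the first fit, the effective sample size of a
    partial-likelihood analysis.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("pooling requires at least 2 fits")
    est = pd.DataFrame([f.params for f in fits])
    se2 = pd.DataFrame([f.bse**2 for f in fits])
    qbar = est.mean(axis=0)
    W = se2.mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B

    if df_com is None:
        df_com = max(fits[0].n_events - len(qbar), 1)
    # Barnard-Rubin small-sample degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * B / T  # fraction of missing information
        df_old = (m - 1) / np.maximum(r, 1e-300) ** 2
        df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - r)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    df = pd.Series(np.where(B > 0, df, df_com), index=qbar.index)

    return PooledResult(
        params=qbar,
        within=W,
        between=B,
        total=T,
        df=df,
        m=m,
        theta_mean=float(np.mean([f.theta for f in fits])),
        converged=all(f.converged for f in fits),
    )
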