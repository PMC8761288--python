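import numpy as np
import pandas as pd
import pytest

import recurmi as rm


@pytest.fixture(scope="session")
def pop1():
    return rm.get_population(1)


@pytest.fixture(scope="session")
def small_cohort(pop1):
    """Population-1 cohort with left censoring: 200 subjects, half at prior risk."""
    cfg = rm.CohortConfig.from_years(200, 5, 10, 0.5, seed=1234)
    return rm.simulate_cohort(pop1, cfg)


@pytest.fixture(scope="session")
def clean_cohort(pop1):
    """Fully observed cohort (no prior risk), everyone entering at t = 0."""
    cfg = rm.CohortConfig.from_years(400, 5, 0, 0.0, seed=99, entry_at_zero=True)
    return rm.simulate_cohort(pop1, cfg)


@pytest.fixture
def tiny_table():
    """Hand-built 6-row start-stop fixture with delayed entry and a tie."""
    df = pd.DataFrame(
        {
            "id": [1, 1, 2, 3, 4, 5],
            "start": [0.0, 2.0, 1.0, 0.0, 0.0, 3.0],
            "stop": [2.0, 5.0, 4.0, 4.0, 6.0, 7.0],
            "status": [1, 0, 1, 1, 0, 1],
            "episode": [1, 2, 1, 1, 1, 1],
            "x1": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )
    df.attrs["layout"] = "counting_process"
    return df


def brute_force_partial_loglik(df, beta, offsets=None, ties="efron",
                               strata_col=None):
    """Risk-set enumeration oracle for the stratified partial likelihood.

    Pure-python loops over event times; supports delayed entry, frailty
    offsets per id and Efron/Breslow ties.  Deliberately independent of
    the package's vectorized engine.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    offsets = offsets or {}
    eta = df[xcols].to_numpy() @ beta + np.array(
        [offsets.get(i, 0.0) for i in df["id"]]
    )
    w = np.exp(eta)
    strata = df[strata_col] if strata_col else pd.Series("all", index=df.index)
    ll = 0.0
    for _, sub in df.groupby(strata, sort=False):
        for t in sorted(sub.loc[sub["status"] == 1, "stop"].unique()):
            ev = sub[(sub["status"] == 1) & (sub["stop"] == t)]
            risk = sub[(sub["start"] < t) & (t <= sub["stop"])]
            d = len(ev)
            s0 = w[ev.index].sum()
            ll += eta[ev.index].sum()
            for el in range(d):
                frac = el / d if ties == "efron" else 0.0
                ll -= np.log(w[risk.index].sum() - frac * s0)
    return ll
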