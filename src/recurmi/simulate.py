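"""Cohort simulator and start-stop risk-interval construction.

Subjects are followed over a study window [0, F].  A configurable fraction
was already at risk before t = 0 ("prior risk"): their episode history
before the study clock starts is generated but then discarded, except for
the latent count ``k0`` of prior episodes — the quantity that is unknown
in real left-censored cohorts and that the imputation machinery recovers.
Subjects not at prior risk enter at a random incorporation time within the
window (a dynamic cohort) with ``k0 = 0``.

Episode gap times are drawn from the episode-specific distributions of a
:class:`~recurmi.populations.PopulationSpec`; because episode k's clock
restarts at the previous event, the generator is a modulated renewal
process with event dependence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .populations import PopulationSpec, draw_episode_time

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "simulate_subject",
    "simulate_cohort",
    "build_risk_intervals",
    "write_episode_table",
    "read_episode_table",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.0

LAYOUTS = ("counting_process", "gap_time")

_MAX_EPISODES = 100_000  # safety valve against degenerate configs


@dataclass(frozen=True)
class CohortConfig:
    """Scenario configuration for one simulated cohort.

    All durations are in days; :meth:`from_years` converts from years
    (1 year = 365 days).

    Parameters
    ----------
    n : int
        Cohort size.
    followup : float
        Length of the study follow-up window.
    prior_window : float
        Maximum time a prior-risk subject may already have been at risk
        when the study starts (uniformly distributed over (0, window]).
    prior_risk_prop : float
        Proportion of subjects at risk before t = 0; exactly
        ``round(n * prior_risk_prop)`` subjects are flagged.
    seed : int
        Root seed; per-subject substreams are spawned deterministically.
    entry_at_zero : bool
        If True, non-prior-risk subjects all enter at t = 0 instead of at
        a uniform incorporation time in [0, followup).
    """

    n: int
    followup: float
    prior_window: float
    prior_risk_prop: float
    seed: int = 0
    entry_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        if not self.followup > 0:
            raise ValueError("followup must be positive")
        if self.prior_window < 0:
            raise ValueError("prior_window must be non-negative")
        if not 0.0 <= self.prior_risk_prop <= 1.0:
            raise ValueError("prior_risk_prop must lie in [0, 1]")

    @classmethod
    def from_years(
        cls,
        n: int,
        followup_years: float,
        prior_window_years: float,
        prior_risk_prop: float,
        seed: int = 0,
        entry_at_zero: bool = False,
    ) -> "CohortConfig":
        return cls(
            n=n,
            followup=followup_years * DAYS_PER_YEAR,
            prior_window=prior_window_years * DAYS_PER_YEAR,
            prior_risk_prop=prior_risk_prop,
            seed=seed,
            entry_at_zero=entry_at_zero,
        )


@dataclass
class SubjectRecord:
    """One subject's simulated history on the study clock.

    ``k0`` is the latent number of episodes before t = 0 (0 unless the
    subject was at prior risk); ``prior_time`` is the known time already
    at risk when the study starts.  ``intervals`` are the observed
    (start, stop, status) risk intervals within [entry_time, followup].
    """

    id: int
    covariates: np.ndarray
    prior_risk: bool
    k0: int
    entry_time: float
    prior_time: float
    intervals: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return sum(s for _, _, s in self.intervals)

    @property
    def observed_time(self) -> float:
        return self.intervals[-1][1] - self.intervals[0][0]


def simulate_subject(
    pop: PopulationSpec,
    cfg: CohortConfig,
    at_prior_risk: bool,
    rng: np.random.Generator,
    subject_id: int = 0,
    covariates: np.ndarray | None = None,
) -> SubjectRecord:
    """Simulate a single subject's episode history.

    Prior-risk subjects start their episode clock at ``-a`` with
    ``a ~ U(0, prior_window]``; episodes completed before t = 0 advance the
    true episode index ``k`` and are counted in ``k0`` but their times are
    discarded.  The gap in progress at t = 0 carries over, so the first
    observed interval starts at 0 and its hazard reflects the subject's
    true (latent) episode number.
    """
    if covariates is None:
        covariates = (rng.uniform(size=pop.n_covariates) < np.asarray(pop.covariate_probs)).astype(
            float
        )
    xb = float(covariates @ np.asarray(pop.effects))

    if at_prior_risk and cfg.prior_window > 0:
        prior_time = cfg.prior_window * rng.uniform(low=np.nextafter(0.0, 1.0), high=1.0)
        entry = 0.0
    else:
        prior_time = 0.0
        entry = 0.0 if (at_prior_risk or cfg.entry_at_zero) else rng.uniform(0.0, cfg.followup)

    tau = entry - prior_time  # current position of the episode clock
    k = 1
    k0 = 0
    intervals: list[tuple[float, float, int]] = []
    seg_start = entry
    for _ in range(_MAX_EPISODES):
        gap = float(draw_episode_time(pop.episode_spec(k), xb, rng))
        t_event = tau + gap
        if t_event <= 0.0:
            # episode completed before follow-up starts: latent history
            k0 += 1
            k += 1
            tau = t_event
            continue
        if t_event >= cfg.followup:
            intervals.append((seg_start, cfg.followup, 0))
            break
        intervals.append((seg_start, t_event, 1))
        seg_start = t_event
        tau = t_event
        k += 1
    else:  # pragma: no cover
        raise RuntimeError("episode cap exceeded; check configuration")

    return SubjectRecord(
        id=subject_id,
        covariates=covariates,
        prior_risk=bool(at_prior_risk),
        k0=k0,
        entry_time=entry,
        prior_time=prior_time,
        intervals=intervals,
    )


def simulate_cohort(pop: PopulationSpec, cfg: CohortConfig) -> list[SubjectRecord]:
    """Simulate a cohort of ``cfg.n`` subjects.

    Exactly ``round(n * prior_risk_prop)`` subjects (the first ids) are at
    prior risk.  Each subject gets an independent substream spawned from
    the root seed, so cohorts are reproducible and individual subjects'
    draws do not depend on cohort composition.
    """
    n_prior = int(round(cfg.n * cfg.prior_risk_prop))
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n)
    cohort = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cohort.append(
            simulate_subject(pop, cfg, at_prior_risk=i < n_prior, rng=rng, subject_id=i + 1)
        )
    return cohort


def build_risk_intervals(subjects: list[SubjectRecord], layout: str) -> pd.DataFrame:
    """Arrange observed episodes as start-stop risk intervals.

    ``counting_process`` keeps intervals on the study clock (row k starts
    where row k-1 stopped); ``gap_time`` restarts each row's clock at 0 so
    its stop equals the gap duration.  Columns: id, start, stop, status,
    episode (observed 1-based index), true_episode (= k0 + episode, latent),
    risk_before, prior_time, x1..xp.  The layout is recorded in
    ``df.attrs["layout"]``.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    rows = []
    for s in subjects:
        prev_stop = s.entry_time
        for j, (start, stop, status) in enumerate(s.intervals, start=1):
            if not stop > start:
                raise ValueError(f"subject {s.id}: interval ({start}, {stop}) is empty")
            if start < prev_stop - 1e-9:
                raise ValueError(f"subject {s.id}: overlapping intervals")
            prev_stop = stop
            if layout == "counting_process":
                row_start, row_stop = start, stop
            else:
                row_start, row_stop = 0.0, stop - start
            rows.append(
                (s.id, row_start, row_stop, status, j, s.k0 + j,
                 int(s.prior_risk), s.prior_time, *s.covariates)
            )
    p = len(subjects[0].covariates) if subjects else 0
    cols = ["id", "start", "stop", "status", "episode", "true_episode",
            "risk_before", "prior_time"] + [f"x{i + 1}" for i in range(p)]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["layout"] = layout
    return df


def covariate_columns(df: pd.DataFrame) -> list[str]:
    """Names of the covariate columns (x1, x2, ...) of an episode table."""
    return [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]


def write_episode_table(df: pd.DataFrame, path) -> None:
    """Write an episode table as CSV with a leading layout tag line."""
    layout = df.attrs.get("layout", "counting_process")
    buf = io.StringIO()
    buf.write(f"# layout={layout}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_episode_table(path) -> pd.DataFrame:
    """Read an episode table written by :func:`write_episode_table`."""
    with open(path) as fh:
        first = fh.readline()
        layout = "counting_process"
        if first.startswith("# layout="):
            layout = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout tag {layout!r}")
    df.attrs["layout"] = layout
    return df
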