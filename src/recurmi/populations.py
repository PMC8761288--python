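"""Episode-time distributions and the six simulated worker populations.

Each population is defined by three episode-specific baseline-hazard
distributions (episode 1, episode 2, episode >= 3; the third is reused for
every later episode) together with covariate effects acting on the hazard.
Populations 1-3 use unit-shape Weibull (i.e. exponential) episode times, so
the hazard is constant within an episode but differs between episodes:
pure event dependence.  Populations 4-6 mix lognormal, loglogistic and
Weibull episode times with non-constant within-episode hazards.

Time is measured in days throughout (1 year = 365 days): with location
parameters around beta0 = 8.1 on the log-day scale, mean first-episode
times are on the order of e^8.1 days ~ 9 years, a plausible scale for
occupational sick-leave cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpisodeDistributionSpec",
    "PopulationSpec",
    "POPULATIONS",
    "draw_episode_time",
    "episode_hazard_ratio",
    "get_population",
]

FAMILIES = ("weibull", "lognormal", "loglogistic")


@dataclass(frozen=True)
class EpisodeDistributionSpec:
    """One episode's baseline time-to-event distribution.

    Parameters
    ----------
    family : {"weibull", "lognormal", "loglogistic"}
    beta0 : float
        Location parameter on the log-time scale.  For the Weibull the
        baseline rate is ``lam = exp(-p * beta0)``; for the lognormal
        ``mu = beta0``; for the loglogistic ``lam = exp(-beta0)``.
    ancillary : float
        Shape parameter: Weibull shape ``p``, lognormal ``sigma`` or
        loglogistic ``gamma``.  Must be positive.
    """

    family: str
    beta0: float
    ancillary: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.ancillary > 0:
            raise ValueError("ancillary (shape) parameter must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """A simulated population: episode distributions plus covariate effects.

    ``episodes`` holds exactly three :class:`EpisodeDistributionSpec`
    (episode 1, 2, >=3); any episode index k >= 3 reuses the third spec.
    ``effects`` are log-hazard-ratio coefficients of independent
    Bernoulli covariates with success probabilities ``covariate_probs``.
    """

    episodes: tuple[EpisodeDistributionSpec, ...]
    effects: tuple[float, ...] = (0.25, 0.5, 0.75)
    covariate_probs: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.episodes) != 3:
            raise ValueError("a population needs exactly 3 episode specs")
        if not self.covariate_probs:
            object.__setattr__(
                self, "covariate_probs", tuple(0.5 for _ in self.effects)
            )
        if len(self.covariate_probs) != len(self.effects):
            raise ValueError("covariate_probs must match effects in length")

    @property
    def n_covariates(self) -> int:
        return len(self.effects)

    def episode_spec(self, k: int) -> EpisodeDistributionSpec:
        """Distribution of episode ``k`` (1-based); constant for k >= 3."""
        if k < 1:
            raise ValueError("episode index is 1-based")
        return self.episodes[min(k, 3) - 1]


def _weibull_specs(rows: list[tuple[float, float]]) -> tuple[EpisodeDistributionSpec, ...]:
    return tuple(EpisodeDistributionSpec("weibull", b0, anc) for b0, anc in rows)


#: The six populations of the simulation study.  Populations 1-3 are
#: exponential with increasing event dependence; 4-6 have non-constant
#: within-episode hazards.
POPULATIONS: dict[int, PopulationSpec] = {
    1: PopulationSpec(_weibull_specs([(8.109, 1), (7.927, 1), (7.745, 1)])),
    2: PopulationSpec(_weibull_specs([(8.109, 1), (7.703, 1), (7.298, 1)])),
    3: PopulationSpec(_weibull_specs([(8.109, 1), (7.193, 1), (6.276, 1)])),
    4: PopulationSpec(
        (
            EpisodeDistributionSpec("lognormal", 7.195, 1.498),
            EpisodeDistributionSpec("loglogistic", 6.583, 0.924),
            EpisodeDistributionSpec("weibull", 6.678, 0.92),
        )
    ),
    5: PopulationSpec(
        (
            EpisodeDistributionSpec("loglogistic", 7.974, 0.836),
            EpisodeDistributionSpec("weibull", 7.109, 0.758),
            EpisodeDistributionSpec("lognormal", 5.853, 1.989),
        )
    ),
    6: PopulationSpec(
        (
            EpisodeDistributionSpec("lognormal", 8.924, 1.545),
            EpisodeDistributionSpec("lognormal", 6.650, 2.399),
            EpisodeDistributionSpec("lognormal", 6.696, 2.246),
        )
    ),
}


def get_population(pop_id: int, effects: tuple[float, ...] | None = None) -> PopulationSpec:
    """Population ``pop_id`` (1-6), optionally with overridden effects.

    Overriding ``effects`` is how the type-I-error study sets up a single
    zero-effect covariate on population 1's hazards.
    """
    try:
        pop = POPULATIONS[pop_id]
    except KeyError:
        raise ValueError(f"population id must be 1..6, got {pop_id}") from None
    if effects is None:
        return pop
    return PopulationSpec(pop.episodes, tuple(effects))


def draw_episode_time(
    spec: EpisodeDistributionSpec,
    linear_predictor: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw time(s) to the next episode under ``spec`` for one subject.

    The covariate linear predictor ``x @ beta`` enters proportionally on
    the hazard for the Weibull family (``lam = exp(-p*beta0 + xb)``), and
    as a location shift (accelerated-failure form, ``beta0 - xb``) for the
    lognormal and loglogistic families, which have no proportional-hazards
    representation.
    """
    xb = float(linear_predictor)
    if spec.family == "weibull":
        p = spec.ancillary
        lam = np.exp(-p * spec.beta0 + xb)
        e = rng.exponential(size=size)
        return (e / lam) ** (1.0 / p)
    if spec.family == "lognormal":
        mu = spec.beta0 - xb
        z = rng.standard_normal(size=size)
        return np.exp(mu + spec.ancillary * z)
    if spec.family == "loglogistic":
        gamma = spec.ancillary
        lam = np.exp(-(spec.beta0 - xb))
        u = rng.uniform(size=size)
        return (u / (1.0 - u)) ** gamma / lam
    raise ValueError(f"unknown family {spec.family!r}")  # pragma: no cover


def episode_hazard_ratio(pop: PopulationSpec, k: int) -> float:
    """Hazard ratio of episode ``k`` relative to episode 1.

    Defined only for populations whose episode distributions are all
    unit-shape Weibull (constant hazards), where it equals
    ``exp(beta0_episode1 - beta0_episodek)``.
    """
    if not all(s.family == "weibull" and s.ancillary == 1 for s in pop.episodes):
        raise ValueError(
            "episode hazard ratio is defined only for constant-hazard "
            "(unit-shape Weibull) populations"
        )
    if k < 1:
        raise ValueError("episode index is 1-based")
    return float(np.exp(pop.episode_spec(1).beta0 - pop.episode_spec(k).beta0))
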