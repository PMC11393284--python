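"""Stationary sex- and age-structured life-table engine.

The population is modelled as a sex-specific life table with 25 September-age
classes (0..24).  Age-specific total annual mortality ``q_x`` is the hunting
mortality rate floored at a baseline vehicle-collision rate (0.02 for every
sex and age class); survivorship is the running product of survival rates,
``l_x = prod_{i<x}(1 - q_i)``.  The model is stationary: the same number of
calves is recruited every year, each cohort is thinned by the same schedule,
and the age structure is constant over time.  Recruitment is closed by the
census scaling — the spring population (ages 1..24, both sexes) is scaled to
a target, 1000 individuals by default — rather than by the fecundity
schedule, which is used only for the September (pre-season) census.

Deaths in each cell split into collision deaths ``n_x * baseline`` and
harvest ``n_x * (q_x - baseline)``; survivors of the terminal age class are
counted as deaths that year (q_24 := 1 for accounting), which makes the
per-sex conservation identity recruits == total deaths exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_AGES",
    "TERMINAL_AGE",
    "DEFAULT_BASELINE_COLLISION",
    "MortalitySchedule",
    "FecundityParameters",
    "SurvivorshipCurve",
    "CohortTable",
    "DegenerateScheduleError",
    "effective_mortality",
    "survivorship",
    "stationary_table",
    "mortality_partition",
    "september_population",
    "project_forward",
    "schedule_frame",
    "cohort_frame",
]

N_AGES = 25
TERMINAL_AGE = N_AGES - 1

#: All-class annual vehicle-collision mortality rate.
DEFAULT_BASELINE_COLLISION = 0.02

SEXES = ("female", "male")


class DegenerateScheduleError(ValueError):
    """Raised when a schedule cannot support a positive spring population."""


def _as_rates(values, *, sex: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_AGES,):
        raise ValueError(
            f"{sex} rates must have length {N_AGES}, got shape {arr.shape}"
        )
    bad = np.where((arr < 0.0) | (arr > 1.0))[0]
    if bad.size:
        raise ValueError(
            f"mortality rate outside [0, 1] for sex={sex} at ages {bad.tolist()}"
        )
    return arr


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-sex total annual mortality probabilities for ages 0..24.

    ``provenance`` tags each cell ``stated`` (taken from a strategy
    definition), ``derived`` (filled in where the source text is silent) or
    ``floor`` (raised to the baseline collision rate).
    """

    female: np.ndarray
    male: np.ndarray
    baseline_collision: float = DEFAULT_BASELINE_COLLISION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "female", _as_rates(self.female, sex="female"))
        object.__setattr__(self, "male", _as_rates(self.male, sex="male"))
        b = float(self.baseline_collision)
        if not 0.0 <= b < 1.0:
            raise ValueError(f"baseline_collision must be in [0, 1), got {b}")
        object.__setattr__(self, "baseline_collision", b)

    def rates(self, sex: str) -> np.ndarray:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return getattr(self, sex)

    def accounting_rates(self, sex: str) -> np.ndarray:
        """Rates with the terminal class forced to 1 (survivors die)."""
        q = self.rates(sex).copy()
        q[TERMINAL_AGE] = 1.0
        return q


@dataclass(frozen=True)
class FecundityParameters:
    """Calves per female alive at the season start, and the recruit sex split.

    Danish red deer: 0.57 calves per yearling hind, 0.82 per adult hind,
    half of recruits female.
    """

    m_x: np.ndarray = None
    proportion_female: float = 0.5

    def __post_init__(self):
        if self.m_x is None:
            m = np.zeros(N_AGES)
            m[1] = 0.57
            m[2:] = 0.82
        else:
            m = np.asarray(self.m_x, dtype=float)
            if m.shape != (N_AGES,):
                raise ValueError(f"m_x must have length {N_AGES}")
            if m[0] != 0.0:
                raise ValueError("calves (age 0) cannot reproduce: m_0 must be 0")
            if (m < 0).any():
                raise ValueError("fecundity rates must be nonnegative")
        object.__setattr__(self, "m_x", m)
        p = float(self.proportion_female)
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportion_female must be in [0, 1]")
        object.__setattr__(self, "proportion_female", p)


@dataclass(frozen=True)
class SurvivorshipCurve:
    """l_x per sex: probability of surviving from recruitment to age x."""

    female: np.ndarray
    male: np.ndarray

    def curve(self, sex: str) -> np.ndarray:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return getattr(self, sex)


@dataclass
class CohortTable:
    """Stationary population, deaths, harvest and collision deaths by sex/age.

    ``population[sex][0]`` is the recruit cohort n_0 for that sex; the spring
    census covers ages 1..24 only.
    """

    population: dict
    deaths: dict
    harvest: dict
    collisions: dict
    baseline_collision: float
    spring_target: float

    @property
    def recruits(self) -> dict:
        return {sex: float(self.population[sex][0]) for sex in SEXES}

    @property
    def n_spring(self) -> float:
        return float(sum(self.population[sex][1:].sum() for sex in SEXES))


def effective_mortality(
    hunting_rates: dict,
    baseline: float = DEFAULT_BASELINE_COLLISION,
    provenance: dict | None = None,
) -> MortalitySchedule:
    """Combine hunting rates with the collision floor into total mortality.

    ``q_x = max(hunting_x, baseline)`` per sex and age.  Cells raised by the
    floor are tagged ``floor`` in the returned schedule's provenance.
    """
    if not 0.0 <= float(baseline) < 1.0:
        raise ValueError(f"baseline must be in [0, 1), got {baseline}")
    rates, prov = {}, {}
    for sex in SEXES:
        h = _as_rates(hunting_rates[sex], sex=sex)
        q = np.maximum(h, baseline)
        given = (provenance or {}).get(sex, ("stated",) * N_AGES)
        prov[sex] = tuple(
            "floor" if q[x] > h[x] else given[x] for x in range(N_AGES)
        )
        rates[sex] = q
    return MortalitySchedule(
        female=rates["female"],
        male=rates["male"],
        baseline_collision=float(baseline),
        provenance=prov,
    )


def survivorship(schedule: MortalitySchedule) -> SurvivorshipCurve:
    """l_x = prod_{i=0}^{x-1} (1 - q_i), with l_0 = 1."""
    out = {}
    for sex in SEXES:
        q = schedule.rates(sex)
        out[sex] = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    return SurvivorshipCurve(**out)


def stationary_table(
    schedule: MortalitySchedule, spring_target: float = 1000.0
) -> CohortTable:
    """Scale the stationary age structure to a spring census target.

    Both sexes share one recruit cohort size (equal sex ratio at birth and
    identical calf mortality), chosen so that the spring population — ages
    1..24 summed over sexes — equals ``spring_target`` exactly.  Deaths are
    partitioned into harvest and collisions by :func:`mortality_partition`.
    """
    if not spring_target > 0:
        raise ValueError(f"spring_target must be positive, got {spring_target}")
    lx = survivorship(schedule)
    unit_spring = sum(lx.curve(sex)[1:].sum() for sex in SEXES)
    if unit_spring <= 0.0:
        raise DegenerateScheduleError(
            "schedule kills every cohort before age 1; spring population "
            "cannot be positive"
        )
    n0 = spring_target / unit_spring
    population = {sex: n0 * lx.curve(sex) for sex in SEXES}
    table = CohortTable(
        population=population,
        deaths={sex: np.zeros(N_AGES) for sex in SEXES},
        harvest={sex: np.zeros(N_AGES) for sex in SEXES},
        collisions={sex: np.zeros(N_AGES) for sex in SEXES},
        baseline_collision=schedule.baseline_collision,
        spring_target=float(spring_target),
    )
    return mortality_partition(table, schedule)


def mortality_partition(
    table: CohortTable, schedule: MortalitySchedule
) -> CohortTable:
    """Fill deaths, harvest and collision deaths from the populations.

    Per cell: ``dn = n * q`` (terminal q treated as 1), ``c = n * baseline``
    and ``h = n * (q - baseline)`` floored at zero.  With the floor rule
    q >= baseline this makes ``h + c == dn`` exact.
    """
    b = schedule.baseline_collision
    for sex in SEXES:
        n = table.population[sex]
        q = schedule.accounting_rates(sex)
        table.deaths[sex] = n * q
        table.collisions[sex] = n * b
        table.harvest[sex] = np.maximum(n * (q - b), 0.0)
    return table


def september_population(
    table: CohortTable, fec: FecundityParameters | None = None
) -> float:
    """Pre-season census: spring population plus the calves born that summer.

    The calf cohort implied by the fecundity schedule is split
    ``proportion_female`` / ``1 - proportion_female``; only the total enters
    the census.
    """
    fec = fec or FecundityParameters()
    born = float(table.population["female"][1:] @ fec.m_x[1:])
    return table.n_spring + born


def september_calves(
    table: CohortTable, fec: FecundityParameters | None = None
) -> dict:
    """Sex split of the fecundity-born calf cohort (diagnostic breakdown)."""
    fec = fec or FecundityParameters()
    born = float(table.population["female"][1:] @ fec.m_x[1:])
    return {
        "total": born,
        "female": born * fec.proportion_female,
        "male": born * (1.0 - fec.proportion_female),
    }


def project_forward(
    schedule: MortalitySchedule,
    recruits_per_year: dict,
    years: int,
    initial_structure: dict | None = None,
) -> dict:
    """Iterate cohort aging under constant recruitment.

    Test oracle for stationarity: from any starting structure the projection
    converges (geometrically, within 25 years in exact arithmetic) to the
    closed-form stationary table with the same recruitment.  Survivors of the
    terminal age class leave the population.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    state = {}
    for sex in SEXES:
        if initial_structure is None:
            state[sex] = np.zeros(N_AGES)
        else:
            init = np.asarray(initial_structure[sex], dtype=float)
            if init.shape != (N_AGES,) or (init < 0).any():
                raise ValueError(f"initial structure for {sex} invalid")
            state[sex] = init.copy()
    for _ in range(int(years)):
        for sex in SEXES:
            surv = state[sex][:-1] * (1.0 - schedule.rates(sex)[:-1])
            state[sex] = np.concatenate([[float(recruits_per_year[sex])], surv])
    return state


# -- tabular views -----------------------------------------------------------

def schedule_frame(schedule: MortalitySchedule) -> pd.DataFrame:
    """Long-format view of a schedule (sex, age, total mortality, provenance)."""
    rows = []
    for sex in SEXES:
        q = schedule.rates(sex)
        prov = schedule.provenance.get(sex, ("stated",) * N_AGES)
        for age in range(N_AGES):
            rows.append(
                {
                    "sex": sex,
                    "age": age,
                    "total_mortality": q[age],
                    "provenance": prov[age],
                }
            )
    return pd.DataFrame(rows)


def cohort_frame(table: CohortTable) -> pd.DataFrame:
    """Long-format view of a cohort table, one row per sex and age."""
    rows = []
    for sex in SEXES:
        for age in range(N_AGES):
            rows.append(
                {
                    "sex": sex,
                    "age": age,
                    "population": table.population[sex][age],
                    "deaths": table.deaths[sex][age],
                    "harvest": table.harvest[sex][age],
                    "collisions": table.collisions[sex][age],
                }
            )
    return pd.DataFrame(rows)
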