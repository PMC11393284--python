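"""Cull-based population estimation and the vehicle-collision probability.

A deer population can be reconstructed from hunting-bag statistics as

    N = C * L * lam / eta

with C individuals reported culled per season, L the mean age of harvested
animals in years (longevity), lam the annual population growth rate and eta
the proportion of all deaths due to culling.  The per-individual annual
collision probability divides the red deer share of registered deer-vehicle
collisions by that spring population.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CullEstimateInputs",
    "population_from_cull",
    "collision_probability",
    "browsing_cost_per_individual",
]


@dataclass(frozen=True)
class CullEstimateInputs:
    """Inputs to the cull-based estimator N = C * L * lam / eta."""

    culled: float  # C, individuals per season
    longevity: float  # L, mean age of harvested deer (years)
    growth_rate: float  # lam, annual multiplicative growth
    cull_share: float  # eta, proportion of all deaths due to culling

    def __post_init__(self):
        if self.culled < 0:
            raise ValueError("culled count must be nonnegative")
        if self.longevity <= 0:
            raise ValueError("longevity must be positive")
        if self.growth_rate <= 0:
            raise ValueError("growth rate must be positive")
        if not 0.0 < self.cull_share <= 1.0:
            raise ValueError("cull share must be in (0, 1]")


def population_from_cull(inputs: CullEstimateInputs) -> float:
    """Spring population N = C * L * lam / eta (unrounded).

    Homogeneous of degree 1 in C and reciprocal in eta; round the result for
    reporting.
    """
    return inputs.culled * inputs.longevity * inputs.growth_rate / inputs.cull_share


def collision_probability(
    total_deer_collisions: float,
    red_deer_callouts: float,
    all_deer_callouts: float,
    spring_population: float,
    round_intermediate: bool = False,
) -> float:
    """Annual probability that one red deer is involved in a collision.

    The red deer share of callouts apportions the registered all-species
    deer collision count; dividing by the spring population and capping at 1
    gives the per-individual probability.  The apportioned red deer count is
    kept unrounded by default (``round_intermediate`` truncates it to whole
    animals for comparison with rounded reports).
    """
    if min(total_deer_collisions, red_deer_callouts) < 0:
        raise ValueError("collision counts must be nonnegative")
    if all_deer_callouts <= 0 or spring_population <= 0:
        raise ValueError("denominators must be positive")
    red_deer = total_deer_collisions * red_deer_callouts / all_deer_callouts
    if round_intermediate:
        red_deer = float(int(red_deer))
    return min(red_deer / spring_population, 1.0)


def browsing_cost_per_individual(
    total_annual_cost: float, pre_season_population: float
) -> float:
    """Average browsing damage cost per deer-year (DKK/individual).

    Browsing happens mostly in spring and summer, so the pre-hunting-season
    population is the right denominator.  Feed the result through
    :func:`deer_cba.valuation.allocate_by_weight` for per-class costs.
    """
    if pre_season_population <= 0:
        raise ValueError("population must be positive")
    if total_annual_cost < 0:
        raise ValueError("total cost must be nonnegative")
    return total_annual_cost / pre_season_population
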