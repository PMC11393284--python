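"""Eight-class aggregation and the annual net-benefit function.

The life table collapses to eight sex/age classes:

====  ==================  =================
code  class               September ages
====  ==================  =================
FC    female calves       0 (recruits)
FY    female yearlings    1
FA    adult females       2-24
MC    male calves         0 (recruits)
MY    male yearlings      1
YS    young stags         2-4
NS    near-mature stags   5-7
MS    mature stags        8-24
====  ==================  =================

Annual net benefit (DKK/yr)::

    NB = sum_i m * w_i * h_i  +  sum_i r_i * h_i
       - sum_i b_i * n_i      -  alpha * sum_i t_i * n_i

where h_i / n_i are the class harvest and population, m the meat price
(DKK/kg, identical across classes), w_i carcass weight (kg), r_i the
marginal recreational value (DKK per harvested individual; the trophy value
of old stags is embodied in large r_NS, r_MS), b_i the marginal browsing
damage cost and alpha * t_i the marginal traffic damage cost (DKK per
individual in the population per year).  Meat and recreational values follow
the harvest; browsing and traffic costs follow the standing population.

All monetary benchmark values are producer prices in 2022 DKK; helpers are
provided to bring raw consumer prices onto that basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .demography import CohortTable, FecundityParameters

__all__ = [
    "CLASSES",
    "CLASS_RANGES",
    "ClassAggregate",
    "ValuationParameters",
    "NetBenefitBreakdown",
    "aggregate_classes",
    "net_benefit",
    "allocate_by_weight",
    "normalize_price",
]

CLASSES = ("FC", "FY", "FA", "MC", "MY", "YS", "NS", "MS")

#: (sex, first age, last age) per class; calves are the recruit cohorts.
CLASS_RANGES = {
    "FC": ("female", 0, 0),
    "FY": ("female", 1, 1),
    "FA": ("female", 2, 24),
    "MC": ("male", 0, 0),
    "MY": ("male", 1, 1),
    "YS": ("male", 2, 4),
    "NS": ("male", 5, 7),
    "MS": ("male", 8, 24),
}

GROUPS = ("meat", "recreational", "browsing", "traffic")


@dataclass(frozen=True)
class ClassAggregate:
    """Populations and harvests collapsed to the eight sex/age classes."""

    population: pd.Series
    harvest: pd.Series

    def __post_init__(self):
        for name in ("population", "harvest"):
            s = getattr(self, name).reindex(CLASSES).astype(float)
            if s.isna().any():
                raise ValueError(f"{name} missing classes: "
                                 f"{list(s.index[s.isna()])}")
            if (s < 0).any():
                raise ValueError(f"negative {name} entries")
            object.__setattr__(self, name, s)


@dataclass(frozen=True)
class ValuationParameters:
    """Marginal values and costs per class (annual, producer prices, DKK)."""

    meat_price: float
    weight: pd.Series
    recreational: pd.Series
    browsing: pd.Series
    traffic_constant: pd.Series
    collision_probability: float
    price_nature: str = "producer"
    price_year: int = 2022

    def __post_init__(self):
        if self.meat_price < 0:
            raise ValueError("meat_price must be nonnegative")
        if not 0.0 <= self.collision_probability <= 1.0:
            raise ValueError("collision_probability must be in [0, 1]")
        for name in ("weight", "recreational", "browsing", "traffic_constant"):
            s = getattr(self, name).reindex(CLASSES).astype(float)
            if s.isna().any():
                raise ValueError(
                    f"valuation parameter {name!r} missing classes: "
                    f"{list(s.index[s.isna()])}"
                )
            if (s < 0).any():
                raise ValueError(f"negative entries in {name}")
            object.__setattr__(self, name, s)

    @classmethod
    def benchmark(cls) -> "ValuationParameters":
        """The packaged Danish red deer benchmark parameter set."""
        df = _read_packaged("benchmark_valuation.csv").set_index("class")
        price = df["meat_price_dkk_per_kg"].unique()
        alpha = df["collision_probability"].unique()
        if len(price) != 1 or len(alpha) != 1:
            raise ValueError("benchmark table must have constant price/alpha")
        return cls(
            meat_price=float(price[0]),
            weight=df["weight_kg"],
            recreational=df["recreational_dkk"],
            browsing=df["browsing_dkk"],
            traffic_constant=df["traffic_constant_dkk"],
            collision_probability=float(alpha[0]),
        )

    @classmethod
    def from_csv(cls, path) -> "ValuationParameters":
        df = pd.read_csv(path).set_index("class")
        return cls(
            meat_price=float(df["meat_price_dkk_per_kg"].iloc[0]),
            weight=df["weight_kg"],
            recreational=df["recreational_dkk"],
            browsing=df["browsing_dkk"],
            traffic_constant=df["traffic_constant_dkk"],
            collision_probability=float(df["collision_probability"].iloc[0]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "meat_price_dkk_per_kg": self.meat_price,
                "weight_kg": self.weight,
                "recreational_dkk": self.recreational,
                "browsing_dkk": self.browsing,
                "traffic_constant_dkk": self.traffic_constant,
                "collision_probability": self.collision_probability,
            }
        ).rename_axis("class")

    def scaled(self, factors: dict) -> "ValuationParameters":
        """New parameter set with value/cost groups rescaled.

        ``factors`` maps group names (``meat``, ``recreational``,
        ``browsing``, ``traffic``) to multipliers.  The meat group scales the
        price, the traffic group scales the per-class constants (equivalent
        to scaling the product alpha * t_i).
        """
        unknown = set(factors) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        return ValuationParameters(
            meat_price=self.meat_price * factors.get("meat", 1.0),
            weight=self.weight,
            recreational=self.recreational * factors.get("recreational", 1.0),
            browsing=self.browsing * factors.get("browsing", 1.0),
            traffic_constant=self.traffic_constant * factors.get("traffic", 1.0),
            collision_probability=self.collision_probability,
            price_nature=self.price_nature,
            price_year=self.price_year,
        )


@dataclass(frozen=True)
class NetBenefitBreakdown:
    """Per-class value/cost terms, group totals and the annual net benefit."""

    meat: pd.Series
    recreational: pd.Series
    browsing: pd.Series
    traffic: pd.Series

    def total(self, group: str) -> float:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return float(getattr(self, group).sum())

    @property
    def totals(self) -> dict:
        return {g: self.total(g) for g in GROUPS}

    @property
    def net_benefit(self) -> float:
        return (
            self.total("meat")
            + self.total("recreational")
            - self.total("browsing")
            - self.total("traffic")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "meat_value": self.meat,
                "recreational_value": self.recreational,
                "browsing_cost": self.browsing,
                "traffic_cost": self.traffic,
            }
        ).rename_axis("class")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("deer_cba.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def aggregate_classes(
    table: CohortTable, fec: FecundityParameters | None = None
) -> ClassAggregate:
    """Collapse a cohort table to the eight classes.

    Calf-class populations report the recruit cohorts n_0; older classes sum
    the September-age populations over the class age range.
    """
    pop, har = {}, {}
    for cls, (sex, lo, hi) in CLASS_RANGES.items():
        pop[cls] = float(table.population[sex][lo : hi + 1].sum())
        har[cls] = float(table.harvest[sex][lo : hi + 1].sum())
    return ClassAggregate(
        population=pd.Series(pop).reindex(CLASSES),
        harvest=pd.Series(har).reindex(CLASSES),
    )


def net_benefit(
    agg: ClassAggregate, params: ValuationParameters
) -> NetBenefitBreakdown:
    """Evaluate the annual net-benefit function on a class aggregate."""
    h, n = agg.harvest, agg.population
    return NetBenefitBreakdown(
        meat=params.meat_price * params.weight * h,
        recreational=params.recreational * h,
        browsing=params.browsing * n,
        traffic=params.collision_probability * params.traffic_constant * n,
    )


def allocate_by_weight(
    reference_value: float, reference_weight: float, weights: pd.Series
) -> pd.Series:
    """Distribute a per-individual value across classes linearly in weight.

    Used for browsing and traffic costs, whose per-individual damage scales
    with body size: ``value_i = reference_value * w_i / reference_weight``.
    """
    if reference_weight <= 0:
        raise ValueError("reference weight must be positive")
    w = pd.Series(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    return reference_value * w / reference_weight


def normalize_price(
    value: float,
    vat_rate: float = 0.25,
    index_from: float = 1.0,
    index_to: float = 1.0,
) -> float:
    """Convert a consumer price to a producer price in the target price year.

    Divides out value-added tax (Danish standard rate 25% by default), then
    rescales by the net-price index ratio ``index_to / index_from``.
    """
    if vat_rate < 0:
        raise ValueError("vat_rate must be nonnegative")
    if index_from <= 0 or index_to <= 0:
        raise ValueError("price indices must be positive")
    return value / (1.0 + vat_rate) * (index_to / index_from)
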