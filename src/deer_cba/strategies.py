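"""Registry of the five nonoptimal red deer management strategies.

Each strategy is a set of per-sex hunting-mortality segments over September
ages 0..24.  Rates the source management descriptions leave unstated are
filled with the value that reproduces the documented male survivorship to
age 8+ (tagged ``derived``); resolving a strategy applies the collision
floor (see :mod:`deer_cba.demography`).

Built-in strategies:

1   free harvest        — unrestricted within the season (pre-2017 regime)
2   trophy hunting      — spare males until 8+, then heavy harvest
3   maximum harvest     — heavy calf/yearling-male harvest, many hinds
4.A natural composition — uniform male rate
4.B natural composition — age-differentiated male rates

Strategy definitions are data, not code: the same schema round-trips through
YAML/JSON so users can supply their own files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .demography import (
    DEFAULT_BASELINE_COLLISION,
    N_AGES,
    SEXES,
    CohortTable,
    MortalitySchedule,
    effective_mortality,
)

__all__ = [
    "Segment",
    "StrategyDefinition",
    "SexRatioCheck",
    "builtin_strategies",
    "get_strategy",
    "resolve_schedule",
    "check_sex_ratio",
    "strategy_to_dict",
    "strategy_from_dict",
    "load_strategy",
    "dump_strategy",
]

#: Management guideline: at least one mature (8+) stag per 20 hinds of 1+.
FEMALES_PER_MATURE_MALE = 20


@dataclass(frozen=True)
class Segment:
    """A hunting-mortality rate over an inclusive age range."""

    age_from: int
    age_to: int
    rate: float
    source: str = "stated"  # stated | derived

    def __post_init__(self):
        if not 0 <= self.age_from <= self.age_to <= N_AGES - 1:
            raise ValueError(f"bad age range {self.age_from}-{self.age_to}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(
                f"hunting rate outside [0, 1] for ages "
                f"{self.age_from}-{self.age_to}: {self.rate}"
            )


@dataclass(frozen=True)
class StrategyDefinition:
    id: str
    label: str
    female: tuple
    male: tuple
    notes: str = ""

    def segments(self, sex: str):
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return getattr(self, sex)


def _seg(a, b, r, source="stated"):
    return Segment(a, b, r, source)


def builtin_strategies(age_offset: int = 0) -> list:
    """The five built-in management strategies.

    ``age_offset`` applies only to strategy 1's male bands: the default 0
    places the 0.35 band at September-ages 1-2 and the 0.50 band at 3+ (the
    reading consistent with the documented ~1% male survivorship to 8+ and
    the published population composition); ``age_offset=1`` restores the
    literal "2-3 / 4+ years old" placement.
    """
    if age_offset not in (0, 1):
        raise ValueError("age_offset must be 0 or 1")
    o = age_offset
    s1_male = [_seg(0, 0, 0.35)]
    if o == 1:
        s1_male.append(_seg(1, 1, 0.35, "derived"))
    s1_male += [_seg(1 + o, 2 + o, 0.35), _seg(3 + o, 24, 0.50)]
    return [
        StrategyDefinition(
            id="1",
            label="Free harvest",
            female=(_seg(0, 0, 0.35), _seg(1, 24, 0.20)),
            male=tuple(s1_male),
            notes="male yearling rate derived (0.35); male bands at "
            f"September-ages {1 + o}-{2 + o} and {3 + o}+",
        ),
        StrategyDefinition(
            id="2",
            label="Trophy hunting",
            female=(_seg(0, 0, 0.35), _seg(1, 24, 0.20)),
            male=(_seg(0, 0, 0.35), _seg(1, 7, 0.00), _seg(8, 24, 0.50)),
        ),
        StrategyDefinition(
            id="3",
            label="Maximum harvest",
            female=(_seg(0, 0, 0.72), _seg(1, 24, 0.10)),
            male=(
                _seg(0, 0, 0.72),
                _seg(1, 1, 0.77),
                _seg(2, 7, 0.02),
                _seg(8, 24, 0.50),
            ),
        ),
        StrategyDefinition(
            id="4A",
            label="Natural demographic population composition (uniform male rate)",
            female=(_seg(0, 0, 0.50), _seg(1, 24, 0.163)),
            male=(_seg(0, 0, 0.50), _seg(1, 24, 0.26)),
        ),
        StrategyDefinition(
            id="4B",
            label="Natural demographic population composition (differentiated male rates)",
            female=(_seg(0, 0, 0.50), _seg(1, 24, 0.163)),
            male=(
                _seg(0, 0, 0.50),
                _seg(1, 1, 0.20, "derived"),
                _seg(2, 7, 0.20),
                _seg(8, 24, 0.40),
            ),
            notes="male yearling rate derived (0.20, matching the 2-7 band)",
        ),
    ]


def get_strategy(strategy_id: str, age_offset: int = 0) -> StrategyDefinition:
    sid = str(strategy_id).upper().replace(".", "")
    for strat in builtin_strategies(age_offset=age_offset):
        if strat.id == sid:
            return strat
    known = [s.id for s in builtin_strategies()]
    raise KeyError(f"unknown strategy {strategy_id!r}; built-ins are {known}")


def resolve_schedule(
    strategy: StrategyDefinition,
    baseline: float = DEFAULT_BASELINE_COLLISION,
) -> MortalitySchedule:
    """Expand segments to 25 ages per sex and apply the collision floor."""
    rates, prov = {}, {}
    for sex in SEXES:
        r = np.full(N_AGES, np.nan)
        p = [None] * N_AGES
        for seg in strategy.segments(sex):
            span = slice(seg.age_from, seg.age_to + 1)
            if not np.isnan(r[span]).all():
                raise ValueError(
                    f"strategy {strategy.id}: overlapping {sex} segments "
                    f"at ages {seg.age_from}-{seg.age_to}"
                )
            r[span] = seg.rate
            p[seg.age_from : seg.age_to + 1] = [seg.source] * (
                seg.age_to - seg.age_from + 1
            )
        missing = np.where(np.isnan(r))[0]
        if missing.size:
            raise ValueError(
                f"strategy {strategy.id}: no {sex} hunting rate for ages "
                f"{missing.tolist()}"
            )
        rates[sex] = r
        prov[sex] = tuple(p)
    return effective_mortality(rates, baseline=baseline, provenance=prov)


@dataclass(frozen=True)
class SexRatioCheck:
    """Result of the polygyny feasibility check (1 mature stag : 20 hinds)."""

    ok: bool
    mature_males: float
    females_1plus: float
    required_males: float

    @property
    def ratio(self) -> float:
        if self.required_males == 0:
            return float("inf")
        return self.mature_males / self.required_males


def check_sex_ratio(table: CohortTable) -> SexRatioCheck:
    """Warn (not fail) when mature stags fall below 1 per 20 hinds of 1+.

    Red deer are polygynous, so conception is secure as long as the minimum
    ratio holds; with zero females the check passes vacuously.
    """
    males_8plus = float(table.population["male"][8:].sum())
    females_1plus = float(table.population["female"][1:].sum())
    required = females_1plus / FEMALES_PER_MATURE_MALE
    ok = females_1plus == 0.0 or males_8plus >= required
    return SexRatioCheck(
        ok=ok,
        mature_males=males_8plus,
        females_1plus=females_1plus,
        required_males=required,
    )


# -- serialization -----------------------------------------------------------

def strategy_to_dict(strategy: StrategyDefinition) -> dict:
    return {
        "id": strategy.id,
        "label": strategy.label,
        **{
            sex: [
                {
                    "ages": f"{s.age_from}-{s.age_to}",
                    "rate": s.rate,
                    "source": s.source,
                }
                for s in strategy.segments(sex)
            ]
            for sex in SEXES
        },
        "notes": strategy.notes,
    }


def strategy_from_dict(data: dict) -> StrategyDefinition:
    segs = {}
    for sex in SEXES:
        out = []
        for item in data[sex]:
            a, b = (int(v) for v in str(item["ages"]).split("-"))
            out.append(Segment(a, b, float(item["rate"]), item.get("source", "stated")))
        segs[sex] = tuple(out)
    return StrategyDefinition(
        id=str(data["id"]),
        label=data.get("label", str(data["id"])),
        female=segs["female"],
        male=segs["male"],
        notes=data.get("notes", ""),
    )


def dump_strategy(strategy: StrategyDefinition, path) -> None:
    path = Path(path)
    payload = strategy_to_dict(strategy)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_strategy(path) -> StrategyDefinition:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return strategy_from_dict(data)
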