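"""Decision rules over strategies and the grouped ±50% sensitivity analysis.

A strategy with the highest positive net benefit is implemented.  If every
candidate's net benefit is negative, the zero-population alternative
(NB = 0) dominates and the recommendation is to drive the population toward
extinction; an exact zero is indifferent to extinction.

The sensitivity analysis varies one marginal value or cost group at a time —
meat values m*w_i, recreational values r_i, browsing costs b_i, traffic
costs alpha*t_i — simultaneously across all classes by a ± factor (50% by
default).  Because the net benefit is linear in each group, the bounds obey
an exact identity: NB_bound = NB ± factor * group_total for value groups and
NB ∓ factor * group_total for cost groups (raising a cost lowers NB).  An
independent recomputation path (rescale the parameters, re-evaluate the
net-benefit function) is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .valuation import (
    GROUPS,
    ClassAggregate,
    NetBenefitBreakdown,
    ValuationParameters,
    net_benefit,
)

__all__ = [
    "Recommendation",
    "rank_and_decide",
    "sensitivity_table",
    "sensitivity_by_recomputation",
    "EXTINCTION",
]

#: Value groups enter NB with a plus sign, cost groups with a minus sign.
GROUP_SIGNS = {"meat": 1.0, "recreational": 1.0, "browsing": -1.0, "traffic": -1.0}

EXTINCTION = "extinction"


@dataclass(frozen=True)
class Recommendation:
    """Outcome of the decision rules.

    ``action`` is ``implement`` (a unique best strategy with NB > 0),
    ``indifferent`` (ties at the top, or best NB exactly 0 vs extinction)
    or ``extinction`` (all NB < 0, so the NB = 0 zero-population
    alternative dominates).
    """

    action: str
    strategies: tuple
    net_benefit: float

    @property
    def strategy(self):
        return self.strategies[0] if self.strategies else None


def rank_and_decide(net_benefits: dict) -> Recommendation:
    """Apply the decision rules to a mapping strategy id -> annual NB."""
    if not net_benefits:
        raise ValueError("at least one strategy is required")
    for sid, nb in net_benefits.items():
        if not pd.notna(nb) or nb in (float("inf"), float("-inf")):
            raise ValueError(f"net benefit for strategy {sid!r} is not finite")
    best = max(net_benefits.values())
    winners = tuple(s for s, nb in net_benefits.items() if nb == best)
    if best < 0:
        return Recommendation(EXTINCTION, (), 0.0)
    if best == 0:
        return Recommendation("indifferent", winners + (EXTINCTION,), 0.0)
    if len(winners) > 1:
        return Recommendation("indifferent", winners, float(best))
    return Recommendation("implement", winners, float(best))


def sensitivity_table(
    breakdowns: dict, factor: float = 0.5
) -> pd.DataFrame:
    """Grouped lower/upper net-benefit bounds per strategy.

    ``breakdowns`` maps strategy id -> benchmark
    :class:`~deer_cba.valuation.NetBenefitBreakdown`.  Returns a frame with
    one row per strategy and columns ``benchmark`` plus
    ``{lower,upper}_{meat,recreational,browsing,traffic}``, computed through
    the exact linearity identity.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    rows = {}
    for sid, bd in breakdowns.items():
        nb = bd.net_benefit
        row = {"benchmark": nb}
        for g in GROUPS:
            shift = factor * bd.total(g) * GROUP_SIGNS[g]
            row[f"lower_{g}"] = nb - shift
            row[f"upper_{g}"] = nb + shift
        rows[sid] = row
    cols = ["benchmark"] + [
        f"{bound}_{g}" for g in GROUPS for bound in ("lower", "upper")
    ]
    return pd.DataFrame.from_dict(rows, orient="index")[cols].rename_axis(
        "strategy"
    )


def sensitivity_by_recomputation(
    aggregates: dict,
    params: ValuationParameters,
    factor: float = 0.5,
) -> pd.DataFrame:
    """Independent sensitivity path: rescale parameters, re-evaluate NB.

    Same output layout as :func:`sensitivity_table`; both paths agree to
    floating-point precision, which the test suite asserts.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    rows = {}
    for sid, agg in aggregates.items():
        row = {"benchmark": net_benefit(agg, params).net_benefit}
        for g in GROUPS:
            for bound, mult in (("lower", 1.0 - factor), ("upper", 1.0 + factor)):
                scaled = params.scaled({g: mult})
                row[f"{bound}_{g}"] = net_benefit(agg, scaled).net_benefit
        rows[sid] = row
    cols = ["benchmark"] + [
        f"{bound}_{g}" for g in GROUPS for bound in ("lower", "upper")
    ]
    return pd.DataFrame.from_dict(rows, orient="index")[cols].rename_axis(
        "strategy"
    )
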