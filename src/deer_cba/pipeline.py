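"""End-to-end pipeline: strategies -> life tables -> valuation -> decision.

``run_pipeline`` resolves each selected strategy to a mortality schedule,
builds the stationary cohort table at the configured spring census, collapses
it to the eight classes, evaluates the net-benefit function, applies the
decision rules and the grouped sensitivity analysis, and (optionally) writes
a report bundle: per-strategy population/harvest CSV, value-component CSV,
sensitivity CSV and a JSON summary carrying warnings and provenance notes.

Reports round individuals and DKK amounts to integers; the JSON summary
keeps full precision.  Runs are deterministic: the same configuration
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import cba, demography, strategies, valuation
from .scenarios import component_discrepancies

__all__ = ["RunConfig", "StrategyResult", "PipelineResult", "run_pipeline"]

log = logging.getLogger("deer_cba")

ALL_STRATEGIES = ("1", "2", "3", "4A", "4B")


class RunConfig(BaseModel):
    """Configuration for one pipeline run; defaults give the benchmark setup
    (all five strategies, spring census 1000, collision floor 0.02,
    benchmark valuation, ±50% sensitivity)."""

    strategies: tuple = ALL_STRATEGIES
    spring_target: float = Field(default=1000.0, gt=0)
    baseline_collision: float = Field(default=0.02, ge=0, lt=1)
    valuation_csv: Path | None = None
    sensitivity_factor: float = Field(default=0.5, gt=0, le=1)
    age_offset: int = Field(default=0, ge=0, le=1)
    output_dir: Path | None = None
    verbose: bool = False

    @field_validator("strategies", mode="before")
    @classmethod
    def _norm_strategies(cls, v):
        if isinstance(v, str):
            v = ALL_STRATEGIES if v == "all" else (v,)
        ids = tuple(str(s).upper().replace(".", "") for s in v)
        unknown = [s for s in ids if s not in ALL_STRATEGIES]
        if unknown:
            raise ValueError(
                f"unknown strategy ids {unknown}; built-ins are {list(ALL_STRATEGIES)}"
            )
        if not ids:
            raise ValueError("at least one strategy must be selected")
        return ids


@dataclass(frozen=True)
class StrategyResult:
    definition: strategies.StrategyDefinition
    schedule: demography.MortalitySchedule
    table: demography.CohortTable
    aggregate: valuation.ClassAggregate
    breakdown: valuation.NetBenefitBreakdown
    sex_ratio: strategies.SexRatioCheck
    september_population: float


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    results: dict
    recommendation: cba.Recommendation
    sensitivity: pd.DataFrame
    warnings: tuple

    @property
    def net_benefits(self) -> dict:
        return {sid: r.breakdown.net_benefit for sid, r in self.results.items()}


def _load_valuation(config: RunConfig) -> valuation.ValuationParameters:
    if config.valuation_csv is None:
        return valuation.ValuationParameters.benchmark()
    return valuation.ValuationParameters.from_csv(config.valuation_csv)


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    if config.verbose:
        logging.basicConfig(level=logging.INFO)
    params = _load_valuation(config)
    warnings: list[str] = []
    results: dict[str, StrategyResult] = {}
    for sid in config.strategies:
        definition = strategies.get_strategy(sid, age_offset=config.age_offset)
        schedule = strategies.resolve_schedule(
            definition, baseline=config.baseline_collision
        )
        for sex in demography.SEXES:
            prov = schedule.provenance.get(sex, ())
            derived = [a for a, p in enumerate(prov) if p == "derived"]
            floored = [a for a, p in enumerate(prov) if p == "floor"]
            if derived:
                log.info(
                    "strategy %s: %s rates at ages %s filled by derivation",
                    sid, sex, derived,
                )
            if floored:
                log.info(
                    "strategy %s: %s rates at ages %s raised to the collision floor",
                    sid, sex, floored,
                )
        table = demography.stationary_table(schedule, config.spring_target)
        agg = valuation.aggregate_classes(table)
        breakdown = valuation.net_benefit(agg, params)
        ratio = strategies.check_sex_ratio(table)
        if not ratio.ok:
            warnings.append(
                f"strategy {sid}: mature stags ({ratio.mature_males:.1f}) below "
                f"1 per {strategies.FEMALES_PER_MATURE_MALE} hinds "
                f"({ratio.required_males:.1f} required); fecundity assumption "
                "may not hold"
            )
        results[sid] = StrategyResult(
            definition=definition,
            schedule=schedule,
            table=table,
            aggregate=agg,
            breakdown=breakdown,
            sex_ratio=ratio,
            september_population=demography.september_population(table),
        )
    if config.valuation_csv is None:
        gaps = component_discrepancies()
        for sid, gap in gaps.items():
            if abs(gap) > 1.5 and sid in config.strategies:
                warnings.append(
                    f"reference dataset: strategy {sid} reported net benefit "
                    f"differs from the sum of its own components by {gap:+,.0f} DKK; "
                    "the pipeline reports its exact arithmetic"
                )
    breakdowns = {sid: r.breakdown for sid, r in results.items()}
    recommendation = cba.rank_and_decide(
        {sid: bd.net_benefit for sid, bd in breakdowns.items()}
    )
    sens = cba.sensitivity_table(breakdowns, factor=config.sensitivity_factor)
    out = PipelineResult(
        config=config,
        results=results,
        recommendation=recommendation,
        sensitivity=sens,
        warnings=tuple(warnings),
    )
    if config.output_dir is not None:
        write_reports(out, Path(config.output_dir))
    return out


# -- report writers ----------------------------------------------------------

def _round_int(x: float) -> int:
    return int(round(x))


def population_harvest_report(result: PipelineResult) -> pd.DataFrame:
    """Class x strategy table of spring populations and harvests (integers)."""
    rows = []
    for quantity in ("population", "harvest"):
        for cls in valuation.CLASSES:
            row = {"quantity": quantity, "class": cls}
            for sid, res in result.results.items():
                row[sid] = _round_int(getattr(res.aggregate, quantity)[cls])
            rows.append(row)
    return pd.DataFrame(rows)


def value_components_report(result: PipelineResult) -> pd.DataFrame:
    """Group totals and net benefit per strategy, whole DKK."""
    rows = []
    for sid, res in result.results.items():
        bd = res.breakdown
        rows.append(
            {
                "strategy": sid,
                "meat_total": _round_int(bd.total("meat")),
                "recreational_total": _round_int(bd.total("recreational")),
                "browsing_total": _round_int(bd.total("browsing")),
                "traffic_total": _round_int(bd.total("traffic")),
                "net_benefit": _round_int(bd.net_benefit),
            }
        )
    return pd.DataFrame(rows)


def write_reports(result: PipelineResult, outdir: Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["population_harvest"] = outdir / "population_harvest.csv"
    population_harvest_report(result).to_csv(
        paths["population_harvest"], index=False
    )
    paths["value_components"] = outdir / "value_components.csv"
    value_components_report(result).to_csv(
        paths["value_components"], index=False
    )
    paths["sensitivity"] = outdir / "sensitivity.csv"
    result.sensitivity.round(0).astype(int).to_csv(paths["sensitivity"])
    summary = {
        "config": json.loads(
            result.config.model_dump_json(exclude={"output_dir"})
        ),
        "net_benefits": result.net_benefits,
        "september_populations": {
            sid: r.september_population for sid, r in result.results.items()
        },
        "recommendation": {
            "action": result.recommendation.action,
            "strategies": list(result.recommendation.strategies),
            "net_benefit": result.recommendation.net_benefit,
        },
        "sex_ratio_ok": {
            sid: r.sex_ratio.ok for sid, r in result.results.items()
        },
        "warnings": list(result.warnings),
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths
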