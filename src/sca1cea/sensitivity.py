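"""One-way deterministic sensitivity analysis and discount scenarios.

Each parameter is pushed, one at a time, to a low and a high value —
costs +/- 20% around the mean, utilities and the progression rate to
their 95% CI bounds — and the paired simulation (treatment arm vs usual
care, same master seed) is rerun in full.  Tornado rows are sorted by
swing, the absolute difference of the two resulting iNMBs.  The discount
scenario analysis reruns the pairing with alternative annual discount
rates for QALYs and costs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import STATE_NAMES, ConfigError, ModelConfig
from .econ import IncrementalResult, accrue_cohort, incremental, summarize
from .engine import USUAL_CARE, Strategy, run_cohort

__all__ = [
    "DsaSpec",
    "TornadoRow",
    "default_dsa_specs",
    "paired_incremental",
    "one_way_dsa",
    "discount_scenarios",
    "DEFAULT_SCENARIO_RATES",
]


@dataclass(frozen=True)
class DsaSpec:
    """One parameter excursion: name, kind, low/high values.

    Kinds: ``progression_mean`` (shift the rate-sampling mean, sd fixed),
    ``utility`` (one state's utility), ``cost`` (one state's annual cost),
    ``cost_all`` (all state costs scaled jointly by low/high factors).
    """

    name: str
    kind: str
    low: float
    high: float
    state: str | None = None
    base: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("progression_mean", "utility", "cost", "cost_all"):
            raise ValueError(f"unknown DSA parameter kind {self.kind!r}")
        if self.kind in ("utility", "cost") and self.state not in STATE_NAMES:
            raise ValueError(f"DSA spec {self.name!r}: needs a valid state, got {self.state!r}")
        if not self.low <= self.high:
            raise ValueError(f"DSA spec {self.name!r}: low {self.low} > high {self.high}")
        if self.base is not None and not self.low <= self.base <= self.high:
            raise ValueError(
                f"DSA spec {self.name!r}: base {self.base} outside [{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class TornadoRow:
    """iNMB at both excursions of one parameter; swing = |high - low|."""

    parameter: str
    low_value: float
    high_value: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


def default_dsa_specs(
    cfg: ModelConfig,
    cost_variation: float = 0.20,
    joint_costs: bool = False,
) -> list[DsaSpec]:
    """The tornado parameter set: progression rate at its CI bounds, each
    state utility with a published CI at its bounds, and per-state (or
    jointly scaled) annual costs at +/-20%.

    The pre-ataxic utility has no published CI and is excluded.
    """
    specs = [
        DsaSpec(
            "progression_rate",
            "progression_mean",
            cfg.progression.ci_low,
            cfg.progression.ci_high,
            base=cfg.progression.mean_rate,
        )
    ]
    for state in STATE_NAMES:
        if state in cfg.econ.utility_ci:
            lo, hi = cfg.econ.utility_ci[state]
            specs.append(
                DsaSpec(f"utility_{state}", "utility", lo, hi, state=state,
                        base=float(cfg.econ.utility[state]))
            )
    if joint_costs:
        specs.append(DsaSpec("cost_all_states", "cost_all",
                             1.0 - cost_variation, 1.0 + cost_variation, base=1.0))
    else:
        for state in STATE_NAMES:
            base = float(cfg.econ.annual_cost[state])
            specs.append(
                DsaSpec(f"cost_{state}", "cost",
                        base * (1.0 - cost_variation), base * (1.0 + cost_variation),
                        state=state, base=base)
            )
    return specs


def _apply_spec(cfg: ModelConfig, spec: DsaSpec, value: float) -> ModelConfig:
    if spec.kind == "progression_mean":
        return cfg.replace(progression=cfg.progression.shifted(value))
    if spec.kind == "utility":
        utility = dict(cfg.econ.utility)
        utility[spec.state] = value
        utility_ci = {k: v for k, v in cfg.econ.utility_ci.items() if k != spec.state}
        return cfg.replace(
            econ=cfg.econ.replace(utility=utility, utility_ci=utility_ci,
                                  validate_ordering=False)
        )
    if spec.kind == "cost":
        cost = dict(cfg.econ.annual_cost)
        cost[spec.state] = value
        return cfg.replace(econ=cfg.econ.replace(annual_cost=cost, validate_ordering=False))
    if spec.kind == "cost_all":
        cost = {k: v * value for k, v in cfg.econ.annual_cost.items()}
        return cfg.replace(econ=cfg.econ.replace(annual_cost=cost, validate_ordering=False))
    raise ValueError(f"unknown DSA parameter kind {spec.kind!r}")


def paired_incremental(cfg: ModelConfig, strategy: Strategy) -> IncrementalResult:
    """Full paired run: usual care and the strategy arm on the same seed."""
    usual_traces = run_cohort(cfg.settings, USUAL_CARE, cfg.progression, cfg.mortality, cfg.states)
    arm_traces = run_cohort(cfg.settings, strategy, cfg.progression, cfg.mortality, cfg.states)
    usual = summarize(accrue_cohort(usual_traces, cfg.econ), USUAL_CARE, seed=cfg.settings.seed)
    arm = summarize(accrue_cohort(arm_traces, cfg.econ), strategy, seed=cfg.settings.seed)
    return incremental(arm, usual, cfg.econ)


def one_way_dsa(
    specs: Sequence[DsaSpec],
    strategy: Strategy,
    cfg: ModelConfig,
) -> list[TornadoRow]:
    """Rerun the paired simulation at each spec's low and high value.

    Only the named parameter changes between reruns; the master seed (and
    hence every random draw) is held fixed, so swings measure parameter
    influence, not Monte-Carlo noise.  Rows come back sorted by
    descending swing (tornado order).
    """
    rows = []
    for spec in specs:
        inmb_low = paired_incremental(_apply_spec(cfg, spec, spec.low), strategy).inmb
        inmb_high = paired_incremental(_apply_spec(cfg, spec, spec.high), strategy).inmb
        rows.append(
            TornadoRow(
                parameter=spec.name,
                low_value=spec.low,
                high_value=spec.high,
                inmb_at_low=inmb_low,
                inmb_at_high=inmb_high,
            )
        )
    rows.sort(key=lambda r: r.swing, reverse=True)
    return rows


def tornado_frame(rows: Sequence[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low": [r.low_value for r in rows],
            "high": [r.high_value for r in rows],
            "inmb_low": [r.inmb_at_low for r in rows],
            "inmb_high": [r.inmb_at_high for r in rows],
            "swing": [r.swing for r in rows],
        }
    )


#: The discount-rate grid of the scenario analysis: base 1.5%/4%, plus 0%
#: and 5% for each of QALYs and costs.
DEFAULT_SCENARIO_RATES: tuple[tuple[float, float], ...] = (
    (0.015, 0.04),
    (0.00, 0.04),
    (0.05, 0.04),
    (0.015, 0.00),
    (0.015, 0.05),
    (0.00, 0.00),
    (0.05, 0.05),
)


def discount_scenarios(
    rates: Sequence[tuple[float, float]],
    strategy: Strategy,
    cfg: ModelConfig,
) -> pd.DataFrame:
    """iNMB of the strategy at each (QALY rate, cost rate) pair, same seed."""
    records = []
    for qaly_rate, cost_rate in rates:
        if qaly_rate < 0 or cost_rate < 0:
            raise ConfigError(f"discount rates must be >= 0, got ({qaly_rate}, {cost_rate})")
        scenario_cfg = cfg.replace(
            econ=cfg.econ.replace(discount_rate_qaly=qaly_rate, discount_rate_cost=cost_rate)
        )
        result = paired_incremental(scenario_cfg, strategy)
        records.append(
            {
                "qaly_rate": qaly_rate,
                "cost_rate": cost_rate,
                "delta_qalys": result.delta_qalys,
                "delta_costs": result.delta_costs,
                "inmb": result.inmb,
            }
        )
    return pd.DataFrame(records)
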