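"""Economic outcomes: discounted QALYs and costs, cohort summaries with
95% confidence intervals, incremental results and (yearly) net monetary
benefit.

Each lived cycle *t* (0-based; the entry year is undiscounted) accrues
``utility(state) / (1 + r_q)^t`` QALYs and ``cost(state) / (1 + r_c)^t``
euros.  The incremental net monetary benefit against usual care is
``iNMB = wtp * dQALY - dCost``; because therapy costs are not modelled,
the iNMB is the maximum total therapy price that would still be
cost-effective, and the yearly iNMB (divided by mean treatment years)
the maximum price per treated year.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Z_95, STATE_NAMES, EconParams
from .engine import PatientTrace, Strategy

__all__ = [
    "PatientOutcome",
    "CohortResult",
    "IncrementalResult",
    "accrue",
    "accrue_cohort",
    "summarize",
    "incremental",
]

_YIS_COLUMNS = [f"years_{name}" for name in STATE_NAMES]
#: Cohort quantities summarised with mean and 95% CI.
SUMMARY_COLUMNS = ["qalys", "costs", "survival_years", "treatment_years"] + _YIS_COLUMNS


@dataclass(frozen=True)
class PatientOutcome:
    """Discounted lifetime outcomes for one simulated individual."""

    patient_id: int
    qalys: float
    costs: float
    survival_years: float
    treatment_years: float
    years_in_state: Mapping[str, float]


def _discount_factors(rate: float, n: int) -> np.ndarray:
    if rate == 0.0:
        return np.ones(n)
    return (1.0 + rate) ** -np.arange(n, dtype=float)


def accrue(trace: PatientTrace, econ: EconParams) -> PatientOutcome:
    """Turn one trace into discounted QALYs, costs and time tallies."""
    n = trace.n_cycles
    if n == 0:
        return PatientOutcome(
            trace.patient_id, 0.0, 0.0, 0.0, 0.0, dict.fromkeys(STATE_NAMES, 0.0)
        )
    utilities = econ.utility_array[trace.state]
    costs = econ.cost_array[trace.state]
    qalys = float(utilities @ _discount_factors(econ.discount_rate_qaly, n))
    total_cost = float(costs @ _discount_factors(econ.discount_rate_cost, n))
    years = np.bincount(trace.state, minlength=len(STATE_NAMES)).astype(float)
    return PatientOutcome(
        patient_id=trace.patient_id,
        qalys=qalys,
        costs=total_cost,
        survival_years=float(n),
        treatment_years=float(trace.treatment_cycles),
        years_in_state=dict(zip(STATE_NAMES, years)),
    )


def accrue_cohort(traces: Iterable[PatientTrace], econ: EconParams) -> pd.DataFrame:
    """Per-patient outcome table (one row per individual).

    Vectorised equivalent of mapping :func:`accrue` over the cohort.
    """
    records = []
    dq = econ.discount_rate_qaly
    dc = econ.discount_rate_cost
    u_arr = econ.utility_array
    c_arr = econ.cost_array
    max_n = 0
    fq = fc = np.ones(0)
    for tr in traces:
        n = tr.n_cycles
        if n > max_n:
            max_n = max(2 * max_n, n)
            fq = _discount_factors(dq, max_n)
            fc = _discount_factors(dc, max_n)
        years = np.bincount(tr.state, minlength=len(STATE_NAMES))
        records.append(
            (
                tr.patient_id,
                float(u_arr[tr.state] @ fq[:n]),
                float(c_arr[tr.state] @ fc[:n]),
                float(n),
                float(tr.treatment_cycles),
                *years.astype(float),
            )
        )
    frame = pd.DataFrame.from_records(
        records,
        columns=["patient_id", "qalys", "costs", "survival_years", "treatment_years"]
        + _YIS_COLUMNS,
    )
    return frame.set_index("patient_id")


@dataclass(frozen=True)
class CohortResult:
    """Cohort means and 95% CIs, keeping the per-patient table for pairing."""

    strategy: str
    effectiveness: float
    n: int
    seed: int | None
    stats: Mapping[str, tuple[float, float, float]]  # quantity -> (mean, lo, hi)
    outcomes: pd.DataFrame = field(repr=False)

    def mean(self, quantity: str) -> float:
        return self.stats[quantity][0]

    def ci(self, quantity: str) -> tuple[float, float]:
        return self.stats[quantity][1:]


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, float("nan"), float("nan")
    half = Z_95 * float(np.std(values, ddof=1)) / np.sqrt(len(values))
    return mean, mean - half, mean + half


def summarize(
    outcomes: pd.DataFrame | Sequence[PatientOutcome],
    strategy: str | Strategy = "",
    effectiveness: float | None = None,
    seed: int | None = None,
) -> CohortResult:
    """Aggregate per-patient outcomes to means with normal-approximation
    95% CIs (mean +/- 1.959964 * sd / sqrt(n))."""
    if not isinstance(outcomes, pd.DataFrame):
        outcomes = pd.DataFrame(
            [
                {
                    "patient_id": o.patient_id,
                    "qalys": o.qalys,
                    "costs": o.costs,
                    "survival_years": o.survival_years,
                    "treatment_years": o.treatment_years,
                    **{f"years_{k}": v for k, v in o.years_in_state.items()},
                }
                for o in outcomes
            ]
        ).set_index("patient_id")
    if outcomes.empty:
        raise ValueError("cannot summarise an empty cohort")
    if isinstance(strategy, Strategy):
        if effectiveness is None:
            effectiveness = strategy.effectiveness
        strategy = strategy.name
    stats = {col: _mean_ci(outcomes[col].to_numpy()) for col in SUMMARY_COLUMNS}
    return CohortResult(
        strategy=strategy,
        effectiveness=float("nan") if effectiveness is None else effectiveness,
        n=len(outcomes),
        seed=seed,
        stats=stats,
        outcomes=outcomes,
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Paired contrast of a treatment arm against usual care.

    CIs are paired per-patient differences under common random numbers.
    ``yearly_inmb`` divides the total iNMB by the arm's mean treatment
    years (NaN if the arm involves no treatment).
    """

    strategy: str
    effectiveness: float
    delta_costs: float
    delta_qalys: float
    delta_survival_years: float
    inmb: float
    yearly_inmb: float
    delta_costs_ci: tuple[float, float]
    delta_qalys_ci: tuple[float, float]
    delta_survival_ci: tuple[float, float]
    inmb_ci: tuple[float, float]


def incremental(
    arm: CohortResult, usual_care: CohortResult, econ: EconParams
) -> IncrementalResult:
    """Pairwise incremental outcomes and (yearly) net monetary benefit."""
    if arm.n != usual_care.n:
        raise ValueError(
            f"mismatched cohort sizes: {arm.n} vs {usual_care.n} — arms must "
            "share the simulated cohort"
        )
    if arm.seed is not None and usual_care.seed is not None and arm.seed != usual_care.seed:
        raise ValueError(
            f"mismatched seeds: {arm.seed} vs {usual_care.seed} — arms must be "
            "run under common random numbers"
        )
    if not arm.outcomes.index.equals(usual_care.outcomes.index):
        raise ValueError("patient indices differ between arms")

    dq = arm.outcomes["qalys"].to_numpy() - usual_care.outcomes["qalys"].to_numpy()
    dc = arm.outcomes["costs"].to_numpy() - usual_care.outcomes["costs"].to_numpy()
    ds = (
        arm.outcomes["survival_years"].to_numpy()
        - usual_care.outcomes["survival_years"].to_numpy()
    )
    inmb_per_patient = econ.wtp_threshold * dq - dc

    dq_mean, dq_lo, dq_hi = _mean_ci(dq)
    dc_mean, dc_lo, dc_hi = _mean_ci(dc)
    ds_mean, ds_lo, ds_hi = _mean_ci(ds)
    inmb_mean, inmb_lo, inmb_hi = _mean_ci(inmb_per_patient)

    treatment_years = arm.mean("treatment_years")
    yearly = inmb_mean / treatment_years if treatment_years > 0 else float("nan")

    return IncrementalResult(
        strategy=arm.strategy,
        effectiveness=arm.effectiveness,
        delta_costs=dc_mean,
        delta_qalys=dq_mean,
        delta_survival_years=ds_mean,
        inmb=inmb_mean,
        yearly_inmb=yearly,
        delta_costs_ci=(dc_lo, dc_hi),
        delta_qalys_ci=(dq_lo, dq_hi),
        delta_survival_ci=(ds_lo, ds_hi),
        inmb_ci=(inmb_lo, inmb_hi),
    )
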