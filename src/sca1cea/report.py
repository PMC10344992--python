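"""Run orchestration and report rendering.

``run_grid`` simulates usual care plus every requested strategy at every
effectiveness level on one shared cohort and tabulates absolute and
incremental outcomes.  Plot helpers render the standard figures: survival
curves per strategy, mean time per health state, (yearly) iNMB against
effectiveness, and the DSA tornado.  A ``RunManifest`` records everything
needed to reproduce a run byte-for-byte.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .config import STATE_NAMES, ModelConfig
from .econ import CohortResult, accrue_cohort, incremental, summarize
from .engine import USUAL_CARE, PatientTrace, Strategy, paper_strategies, run_cohort
from .sensitivity import TornadoRow

__all__ = [
    "DEFAULT_EFFECTIVENESS_GRID",
    "RunManifest",
    "run_strategy_arm",
    "run_grid",
    "plot_survival_curves",
    "plot_time_in_state",
    "plot_inmb_curves",
    "plot_tornado",
]

#: 5% to 50% in steps of 5%.
DEFAULT_EFFECTIVENESS_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 11)
)

_STRATEGY_LOOKUP = {s.name: s for s in paper_strategies()}


def strategy_by_name(name: str) -> Strategy:
    """Resolve one of the five named treatment strategies (effectiveness 0)."""
    if name == USUAL_CARE.name:
        return USUAL_CARE
    if name not in _STRATEGY_LOOKUP:
        raise KeyError(
            f"unknown strategy {name!r}; known: {sorted(_STRATEGY_LOOKUP)}"
        )
    return _STRATEGY_LOOKUP[name]


@dataclass(frozen=True)
class RunManifest:
    """Everything that determines a run's outputs."""

    seed: int
    n_patients: int
    strategies: tuple[str, ...] = tuple(_STRATEGY_LOOKUP)
    effectiveness_grid: tuple[float, ...] = DEFAULT_EFFECTIVENESS_GRID
    config_path: str | None = None
    out_dir: str = "results"
    version: str = ""

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "n_patients": self.n_patients,
                    "strategies": list(self.strategies),
                    "effectiveness_grid": [float(e) for e in self.effectiveness_grid],
                    "config_path": self.config_path,
                    "out_dir": self.out_dir,
                    "version": self.version,
                },
                fh,
                sort_keys=False,
            )
        return path

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunManifest":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=int(raw["seed"]),
            n_patients=int(raw["n_patients"]),
            strategies=tuple(raw.get("strategies", list(_STRATEGY_LOOKUP))),
            effectiveness_grid=tuple(raw.get("effectiveness_grid", DEFAULT_EFFECTIVENESS_GRID)),
            config_path=raw.get("config_path"),
            out_dir=raw.get("out_dir", "results"),
            version=raw.get("version", ""),
        )


def run_strategy_arm(
    cfg: ModelConfig, strategy: Strategy
) -> tuple[list[PatientTrace], CohortResult]:
    """Simulate and summarise one arm."""
    traces = run_cohort(cfg.settings, strategy, cfg.progression, cfg.mortality, cfg.states)
    result = summarize(accrue_cohort(traces, cfg.econ), strategy, seed=cfg.settings.seed)
    return traces, result


def _result_row(result: CohortResult, inc=None) -> dict:
    row = {
        "strategy": result.strategy,
        "effectiveness": result.effectiveness,
        "mean_costs": result.mean("costs"),
        "mean_qalys": result.mean("qalys"),
        "mean_survival_years": result.mean("survival_years"),
        "mean_treatment_years": result.mean("treatment_years"),
        "qalys_ci_low": result.ci("qalys")[0],
        "qalys_ci_high": result.ci("qalys")[1],
        "survival_ci_low": result.ci("survival_years")[0],
        "survival_ci_high": result.ci("survival_years")[1],
    }
    for name in STATE_NAMES:
        row[f"mean_years_{name}"] = result.mean(f"years_{name}")
    if inc is None:
        row.update(
            incremental_costs=float("nan"),
            incremental_qalys=float("nan"),
            incremental_survival_years=float("nan"),
            inmb=float("nan"),
            yearly_inmb=float("nan"),
        )
    else:
        row.update(
            incremental_costs=inc.delta_costs,
            incremental_qalys=inc.delta_qalys,
            incremental_survival_years=inc.delta_survival_years,
            inmb=inc.inmb,
            yearly_inmb=inc.yearly_inmb,
        )
    return row


def run_grid(
    cfg: ModelConfig,
    strategies: Sequence[Strategy] | None = None,
    effectiveness_grid: Sequence[float] = DEFAULT_EFFECTIVENESS_GRID,
    keep_traces: bool = False,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict[str, list[PatientTrace]]]:
    """Usual care plus every strategy x effectiveness level, one cohort.

    Returns the results table (one row per arm; usual care first with NaN
    incrementals) and, if requested, the traces of usual care and of each
    strategy at the highest effectiveness level (for plotting).
    """
    if strategies is None:
        strategies = paper_strategies()
    traces_out: dict[str, list[PatientTrace]] = {}

    usual_traces, usual = run_strategy_arm(cfg, USUAL_CARE)
    if keep_traces:
        traces_out[USUAL_CARE.name] = usual_traces
    rows = [_result_row(usual)]

    top_level = max(effectiveness_grid) if len(effectiveness_grid) else None
    for base in strategies:
        for eff in effectiveness_grid:
            arm_strategy = base.with_effectiveness(eff)
            traces, result = run_strategy_arm(cfg, arm_strategy)
            inc = incremental(result, usual, cfg.econ)
            rows.append(_result_row(result, inc))
            if keep_traces and eff == top_level:
                traces_out[base.name] = traces
            if progress:
                print(f"  arm {base.name} @ {eff:.0%}: iNMB = {inc.inmb:,.0f}")
    return pd.DataFrame(rows), traces_out


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def _alive_fraction(traces: Sequence[PatientTrace]) -> np.ndarray:
    horizon = max(t.n_cycles for t in traces) + 1
    alive = np.zeros(horizon)
    for t in traces:
        alive[: t.n_cycles] += 1
    return alive / len(traces)


def plot_survival_curves(
    traces_by_strategy: Mapping[str, Sequence[PatientTrace]], path: Path | str
) -> Path:
    """Fraction of the cohort alive against model year, per strategy."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, traces in traces_by_strategy.items():
        frac = _alive_fraction(traces)
        ax.step(np.arange(len(frac)), frac, where="post", label=name)
    ax.set_xlabel("years since model entry")
    ax.set_ylabel("fraction alive")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_time_in_state(results: pd.DataFrame, path: Path | str) -> Path:
    """Mean years per health state, grouped bars per arm."""
    cols = [f"mean_years_{name}" for name in STATE_NAMES]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = 0.8 / len(results)
    x = np.arange(len(STATE_NAMES))
    for i, (_, row) in enumerate(results.iterrows()):
        eff = row["effectiveness"]
        label = row["strategy"] if pd.isna(eff) else f"{row['strategy']} @ {eff:.0%}"
        ax.bar(x + i * width, [row[c] for c in cols], width, label=label)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(["PR", "SL", "MO", "SE", "ES"])
    ax.set_ylabel("mean years in state")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_inmb_curves(
    results: pd.DataFrame, path: Path | str, yearly: bool = True
) -> Path:
    """(Yearly) iNMB against effectiveness level, one curve per strategy."""
    col = "yearly_inmb" if yearly else "inmb"
    fig, ax = plt.subplots(figsize=(7, 4.5))
    arms = results.dropna(subset=["effectiveness"])
    for name, group in arms.groupby("strategy", sort=False):
        group = group.sort_values("effectiveness")
        ax.plot(group["effectiveness"] * 100, group[col], marker="o", ms=3, label=name)
    ax.set_xlabel("treatment effectiveness (%)")
    ax.set_ylabel("iNMB per treatment year (EUR)" if yearly else "total iNMB (EUR)")
    ax.axhline(0, color="0.6", lw=0.8)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_tornado(
    rows: Sequence[TornadoRow], base_inmb: float, path: Path | str
) -> Path:
    """Tornado diagram: largest swing at the top, bars around the base iNMB."""
    fig, ax = plt.subplots(figsize=(7, 0.5 + 0.45 * max(len(rows), 1)))
    ordered = sorted(rows, key=lambda r: r.swing)  # largest plotted last = top
    for y, row in enumerate(ordered):
        lo = min(row.inmb_at_low, row.inmb_at_high)
        hi = max(row.inmb_at_low, row.inmb_at_high)
        ax.barh(y, hi - lo, left=lo, color="#4477aa", height=0.6)
    ax.axvline(base_inmb, color="k", lw=1)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([r.parameter for r in ordered], fontsize=8)
    ax.set_xlabel("iNMB (EUR)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
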