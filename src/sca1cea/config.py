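"""Model parameters as validated domain types, plus config-file I/O.

Every other module of the package is parameter-driven: health-state
definitions on the SARA scale, the SCA1 progression-rate distribution,
nomogram-derived mortality inputs, per-state utilities and annual costs,
discount rates, the willingness-to-pay threshold, and simulation settings
all live here.  Parameters are read from a single YAML file that may
reference CSV tables (cost line items, the 5-year-survival table), and the
package ships a bundled default configuration.

Monetary amounts are handled as exact decimals (cents) at the config layer
and converted to floating point only when they enter the simulation.
"""
from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Z_95",
    "STATE_NAMES",
    "SARA_MIN",
    "SARA_MAX",
    "DEFAULT_BOUNDARIES",
    "ConfigError",
    "StateDefinition",
    "make_states",
    "validate_states",
    "ProgressionParams",
    "MortalityParams",
    "EconParams",
    "CostItem",
    "SimulationSettings",
    "ModelConfig",
    "build_cost_table",
    "read_cost_items_csv",
    "load_model_config",
    "write_model_config",
    "default_config",
    "default_data_dir",
]

#: Two-sided 95% normal quantile used throughout for confidence intervals.
Z_95 = 1.959964

#: Living health states, ordered by increasing severity.
STATE_NAMES = ("pre_ataxic", "slight", "moderate", "severe", "end_stage")

SARA_MIN = 0.0
SARA_MAX = 40.0

#: SARA cut-offs between consecutive living states.
DEFAULT_BOUNDARIES = (2.0, 14.0, 26.0, 34.0)

_CENT = Decimal("0.01")

_DATA_DIR = Path(__file__).resolve().parent / "data"


class ConfigError(ValueError):
    """A configuration value violates the model's contract."""


def default_data_dir() -> Path:
    """Directory holding the bundled default configuration files."""
    return _DATA_DIR


# ---------------------------------------------------------------------------
# Health states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateDefinition:
    """One living health state bound to a half-open SARA interval.

    A state is occupied when ``sara_low < SARA <= sara_high``, except the
    first (pre-ataxic) state, which is closed below: ``0 <= SARA <= 2``.
    """

    name: str
    sara_low: float
    sara_high: float

    def __post_init__(self) -> None:
        if self.name not in STATE_NAMES:
            raise ConfigError(f"unknown state name {self.name!r}")
        if not self.sara_low < self.sara_high:
            raise ConfigError(
                f"state {self.name!r}: sara_low ({self.sara_low}) must be "
                f"< sara_high ({self.sara_high})"
            )

    def contains(self, sara: float) -> bool:
        if self.sara_low == SARA_MIN:
            return self.sara_low <= sara <= self.sara_high
        return self.sara_low < sara <= self.sara_high


def make_states(
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> tuple[StateDefinition, ...]:
    """Build the five living states from the four interior SARA cut-offs."""
    if len(boundaries) != len(STATE_NAMES) - 1:
        raise ConfigError(
            f"states.boundaries: expected {len(STATE_NAMES) - 1} cut-offs, "
            f"got {len(boundaries)}"
        )
    edges = (SARA_MIN, *map(float, boundaries), SARA_MAX)
    states = tuple(
        StateDefinition(name, edges[i], edges[i + 1])
        for i, name in enumerate(STATE_NAMES)
    )
    validate_states(states)
    return states


def validate_states(states: Sequence[StateDefinition]) -> None:
    """Check that the five intervals partition [0, 40] without gaps."""
    if tuple(s.name for s in states) != STATE_NAMES:
        raise ConfigError(
            "states must be the five canonical states in order "
            f"{STATE_NAMES}, got {tuple(s.name for s in states)}"
        )
    if states[0].sara_low != SARA_MIN or states[-1].sara_high != SARA_MAX:
        raise ConfigError("state intervals must span [0, 40]")
    for left, right in zip(states, states[1:]):
        if left.sara_high != right.sara_low:
            raise ConfigError(
                f"state intervals must partition [0, 40]: {left.name} ends at "
                f"{left.sara_high} but {right.name} starts at {right.sara_low}"
            )


DEFAULT_STATES = make_states()


# ---------------------------------------------------------------------------
# Progression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgressionParams:
    """Meta-analytic annual SARA progression rate with its 95% CI.

    The per-patient rate is drawn from ``Normal(mean_rate, sd)`` where the
    standard deviation is back-solved from the confidence interval:
    ``sd = (ci_high - ci_low) / (2 * 1.959964)``.
    """

    mean_rate: float = 1.83
    ci_low: float = 1.45
    ci_high: float = 2.21

    def __post_init__(self) -> None:
        if not self.mean_rate > 0:
            raise ConfigError(f"progression.mean_rate must be > 0, got {self.mean_rate}")
        if not self.ci_low <= self.mean_rate <= self.ci_high:
            raise ConfigError(
                "progression: ci_low <= mean_rate <= ci_high required, got "
                f"({self.ci_low}, {self.mean_rate}, {self.ci_high})"
            )

    @property
    def sd(self) -> float:
        """Sampling standard deviation implied by the 95% CI."""
        return (self.ci_high - self.ci_low) / (2.0 * Z_95)

    def shifted(self, new_mean: float) -> "ProgressionParams":
        """Translate mean and CI together, keeping the implied sd fixed."""
        delta = new_mean - self.mean_rate
        return ProgressionParams(
            mean_rate=self.mean_rate + delta,
            ci_low=self.ci_low + delta,
            ci_high=self.ci_high + delta,
        )


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityParams:
    """Inputs for per-cycle death probabilities.

    Below ``background_below_sara`` (SARA 14) an annual background
    probability applies.  From SARA 14 up, a 5-year survival probability is
    interpolated linearly in ``survival5yr_table`` and converted to an
    annual probability via ``p = 1 - S5**(1/5)``.  At
    ``certain_death_sara`` (SARA 40) death is certain within one cycle.

    The bundled default table is a synthetic, calibrated stand-in for a
    published survival nomogram (see :mod:`sca1cea.synthetic`), not measured
    survival data.
    """

    sara_grid: np.ndarray
    survival_5yr: np.ndarray
    background_annual_prob: float = 1e-3
    background_below_sara: float = 14.0
    certain_death_sara: float = 40.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.sara_grid, dtype=float)
        s5 = np.asarray(self.survival_5yr, dtype=float)
        object.__setattr__(self, "sara_grid", grid)
        object.__setattr__(self, "survival_5yr", s5)
        if grid.ndim != 1 or grid.shape != s5.shape or grid.size < 2:
            raise ConfigError("mortality.survival5yr_table: need >= 2 (sara, S5) pairs")
        if not np.all(np.diff(grid) > 0):
            raise ConfigError("mortality.survival5yr_table: SARA knots must be strictly increasing")
        if np.any(s5 < 0) or np.any(s5 > 1):
            raise ConfigError("mortality.survival5yr_table: survival values must lie in [0, 1]")
        if np.any(np.diff(s5) > 0):
            raise ConfigError("mortality.survival5yr_table: 5-year survival must be non-increasing in SARA")
        if not 0.0 <= self.background_annual_prob <= 1.0:
            raise ConfigError(
                f"mortality.background_annual_prob must be in [0, 1], got {self.background_annual_prob}"
            )
        if grid[0] > self.background_below_sara:
            raise ConfigError(
                f"mortality.survival5yr_table must cover SARA >= {self.background_below_sara}; "
                f"first knot is {grid[0]}"
            )
        if grid[-1] < self.certain_death_sara:
            raise ConfigError(
                f"mortality.survival5yr_table must extend to SARA {self.certain_death_sara}; "
                f"last knot is {grid[-1]}"
            )
        # plain-python copies for fast scalar interpolation in the engine
        object.__setattr__(self, "_grid_list", grid.tolist())
        object.__setattr__(self, "_s5_list", s5.tolist())

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], **kwargs: float
    ) -> "MortalityParams":
        pairs = sorted((float(s), float(v)) for s, v in pairs)
        grid = np.array([p[0] for p in pairs])
        s5 = np.array([p[1] for p in pairs])
        return cls(sara_grid=grid, survival_5yr=s5, **kwargs)

    @classmethod
    def from_csv(cls, path: Path | str, **kwargs: float) -> "MortalityParams":
        """Read a ``sara,survival_5yr`` CSV table."""
        path = Path(path)
        pairs = []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"sara", "survival_5yr"} <= set(reader.fieldnames):
                raise ConfigError(
                    f"{path}: survival table needs columns 'sara,survival_5yr'"
                )
            for row in reader:
                pairs.append((float(row["sara"]), float(row["survival_5yr"])))
        return cls.from_pairs(pairs, **kwargs)


# ---------------------------------------------------------------------------
# Economics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EconParams:
    """Per-state utilities and annual costs, discount rates and threshold.

    ``utility_ci`` may omit states whose utility has no published
    uncertainty (the pre-ataxic population-norm value by default).
    ``validate_ordering`` exists so one-way sensitivity excursions to CI
    bounds are not rejected; the base case keeps it on.
    """

    utility: Mapping[str, float]
    annual_cost: Mapping[str, float]
    utility_ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    discount_rate_qaly: float = 0.015
    discount_rate_cost: float = 0.04
    wtp_threshold: float = 80_000.0
    validate_ordering: bool = True

    def __post_init__(self) -> None:
        for table_name, table in (("utility_per_state", self.utility),
                                  ("annual_cost_per_state", self.annual_cost)):
            missing = set(STATE_NAMES) - set(table)
            if missing:
                raise ConfigError(f"{table_name}: missing states {sorted(missing)}")
        for name, u in self.utility.items():
            if not 0.0 <= float(u) <= 1.0:
                raise ConfigError(f"utility_per_state[{name!r}] = {u} outside [0, 1]")
        for name, c in self.annual_cost.items():
            if float(c) < 0.0:
                raise ConfigError(f"annual_cost_per_state[{name!r}] = {c} is negative")
        for name, (lo, hi) in self.utility_ci.items():
            if name not in STATE_NAMES:
                raise ConfigError(f"utility_ci: unknown state {name!r}")
            if not lo <= float(self.utility[name]) <= hi:
                raise ConfigError(
                    f"utility_ci[{name!r}] = ({lo}, {hi}) does not contain the "
                    f"point value {self.utility[name]}"
                )
        for key, rate in (("discount_rate_qaly", self.discount_rate_qaly),
                          ("discount_rate_cost", self.discount_rate_cost)):
            if rate < 0:
                raise ConfigError(f"{key} must be >= 0, got {rate}")
        if self.wtp_threshold <= 0:
            raise ConfigError(f"wtp_threshold must be > 0, got {self.wtp_threshold}")
        if self.validate_ordering:
            u = [float(self.utility[n]) for n in STATE_NAMES]
            if any(a < b for a, b in zip(u, u[1:])):
                raise ConfigError(
                    "utility_per_state must be non-increasing from pre_ataxic "
                    f"to end_stage, got {u}"
                )
            c = [float(self.annual_cost[n]) for n in STATE_NAMES]
            if any(a > b for a, b in zip(c, c[1:])):
                raise ConfigError(
                    "annual_cost_per_state must be non-decreasing from "
                    f"pre_ataxic to end_stage, got {c}"
                )

    @property
    def utility_array(self) -> np.ndarray:
        """Utilities as a float vector in state order."""
        return np.array([float(self.utility[n]) for n in STATE_NAMES])

    @property
    def cost_array(self) -> np.ndarray:
        """Annual costs as a float vector in state order."""
        return np.array([float(self.annual_cost[n]) for n in STATE_NAMES])

    def replace(self, **changes) -> "EconParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CostItem:
    """One resource line of the per-state annual cost table.

    The weighted annual cost is ``unit_cost * annual_use *
    fraction_of_patients``; only a fraction of patients in a state may use
    a resource (e.g. home care).
    """

    resource: str
    state: str
    unit_cost: Decimal
    annual_use: Decimal
    fraction_of_patients: Decimal

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_cost", Decimal(str(self.unit_cost)))
        object.__setattr__(self, "annual_use", Decimal(str(self.annual_use)))
        object.__setattr__(self, "fraction_of_patients", Decimal(str(self.fraction_of_patients)))
        if self.state not in STATE_NAMES:
            raise ConfigError(f"cost item {self.resource!r}: unknown state {self.state!r}")
        if self.unit_cost < 0:
            raise ConfigError(f"cost item {self.resource!r}: negative unit_cost")
        if self.annual_use < 0:
            raise ConfigError(f"cost item {self.resource!r}: negative annual_use")
        if not Decimal(0) <= self.fraction_of_patients <= Decimal(1):
            raise ConfigError(
                f"cost item {self.resource!r}: fraction_of_patients outside [0, 1]"
            )

    @property
    def weighted_annual_cost(self) -> Decimal:
        return self.unit_cost * self.annual_use * self.fraction_of_patients


def build_cost_table(
    items: Iterable[CostItem],
    states: Sequence[str] = STATE_NAMES,
) -> dict[str, Decimal]:
    """Sum weighted line items into per-state annual costs (exact cents).

    Line items are summed unrounded; only the per-state total is rounded,
    half-up, to the cent.  States with no items total 0.00.
    """
    totals: dict[str, Decimal] = {name: Decimal(0) for name in states}
    for item in items:
        if item.state not in totals:
            raise ConfigError(f"cost item {item.resource!r}: state {item.state!r} not requested")
        totals[item.state] += item.weighted_annual_cost
    return {name: t.quantize(_CENT, rounding=ROUND_HALF_UP) for name, t in totals.items()}


def read_cost_items_csv(path: Path | str) -> list[CostItem]:
    """Read a ``resource,state,unit_cost,annual_use,fraction`` CSV table."""
    path = Path(path)
    required = {"resource", "state", "unit_cost", "annual_use", "fraction"}
    items = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"{path}: cost table needs columns {sorted(required)}")
        for row in reader:
            items.append(
                CostItem(
                    resource=row["resource"],
                    state=row["state"],
                    unit_cost=Decimal(row["unit_cost"]),
                    annual_use=Decimal(row["annual_use"]),
                    fraction_of_patients=Decimal(row["fraction"]),
                )
            )
    return items


# ---------------------------------------------------------------------------
# Simulation settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSettings:
    """Cohort size, cycle length and master seed.

    The horizon is lifetime: every simulated individual is followed until
    death.  The cycle is fixed at one year, matching the yearly SARA
    progression increment and annual discounting.
    """

    n_patients: int = 10_000
    cycle_length: float = 1.0
    seed: int = 2023
    max_cycles: int = 100_000

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"simulation.n_patients must be >= 1, got {self.n_patients}")
        if self.cycle_length != 1.0:
            raise ConfigError("simulation.cycle_length is fixed at 1 year")
        if self.max_cycles < 1:
            raise ConfigError("simulation.max_cycles must be >= 1")

    def replace(self, **changes) -> "SimulationSettings":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Whole-model config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """All parameters needed to run the model, as one validated bundle."""

    states: tuple[StateDefinition, ...]
    progression: ProgressionParams
    mortality: MortalityParams
    econ: EconParams
    settings: SimulationSettings

    def __iter__(self):
        return iter((self.states, self.progression, self.mortality, self.econ, self.settings))

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {context}.{key}" if context else
                          f"missing required key {key}")
    return mapping[key]


def load_model_config(path: Path | str) -> ModelConfig:
    """Load and validate a model configuration.

    The YAML file may reference CSV tables (cost line items, survival
    table) by paths relative to its own location.  Omitted optional keys
    fall back to the documented defaults; validation errors name the
    offending key.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent

    states = make_states(tuple(raw.get("states", {}).get("boundaries", DEFAULT_BOUNDARIES)))

    prog_raw = raw.get("progression", {})
    progression = ProgressionParams(
        mean_rate=float(prog_raw.get("mean_rate", 1.83)),
        ci_low=float(prog_raw.get("ci_low", 1.45)),
        ci_high=float(prog_raw.get("ci_high", 2.21)),
    )

    mort_raw = _require(raw, "mortality", "")
    table_ref = _require(mort_raw, "survival_table", "mortality")
    mortality = MortalityParams.from_csv(
        base / table_ref,
        background_annual_prob=float(mort_raw.get("background_annual_prob", 1e-3)),
        background_below_sara=float(mort_raw.get("background_below_sara", 14.0)),
        certain_death_sara=float(mort_raw.get("certain_death_sara", 40.0)),
    )

    util_raw = _require(raw, "utilities", "")
    utility: dict[str, float] = {}
    utility_ci: dict[str, tuple[float, float]] = {}
    for name in STATE_NAMES:
        entry = _require(util_raw, name, "utilities")
        if isinstance(entry, Mapping):
            value = float(_require(entry, "value", f"utilities.{name}"))
            if "ci_low" in entry or "ci_high" in entry:
                utility_ci[name] = (
                    float(_require(entry, "ci_low", f"utilities.{name}")),
                    float(_require(entry, "ci_high", f"utilities.{name}")),
                )
        else:
            value = float(entry)
        utility[name] = value

    costs_raw = _require(raw, "costs", "")
    if "table" in costs_raw:
        items = read_cost_items_csv(base / costs_raw["table"])
        cost_totals = build_cost_table(items)
    elif "per_state" in costs_raw:
        cost_totals = {
            name: Decimal(str(_require(costs_raw["per_state"], name, "costs.per_state")))
            for name in STATE_NAMES
        }
    else:
        raise ConfigError("costs: need either 'table' (CSV path) or 'per_state' mapping")

    disc_raw = raw.get("discounting", {})
    econ = EconParams(
        utility=utility,
        utility_ci=utility_ci,
        annual_cost={name: float(v) for name, v in cost_totals.items()},
        discount_rate_qaly=float(disc_raw.get("qaly_rate", 0.015)),
        discount_rate_cost=float(disc_raw.get("cost_rate", 0.04)),
        wtp_threshold=float(raw.get("wtp_threshold", 80_000.0)),
    )

    sim_raw = raw.get("simulation", {})
    settings = SimulationSettings(
        n_patients=int(sim_raw.get("n_patients", 10_000)),
        cycle_length=float(sim_raw.get("cycle_length", 1.0)),
        seed=int(sim_raw.get("seed", 2023)),
        max_cycles=int(sim_raw.get("max_cycles", 100_000)),
    )

    return ModelConfig(states, progression, mortality, econ, settings)


def write_model_config(cfg: ModelConfig, path: Path | str) -> Path:
    """Write a config to YAML (+ survival CSV) that reloads identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    survival_name = path.stem + "_survival_5yr.csv"
    with (path.parent / survival_name).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sara", "survival_5yr"])
        for s, v in zip(cfg.mortality.sara_grid, cfg.mortality.survival_5yr):
            writer.writerow([repr(float(s)), repr(float(v))])
    doc = {
        "states": {"boundaries": [float(s.sara_high) for s in cfg.states[:-1]]},
        "progression": {
            "mean_rate": cfg.progression.mean_rate,
            "ci_low": cfg.progression.ci_low,
            "ci_high": cfg.progression.ci_high,
        },
        "mortality": {
            "survival_table": survival_name,
            "background_annual_prob": cfg.mortality.background_annual_prob,
            "background_below_sara": cfg.mortality.background_below_sara,
            "certain_death_sara": cfg.mortality.certain_death_sara,
        },
        "utilities": {
            name: (
                {"value": float(cfg.econ.utility[name]),
                 "ci_low": cfg.econ.utility_ci[name][0],
                 "ci_high": cfg.econ.utility_ci[name][1]}
                if name in cfg.econ.utility_ci
                else {"value": float(cfg.econ.utility[name])}
            )
            for name in STATE_NAMES
        },
        "costs": {"per_state": {name: float(cfg.econ.annual_cost[name]) for name in STATE_NAMES}},
        "discounting": {
            "qaly_rate": cfg.econ.discount_rate_qaly,
            "cost_rate": cfg.econ.discount_rate_cost,
        },
        "wtp_threshold": cfg.econ.wtp_threshold,
        "simulation": {
            "n_patients": cfg.settings.n_patients,
            "cycle_length": cfg.settings.cycle_length,
            "seed": cfg.settings.seed,
            "max_cycles": cfg.settings.max_cycles,
        },
    }
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def default_config() -> ModelConfig:
    """Load the bundled default configuration."""
    return load_model_config(_DATA_DIR / "model.yaml")
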