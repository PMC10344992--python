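"""Synthetic study inputs: a EUROSCA-like visit dataset and a stand-in
5-year-survival table.

Two inputs of the pipeline are not printed in any table and must be
supplied by the user or generated here:

* a visit-level EQ-5D-3L dataset with the statistical structure of the
  EUROSCA SCA1 extract (117 patients, 479 visits split 186/193/77/23 over
  the slight/moderate/severe/end-stage states) used to derive per-state
  utilities; and
* the 5-year-survival-by-SARA lookup standing in for the published
  survival nomogram.  The bundled default table is *synthetic*: a smooth
  monotone family whose shape parameter is calibrated so that the
  usual-care cohort's mean survival from simulation start reproduces the
  reported 16.59 years.  Every downstream result that depends on
  nomogram mortality is therefore conditional on this stand-in.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    DEFAULT_STATES,
    STATE_NAMES,
    ModelConfig,
    MortalityParams,
    ProgressionParams,
    SimulationSettings,
    StateDefinition,
)
from .engine import USUAL_CARE, run_cohort
from .eq5d import (
    Eq5dProfile,
    ValueSet,
    VisitRecord,
    all_profiles,
    eq5d_index,
    load_dutch_valueset,
)

__all__ = [
    "VisitGenSpec",
    "SurvivalGenSpec",
    "generate_visits",
    "generate_survival_table",
    "survival_table_to_csv",
    "calibrate_survival_shape",
    "DEFAULT_VISIT_TARGETS",
    "DEFAULT_VISIT_COUNTS",
]

#: Per-state target mean utilities and sd emulating the EUROSCA extract.
#: The sds are back-solved from the reported per-state 95% CIs
#: (half-width * sqrt(n) / 1.96).
DEFAULT_VISIT_TARGETS: dict[str, tuple[float, float]] = {
    "slight": (0.74, 0.174),
    "moderate": (0.65, 0.177),
    "severe": (0.38, 0.291),
    "end_stage": (0.16, 0.245),
}

#: Per-state visit counts of the source extract.
DEFAULT_VISIT_COUNTS: dict[str, int] = {
    "slight": 186,
    "moderate": 193,
    "severe": 77,
    "end_stage": 23,
}


@dataclass(frozen=True)
class VisitGenSpec:
    """Recipe for a synthetic visit-level EQ-5D-3L dataset.

    ``targets`` maps state name to (mean utility, sd); ``counts`` gives
    visits per state.  Visits are assigned to ``n_patients`` patients
    round-robin (no within-patient correlation) unless
    ``cluster_sd`` adds a shared per-patient utility shift.
    """

    targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_TARGETS)
    )
    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_VISIT_COUNTS))
    n_patients: int = 117
    seed: int = 0
    cluster_sd: float = 0.0

    def __post_init__(self) -> None:
        unknown = (set(self.targets) | set(self.counts)) - set(STATE_NAMES)
        if unknown:
            raise ValueError(f"unknown states {sorted(unknown)}")
        if set(self.counts) - set(self.targets):
            raise ValueError("every state with visits needs a target (mean, sd)")
        for name, count in self.counts.items():
            if count < 0:
                raise ValueError(f"counts[{name!r}] must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")

    @property
    def total_visits(self) -> int:
        return sum(self.counts.values())


def generate_visits(
    spec: VisitGenSpec,
    valueset: ValueSet | None = None,
    states: Sequence[StateDefinition] = DEFAULT_STATES,
) -> list[VisitRecord]:
    """Generate synthetic visits with target per-state utility structure.

    For each visit: a SARA score is drawn uniformly within the state's
    interval, a latent utility from Normal(target mean, sd), and the
    profile whose index is nearest to the latent draw (over the value
    set's 243 profiles) is recorded.  Deterministic given the spec seed.
    """
    if valueset is None:
        valueset = load_dutch_valueset()
    profiles = all_profiles()
    indices = np.array([eq5d_index(p, valueset) for p in profiles])
    order = np.argsort(indices, kind="stable")
    sorted_idx = indices[order]
    lo_idx, hi_idx = float(sorted_idx[0]), float(sorted_idx[-1])
    for name in spec.counts:
        mean = spec.targets[name][0]
        if not lo_idx <= mean <= hi_idx:
            raise ValueError(
                f"target mean {mean} for state {name!r} outside the value set's "
                f"attainable index range [{lo_idx:.3f}, {hi_idx:.3f}]"
            )

    rng = np.random.default_rng(spec.seed)
    state_by_name = {s.name: s for s in states}
    patient_shift = (
        rng.normal(0.0, spec.cluster_sd, spec.n_patients)
        if spec.cluster_sd > 0
        else np.zeros(spec.n_patients)
    )

    visits: list[VisitRecord] = []
    patient_cursor = 0
    for name in STATE_NAMES:
        count = spec.counts.get(name, 0)
        if count == 0:
            continue
        state = state_by_name[name]
        mean, sd = spec.targets[name]
        saras = rng.uniform(state.sara_low, state.sara_high, count)
        # keep pre-ataxic draws inside the closed interval, others off the
        # open lower boundary
        if state.sara_low > 0:
            saras = np.nextafter(saras, np.inf)
        for sara in saras:
            pid = patient_cursor % spec.n_patients
            patient_cursor += 1
            latent = rng.normal(mean, sd) if sd > 0 else mean
            latent += patient_shift[pid]
            pos = np.searchsorted(sorted_idx, latent)
            if pos == 0:
                best = order[0]
            elif pos == len(sorted_idx):
                best = order[-1]
            else:
                below, above = sorted_idx[pos - 1], sorted_idx[pos]
                best = order[pos - 1] if latent - below <= above - latent else order[pos]
            visits.append(VisitRecord(pid, float(sara), profiles[int(best)]))
    return visits


@dataclass(frozen=True)
class SurvivalGenSpec:
    """Recipe for the monotone 5-year-survival stand-in table.

    ``S5(sara) = s5_at_min * (1 - x)**shape`` with
    ``x = (sara - sara_min) / (sara_max - sara_min)``: survival starts
    near 1 at SARA 14 and falls strictly to 0 at SARA 40 (the scale
    ceiling, where death within a year is certain).  Larger ``shape``
    means faster early decline.
    """

    sara_min: float = 14.0
    sara_max: float = 40.0
    s5_at_min: float = 0.98
    shape: float = 1.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.sara_min < self.sara_max:
            raise ValueError("sara_min must be < sara_max")
        if not 0.0 < self.s5_at_min <= 1.0:
            raise ValueError(f"s5_at_min must be in (0, 1], got {self.s5_at_min}")
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not self.step > 0:
            raise ValueError("step must be > 0")


def generate_survival_table(spec: SurvivalGenSpec) -> pd.DataFrame:
    """Evaluate the survival family on its SARA knots.

    The result is strictly decreasing, ends at exactly 0 at ``sara_max``
    and round-trips through :class:`~sca1cea.config.MortalityParams`.
    """
    n_steps = int(round((spec.sara_max - spec.sara_min) / spec.step))
    grid = spec.sara_min + spec.step * np.arange(n_steps + 1)
    grid[-1] = spec.sara_max
    x = (grid - spec.sara_min) / (spec.sara_max - spec.sara_min)
    s5 = spec.s5_at_min * (1.0 - x) ** spec.shape
    s5[-1] = 0.0
    return pd.DataFrame({"sara": grid, "survival_5yr": s5})


def survival_table_to_csv(table: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def _mortality_from_spec(
    spec: SurvivalGenSpec, background_annual_prob: float
) -> MortalityParams:
    table = generate_survival_table(spec)
    return MortalityParams(
        sara_grid=table["sara"].to_numpy(),
        survival_5yr=table["survival_5yr"].to_numpy(),
        background_annual_prob=background_annual_prob,
        background_below_sara=spec.sara_min,
        certain_death_sara=spec.sara_max,
    )


def calibrate_survival_shape(
    target_mean_survival: float = 16.59,
    progression: ProgressionParams | None = None,
    settings: SimulationSettings | None = None,
    base_spec: SurvivalGenSpec | None = None,
    background_annual_prob: float = 1e-3,
    states: Sequence[StateDefinition] = DEFAULT_STATES,
    shape_bounds: tuple[float, float] = (0.1, 12.0),
    xtol: float = 1e-3,
) -> tuple[SurvivalGenSpec, pd.DataFrame]:
    """One-dimensional search for the survival-table shape parameter.

    Finds the ``shape`` at which the usual-care cohort's mean survival
    from simulation start equals ``target_mean_survival`` years, running
    the full microsimulation at each trial value (default 10,000 patients,
    matching the cohort size the reported survival refers to).  Returns
    the calibrated spec and its table.
    """
    if progression is None:
        progression = ProgressionParams()
    if settings is None:
        settings = SimulationSettings()
    if base_spec is None:
        base_spec = SurvivalGenSpec()

    def mean_survival(shape: float) -> float:
        spec = dataclasses.replace(base_spec, shape=shape)
        mort = _mortality_from_spec(spec, background_annual_prob)
        traces = run_cohort(settings, USUAL_CARE, progression, mort, states)
        return float(np.mean([t.n_cycles for t in traces]))

    def objective(shape: float) -> float:
        return mean_survival(shape) - target_mean_survival

    lo, hi = shape_bounds
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target survival {target_mean_survival} not bracketed by shapes "
            f"{shape_bounds}: f({lo})={f_lo:+.3f}, f({hi})={f_hi:+.3f}"
        )
    shape = float(brentq(objective, lo, hi, xtol=xtol))
    spec = dataclasses.replace(base_spec, shape=shape)
    return spec, generate_survival_table(spec)


def build_config_with_survival(
    cfg: ModelConfig, spec: SurvivalGenSpec
) -> ModelConfig:
    """Replace a config's mortality table with a generated one."""
    return cfg.replace(
        mortality=_mortality_from_spec(spec, cfg.mortality.background_annual_prob)
    )
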