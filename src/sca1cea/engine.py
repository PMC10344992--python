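"""Patient-level microsimulation engine.

Each individual is advanced cycle by cycle (1 cycle = 1 year) from SARA 0
until death.  Within a cycle, in order: (1) the state occupied during the
year is recorded from the SARA score at cycle start; (2) treatment status
is determined from the strategy's start/stop rules; (3) death is drawn
with the annual probability at the cycle-start SARA — if death occurs the
cycle is the last one lived; (4) SARA advances by the individual rate,
reduced by the treatment effectiveness while on therapy.  The cycle in
which SARA first reaches 40 is the last cycle lived ("death within one
year" at the scale ceiling).

Strategies are compared under common random numbers: patient *i*'s rate
draw and per-cycle mortality uniforms come from a dedicated substream
spawned from the master seed, identical across strategies, so strategy
contrasts are paired and free of between-arm Monte-Carlo noise.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_STATES,
    STATE_NAMES,
    ModelConfig,
    MortalityParams,
    ProgressionParams,
    SimulationSettings,
    StateDefinition,
)
from .disease import RateSample, annual_death_prob, sample_rate, state_index

__all__ = [
    "Strategy",
    "PatientTrace",
    "USUAL_CARE",
    "paper_strategies",
    "simulate_patient",
    "run_cohort",
    "traces_to_frame",
]

_UNIFORM_CHUNK = 64


@dataclass(frozen=True)
class Strategy:
    """A treatment start/stop rule plus an effectiveness fraction.

    ``start_sara`` is the SARA boundary of the state in which therapy
    begins: 0 starts in the pre-ataxic state (on from the first cycle),
    a positive boundary *b* starts in the first cycle whose starting SARA
    exceeds *b* (e.g. 2 for slight, 14 for moderate).  ``None`` means the
    patient is never treated (usual care).  ``stop_sara`` stops therapy
    permanently once SARA exceeds it; there is no restart.
    ``effectiveness`` is the fractional reduction of the progression rate
    while on treatment.
    """

    name: str
    start_sara: float | None = 0.0
    stop_sara: float | None = None
    effectiveness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError(
                f"strategy {self.name!r}: effectiveness {self.effectiveness} outside [0, 1]"
            )
        if (
            self.stop_sara is not None
            and self.start_sara is not None
            and not self.stop_sara > self.start_sara
        ):
            raise ValueError(
                f"strategy {self.name!r}: stop_sara ({self.stop_sara}) must exceed "
                f"start_sara ({self.start_sara})"
            )

    def with_effectiveness(self, effectiveness: float) -> "Strategy":
        return dataclasses.replace(self, effectiveness=effectiveness)

    def start_condition_met(self, sara: float) -> bool:
        if self.start_sara is None:
            return False
        if self.start_sara == 0.0:
            return True
        return sara > self.start_sara


#: No disease-modifying therapy; symptom relief only.
USUAL_CARE = Strategy("usual_care", start_sara=None, effectiveness=0.0)


def paper_strategies(effectiveness: float = 0.5) -> list[Strategy]:
    """The five hypothetical treatment strategies.

    * full treatment: start pre-ataxic, never stop;
    * start at slight / moderate: start once SARA > 2 / > 14, never stop;
    * stop after moderate / severe: start pre-ataxic, stop permanently
      once SARA exceeds 26 / 34 (i.e. at the end of that stage).
    """
    return [
        Strategy("full_treatment", 0.0, None, effectiveness),
        Strategy("start_at_slight", 2.0, None, effectiveness),
        Strategy("start_at_moderate", 14.0, None, effectiveness),
        Strategy("stop_after_moderate", 0.0, 26.0, effectiveness),
        Strategy("stop_after_severe", 0.0, 34.0, effectiveness),
    ]


@dataclass
class PatientTrace:
    """One simulated individual's lifetime record.

    Arrays are indexed by cycle (year) ``t = 0, 1, ...``; ``sara[t]`` is the
    score at cycle start and ``state[t]`` the state occupied during the
    year.  Every trace terminates in death: the final cycle is the death
    cycle.
    """

    patient_id: int
    rate: float
    sara: np.ndarray
    state: np.ndarray
    on_treatment: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.sara)

    @property
    def died_this_cycle(self) -> np.ndarray:
        flags = np.zeros(self.n_cycles, dtype=bool)
        if self.n_cycles:
            flags[-1] = True
        return flags

    @property
    def treatment_cycles(self) -> int:
        return int(self.on_treatment.sum())


def simulate_patient(
    patient_id: int,
    rate: RateSample | float,
    strategy: Strategy,
    mort: MortalityParams,
    states: Sequence[StateDefinition],
    rng: np.random.Generator,
    max_cycles: int = 100_000,
) -> PatientTrace:
    """Simulate one individual from SARA 0 until death.

    Exactly one uniform is consumed per cycle (the death draw), so the
    random stream position depends only on cycle count — the basis of the
    common-random-numbers pairing across strategies.
    """
    if isinstance(rate, RateSample):
        if rate.patient_id != patient_id:
            raise ValueError("rate sample belongs to a different patient")
        rate_value = rate.rate
    else:
        rate_value = float(rate)
    boundaries = [s.sara_high for s in states[:-1]]
    effectiveness = strategy.effectiveness
    stop_sara = strategy.stop_sara
    certain = mort.certain_death_sara

    sara = 0.0
    stopped = False
    sara_log: list[float] = []
    state_log: list[int] = []
    on_log: list[bool] = []
    uniforms = rng.random(_UNIFORM_CHUNK)
    u_next = 0

    for _ in range(max_cycles):
        state = state_index(sara, boundaries)
        if stop_sara is not None and not stopped and sara > stop_sara:
            stopped = True
        on = (not stopped) and strategy.start_condition_met(sara)
        sara_log.append(sara)
        state_log.append(state)
        on_log.append(on)

        if u_next >= len(uniforms):
            uniforms = rng.random(_UNIFORM_CHUNK)
            u_next = 0
        u = uniforms[u_next]
        u_next += 1
        if u < annual_death_prob(sara, mort):
            break

        step = rate_value * (1.0 - effectiveness) if on else rate_value
        sara += step
        if sara >= certain:
            break  # scale ceiling: this cycle is the last one lived
    else:
        raise RuntimeError(
            f"patient {patient_id} still alive after {max_cycles} cycles"
        )

    return PatientTrace(
        patient_id=patient_id,
        rate=rate_value,
        sara=np.array(sara_log),
        state=np.array(state_log, dtype=np.int8),
        on_treatment=np.array(on_log, dtype=bool),
    )


def run_cohort(
    settings: SimulationSettings,
    strategy: Strategy,
    progression: ProgressionParams,
    mortality: MortalityParams,
    states: Sequence[StateDefinition] = DEFAULT_STATES,
) -> list[PatientTrace]:
    """Simulate the whole cohort under one strategy.

    Patient *i*'s random substream is spawned deterministically from the
    master seed and does not depend on the strategy, so rate draws and
    mortality uniforms are identical across strategies run with the same
    settings (common random numbers).
    """
    root = np.random.SeedSequence(settings.seed)
    children = root.spawn(settings.n_patients)
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rate = sample_rate(progression, rng, patient_id=i)
        traces.append(
            simulate_patient(
                i, rate, strategy, mortality, states, rng, settings.max_cycles
            )
        )
    return traces


def run_cohort_config(cfg: ModelConfig, strategy: Strategy) -> list[PatientTrace]:
    """Convenience wrapper: :func:`run_cohort` driven by a ModelConfig."""
    return run_cohort(cfg.settings, strategy, cfg.progression, cfg.mortality, cfg.states)


def traces_to_frame(traces: Iterable[PatientTrace]) -> pd.DataFrame:
    """Long-format audit dump: one row per patient-cycle."""
    rows = []
    for tr in traces:
        n = tr.n_cycles
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": np.full(n, tr.patient_id),
                    "cycle": np.arange(n),
                    "sara": tr.sara,
                    "state": [STATE_NAMES[s] for s in tr.state],
                    "on_treatment": tr.on_treatment,
                    "alive_at_cycle_end": ~tr.died_this_cycle,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
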