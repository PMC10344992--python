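"""Disease natural history: SARA-to-state mapping, progression-rate
sampling and per-cycle death probabilities.

SCA1 severity is tracked on the SARA scale (0 = no ataxia, 40 = most
severe).  Each simulated individual carries one progression rate, constant
for life, drawn from the meta-analytic distribution; mortality is
background below SARA 14 and nomogram-derived (5-year survival converted
to annual probability) from SARA 14 upward.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .config import (
    DEFAULT_STATES,
    SARA_MAX,
    SARA_MIN,
    STATE_NAMES,
    MortalityParams,
    ProgressionParams,
    StateDefinition,
)

__all__ = [
    "HealthState",
    "RateSample",
    "sara_to_state",
    "state_index",
    "sample_rate",
    "annual_death_prob",
]


class HealthState(IntEnum):
    """The five living states, ordered by severity; death is absorbing and
    represented by trace termination rather than a state code."""

    PRE_ATAXIC = 0
    SLIGHT = 1
    MODERATE = 2
    SEVERE = 3
    END_STAGE = 4

    @property
    def label(self) -> str:
        return STATE_NAMES[self.value]


@dataclass(frozen=True)
class RateSample:
    """One individual's lifetime SARA progression rate (points/year)."""

    patient_id: int
    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"progression rate must be > 0, got {self.rate}")


def _boundaries(states: Sequence[StateDefinition]) -> list[float]:
    return [s.sara_high for s in states[:-1]]


def state_index(sara: float, boundaries: Sequence[float]) -> int:
    """Index of the state containing ``sara``; boundaries belong to the
    lower state (SARA 14 is still slight ataxia, per the ``> x`` interval
    notation)."""
    return bisect_left(boundaries, sara)


def sara_to_state(
    sara: float, states: Sequence[StateDefinition] = DEFAULT_STATES
) -> HealthState:
    """Map a SARA score to its living health state.

    Boundary scores resolve to the less severe state: SARA 2 is
    pre-ataxic, 14 slight, 26 moderate, 34 severe.
    """
    if not SARA_MIN <= sara <= SARA_MAX:
        raise ValueError(f"SARA score {sara} outside [{SARA_MIN}, {SARA_MAX}]")
    return HealthState(state_index(sara, _boundaries(states)))


def sample_rate(
    params: ProgressionParams,
    rng: np.random.Generator,
    patient_id: int = 0,
    max_tries: int = 1000,
) -> RateSample:
    """Draw an individual progression rate from Normal(mean, sd).

    The sd is back-solved from the 95% CI; non-positive draws are redrawn
    (truncation at zero), so the returned rate is always positive.  With a
    degenerate CI (sd = 0) every draw equals the mean.
    """
    sd = params.sd
    if sd == 0.0:
        return RateSample(patient_id, params.mean_rate)
    for _ in range(max_tries):
        rate = rng.normal(params.mean_rate, sd)
        if rate > 0.0:
            return RateSample(patient_id, float(rate))
    raise RuntimeError(
        f"could not draw a positive progression rate in {max_tries} tries "
        f"(mean={params.mean_rate}, sd={sd})"
    )


def annual_death_prob(sara: float, mort: MortalityParams) -> float:
    """Annual probability of death at a given SARA score.

    * ``sara >= certain_death_sara`` (40): certain death, p = 1.
    * ``sara < background_below_sara`` (14): the background probability.
    * otherwise: ``p = 1 - S5(sara)**(1/5)`` with S5 linearly interpolated
      from the 5-year-survival table.
    """
    if not SARA_MIN <= sara <= SARA_MAX:
        raise ValueError(f"SARA score {sara} outside [{SARA_MIN}, {SARA_MAX}]")
    if sara >= mort.certain_death_sara:
        return 1.0
    if sara < mort.background_below_sara:
        return mort.background_annual_prob
    grid: list[float] = mort._grid_list  # type: ignore[attr-defined]
    s5: list[float] = mort._s5_list  # type: ignore[attr-defined]
    if sara > grid[-1]:
        raise ValueError(
            f"survival table covers SARA up to {grid[-1]}; query was {sara}"
        )
    i = bisect_right(grid, sara)
    if i == len(grid):
        s5_value = s5[-1]
    else:
        x0, x1 = grid[i - 1], grid[i]
        y0, y1 = s5[i - 1], s5[i]
        s5_value = y0 + (y1 - y0) * (sara - x0) / (x1 - x0)
    return 1.0 - s5_value ** 0.2
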