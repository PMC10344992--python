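"""EQ-5D-3L index computation and per-state utility aggregation.

The EQ-5D-3L describes health on five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at level 1
(no problems), 2 (some) or 3 (extreme).  A country value set converts a
profile to an index utility through an additive model: a full-health
anchor minus a constant (once any dimension is above level 1), minus
per-dimension level decrements, minus an extra term once any dimension is
at level 3 (the "N3" term of MVH-type tariffs).

Visit-level profiles paired with SARA scores are scored and grouped by
health state to derive the per-state utilities the simulation consumes.
"""
from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import Z_95, DEFAULT_STATES, SARA_MAX, SARA_MIN, StateDefinition
from .disease import sara_to_state

__all__ = [
    "DIMENSIONS",
    "DIMENSION_CODES",
    "Eq5dProfile",
    "ValueSet",
    "VisitRecord",
    "eq5d_index",
    "all_profiles",
    "aggregate_by_state",
    "load_dutch_valueset",
    "read_visits_csv",
    "write_visits_csv",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
#: Conventional two-letter codes, in dimension order (used in CSV headers
#: and value-set term names: mo2, mo3, sc2, ...).
DIMENSION_CODES = ("mo", "sc", "ua", "pd", "ad")

_DATA_DIR = Path(__file__).resolve().parent / "data"


@dataclass(frozen=True)
class Eq5dProfile:
    """One EQ-5D-3L descriptive-system response (five levels in {1,2,3})."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(f"{dim} level must be in {{1, 2, 3}}, got {level}")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    @classmethod
    def from_levels(cls, levels: Sequence[int]) -> "Eq5dProfile":
        return cls(*levels)


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-3L tariff: anchor minus decrement terms.

    ``decrements`` maps term names to non-negative decrements: ``constant``
    (applied once any dimension is above level 1), ``<code><level>`` per
    dimension level above 1 (e.g. ``mo2``, ``pd3``) and optionally ``n3``
    (applied once any dimension is at level 3).
    """

    name: str
    decrements: dict[str, float]
    anchor: float = 1.0

    def __post_init__(self) -> None:
        known = {"constant", "n3"} | {
            f"{code}{level}" for code in DIMENSION_CODES for level in (2, 3)
        }
        unknown = set(self.decrements) - known
        if unknown:
            raise ValueError(f"value set {self.name!r}: unknown terms {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path: Path | str, name: str | None = None) -> "ValueSet":
        """Read a ``term,coefficient`` CSV; an optional ``anchor`` row sets
        the full-health value (default 1.0)."""
        path = Path(path)
        decrements: dict[str, float] = {}
        anchor = 1.0
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"term", "coefficient"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: value set needs columns 'term,coefficient'")
            for row in reader:
                term = row["term"].strip()
                if term == "anchor":
                    anchor = float(row["coefficient"])
                else:
                    decrements[term] = float(row["coefficient"])
        return cls(name=name or path.stem, decrements=decrements, anchor=anchor)

    @property
    def min_index(self) -> float:
        """Smallest attainable index (worst profile 33333)."""
        return min(eq5d_index(p, self) for p in all_profiles())


def eq5d_index(profile: Eq5dProfile, valueset: ValueSet) -> float:
    """Score a profile with an additive value set.

    Full health (1,1,1,1,1) maps to the anchor; otherwise the constant,
    the per-dimension level decrements and (if any level 3) the N3 term
    are subtracted.
    """
    levels = profile.levels
    dec = valueset.decrements
    index = valueset.anchor
    if any(level > 1 for level in levels):
        index -= dec.get("constant", 0.0)
        for code, level in zip(DIMENSION_CODES, levels):
            if level > 1:
                index -= dec.get(f"{code}{level}", 0.0)
        if any(level == 3 for level in levels):
            index -= dec.get("n3", 0.0)
    return index


def all_profiles() -> list[Eq5dProfile]:
    """All 3^5 = 243 descriptive-system profiles."""
    return [
        Eq5dProfile(*levels)
        for levels in itertools.product((1, 2, 3), repeat=len(DIMENSIONS))
    ]


def load_dutch_valueset() -> ValueSet:
    """The bundled Dutch EQ-5D-3L tariff (additive, with an N3 term).

    The coefficients are entered from the published Dutch valuation-study
    tariff and shipped as an editable CSV — user-verifiable input data,
    not a quantity this package derives.
    """
    return ValueSet.from_csv(_DATA_DIR / "valueset_nl_3l.csv", name="NL-3L")


@dataclass(frozen=True)
class VisitRecord:
    """One study visit: patient, SARA score, EQ-5D-3L profile."""

    patient_id: int
    sara: float
    profile: Eq5dProfile

    def __post_init__(self) -> None:
        if not SARA_MIN <= self.sara <= SARA_MAX:
            raise ValueError(f"SARA score {self.sara} outside [{SARA_MIN}, {SARA_MAX}]")


def aggregate_by_state(
    visits: Iterable[VisitRecord],
    states: Sequence[StateDefinition] = DEFAULT_STATES,
    valueset: ValueSet | None = None,
    cluster_by_patient: bool = False,
) -> pd.DataFrame:
    """Score each visit and aggregate utilities per health state.

    Returns one row per living state (``n``, ``mean_utility``, ``ci_low``,
    ``ci_high``); states without visits report n = 0 and NaN means, and a
    single-visit state reports its visit's index with an undefined CI.
    By default visits are treated as independent; with
    ``cluster_by_patient`` the mean and CI are computed over per-patient
    means within each state (repeated visits per patient collapse first).
    """
    if valueset is None:
        valueset = load_dutch_valueset()
    visits = list(visits)
    if not visits:
        raise ValueError("no visits to aggregate")
    frame = pd.DataFrame(
        {
            "patient_id": [v.patient_id for v in visits],
            "state": [sara_to_state(v.sara, states).label for v in visits],
            "index": [eq5d_index(v.profile, valueset) for v in visits],
        }
    )
    rows = []
    for state in states:
        group = frame[frame["state"] == state.name]
        if cluster_by_patient and not group.empty:
            values = group.groupby("patient_id")["index"].mean().to_numpy()
        else:
            values = group["index"].to_numpy()
        n = len(values)
        if n == 0:
            mean = lo = hi = float("nan")
        elif n == 1:
            mean, lo, hi = float(values[0]), float("nan"), float("nan")
        else:
            mean = float(np.mean(values))
            half = Z_95 * float(np.std(values, ddof=1)) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        rows.append(
            {
                "state": state.name,
                "n": n,
                "mean_utility": mean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def read_visits_csv(path: Path | str) -> list[VisitRecord]:
    """Read a ``patient_id,sara,mo,sc,ua,pd,ad`` visit table."""
    path = Path(path)
    visits = []
    required = {"patient_id", "sara", *DIMENSION_CODES}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: visit table needs columns {sorted(required)}")
        for row in reader:
            visits.append(
                VisitRecord(
                    patient_id=int(row["patient_id"]),
                    sara=float(row["sara"]),
                    profile=Eq5dProfile(*(int(row[c]) for c in DIMENSION_CODES)),
                )
            )
    return visits


def write_visits_csv(visits: Iterable[VisitRecord], path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "sara", *DIMENSION_CODES])
        for v in visits:
            writer.writerow([v.patient_id, repr(float(v.sara)), *v.profile.levels])
    return path
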