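"""Longitudinal cohort data model and phase extraction.

A :class:`Cohort` holds one record per participant with an ordered visit
list; each :class:`Visit` carries a consensus diagnosis (CU, MCI or DEM),
months since the participant's baseline visit, and the clinical variable
values of the schema.  Diagnosis trajectories must be monotone
CU -> MCI -> DEM: reversals are rejected at construction.

Three observation sets ("phases") are carved out of an eligible cohort:

* ``MCI_V``  — the first visit with an MCI diagnosis, one row per participant;
* ``M2D_V``  — every visit strictly between the first MCI visit and the
  first dementia visit (zero or more rows per participant);
* ``DEM_V``  — the first visit with a dementia diagnosis, one row per
  participant.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import VariableSchema, default_schema

__all__ = [
    "Diagnosis",
    "Phase",
    "Visit",
    "Participant",
    "Cohort",
    "PhaseDataset",
    "NoEligibleParticipantsError",
    "CohortValidationError",
    "select_study_sample",
    "filter_variables",
    "extract_phase",
    "min_max_normalize",
    "phase_summary_stats",
    "read_visits_csv",
    "write_visits_csv",
]

_META_COLUMNS = [
    "participant_id",
    "visit_index",
    "months_since_baseline",
    "diagnosis",
    "sex",
    "apoe4",
    "age_at_baseline",
]


class Diagnosis(enum.IntEnum):
    """Consensus diagnosis, ordered by severity."""

    CU = 0
    MCI = 1
    DEM = 2

    def __str__(self) -> str:  # CSV label
        return self.name


class Phase(str, enum.Enum):
    MCI_V = "MCI_V"
    M2D_V = "M2D_V"
    DEM_V = "DEM_V"


class CohortValidationError(ValueError):
    """Raised when input rows violate the cohort invariants."""


class NoEligibleParticipantsError(RuntimeError):
    """Raised when study-sample selection leaves no participants."""


@dataclass(frozen=True)
class Visit:
    participant_id: str
    visit_index: int
    months_since_baseline: float
    diagnosis: Diagnosis
    values: dict[str, float]  # missing variables simply absent

    def value(self, name: str) -> float:
        """Return the value or NaN when missing."""
        return self.values.get(name, float("nan"))


@dataclass(frozen=True)
class Participant:
    participant_id: str
    sex: str  # 'F' | 'M'
    apoe4: bool
    age_at_baseline: float
    visits: tuple[Visit, ...]

    def diagnoses(self) -> list[Diagnosis]:
        return [v.diagnosis for v in self.visits]

    def first_visit_with(self, dx: Diagnosis) -> Visit | None:
        for v in self.visits:
            if v.diagnosis is dx:
                return v
        return None


@dataclass(frozen=True)
class Cohort:
    schema: VariableSchema
    participants: tuple[Participant, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        self._validate()

    def _validate(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate participant ids: {dupes}")
        for p in self.participants:
            if p.sex not in ("F", "M"):
                raise CohortValidationError(
                    f"{p.participant_id}: sex must be 'F' or 'M', got {p.sex!r}"
                )
            months = [v.months_since_baseline for v in p.visits]
            if any(b <= a for a, b in zip(months, months[1:])):
                raise CohortValidationError(
                    f"{p.participant_id}: months_since_baseline must be "
                    "strictly increasing"
                )
            dx = p.diagnoses()
            bad = [i for i, (a, b) in enumerate(zip(dx, dx[1:]), start=2) if b < a]
            if bad:
                raise CohortValidationError(
                    f"{p.participant_id}: diagnosis reversal at visit(s) {bad} "
                    "(trajectories must be monotone CU -> MCI -> DEM)"
                )
            unknown = set().union(*(v.values.keys() for v in p.visits)) - set(
                self.schema.names
            ) if p.visits else set()
            if unknown:
                raise CohortValidationError(
                    f"{p.participant_id}: values for variables not in schema: "
                    f"{sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def n_visits(self) -> int:
        return sum(len(p.visits) for p in self.participants)

    def participant(self, participant_id: str) -> Participant:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format visit table, one row per participant-visit."""
        rows = []
        for p in self.participants:
            for v in p.visits:
                row = {
                    "participant_id": p.participant_id,
                    "visit_index": v.visit_index,
                    "months_since_baseline": v.months_since_baseline,
                    "diagnosis": str(v.diagnosis),
                    "sex": p.sex,
                    "apoe4": "yes" if p.apoe4 else "no",
                    "age_at_baseline": p.age_at_baseline,
                }
                for name in self.schema.names:
                    row[name] = v.values.get(name, np.nan)
                rows.append(row)
        return pd.DataFrame(rows, columns=_META_COLUMNS + self.schema.names)


@dataclass(frozen=True)
class PhaseDataset:
    """Observations-by-variables matrix for one phase.

    ``frame`` columns follow schema order; missing values are NaN.
    ``row_keys`` aligns rows with (participant_id, visit_index).
    """

    phase: Phase
    frame: pd.DataFrame
    row_keys: tuple[tuple[str, int], ...]

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)


# --------------------------------------------------------------------------
# Study-sample selection
# --------------------------------------------------------------------------

def _is_eligible(p: Participant) -> bool:
    if not p.visits or p.visits[0].diagnosis is not Diagnosis.CU:
        return False  # impaired (or demented) at baseline
    dx = p.diagnoses()
    try:
        first_mci = dx.index(Diagnosis.MCI)
    except ValueError:
        return False  # never MCI
    if len(dx) - first_mci < 2:
        return False  # fewer than two visits from first MCI onward
    return Diagnosis.DEM in dx[first_mci + 1 :]


def select_study_sample(cohort: Cohort) -> Cohort:
    """Apply the study inclusion criteria.

    Retains participants that (a) are cognitively unimpaired at their
    baseline visit, (b) develop MCI, (c) have at least two visits from the
    first MCI diagnosis onward, and (d) progress to dementia after the first
    MCI visit.  Order is preserved.

    Raises
    ------
    NoEligibleParticipantsError
        When no participant satisfies the criteria.
    """
    kept = tuple(p for p in cohort.participants if _is_eligible(p))
    if not kept:
        raise NoEligibleParticipantsError(
            "no eligible participants: every participant fails the "
            "CU-at-baseline / MCI / progression-to-dementia criteria"
        )
    return Cohort(schema=cohort.schema, participants=kept)


# --------------------------------------------------------------------------
# Variable filtering
# --------------------------------------------------------------------------

def filter_variables(
    cohort: Cohort, max_missing_fraction: float = 0.5
) -> tuple[Cohort, list[str]]:
    """Drop variables with too much missingness.

    A variable is dropped when its missing fraction across all visits is
    *strictly* greater than ``max_missing_fraction`` (a variable missing in
    exactly half the rows survives the default 0.5 cutoff).

    Returns the filtered cohort and the list of dropped variable names.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    n_rows = cohort.n_visits
    if n_rows == 0:
        raise CohortValidationError("cohort has no visits")
    missing = {name: 0 for name in cohort.schema.names}
    for p in cohort.participants:
        for v in p.visits:
            for name in missing:
                val = v.values.get(name)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    missing[name] += 1
    dropped = [
        name
        for name in cohort.schema.names
        if missing[name] / n_rows > max_missing_fraction
    ]
    if len(dropped) == len(cohort.schema):
        raise CohortValidationError(
            "variable filter dropped every variable; lower the missingness "
            "threshold or check the input data"
        )
    if not dropped:
        return cohort, []
    keep = [n for n in cohort.schema.names if n not in dropped]
    new_schema = cohort.schema.subset(keep)
    participants = tuple(
        replace(
            p,
            visits=tuple(
                replace(
                    v, values={k: x for k, x in v.values.items() if k in keep}
                )
                for v in p.visits
            ),
        )
        for p in cohort.participants
    )
    return Cohort(schema=new_schema, participants=participants), dropped


# --------------------------------------------------------------------------
# Phase extraction
# --------------------------------------------------------------------------

def _phase_visits(p: Participant, phase: Phase) -> list[Visit]:
    dx = p.diagnoses()
    first_mci = dx.index(Diagnosis.MCI)
    first_dem = dx.index(Diagnosis.DEM)
    if phase is Phase.MCI_V:
        return [p.visits[first_mci]]
    if phase is Phase.DEM_V:
        return [p.visits[first_dem]]
    if phase is Phase.M2D_V:
        return list(p.visits[first_mci + 1 : first_dem])
    raise ValueError(f"unknown phase: {phase!r}")


def extract_phase(cohort: Cohort, phase: Phase | str) -> PhaseDataset:
    """Extract one observation set from an eligibility-filtered cohort.

    The cohort must already have passed :func:`select_study_sample` (every
    participant has a first MCI visit followed by a dementia visit).
    """
    phase = Phase(phase)
    rows: list[list[float]] = []
    keys: list[tuple[str, int]] = []
    names = cohort.schema.names
    for p in sorted(cohort.participants, key=lambda q: q.participant_id):
        for v in _phase_visits(p, phase):
            rows.append([v.values.get(n, np.nan) for n in names])
            keys.append((p.participant_id, v.visit_index))
    frame = pd.DataFrame(rows, columns=names, dtype=float)
    return PhaseDataset(phase=phase, frame=frame, row_keys=tuple(keys))


# --------------------------------------------------------------------------
# Normalization and summaries
# --------------------------------------------------------------------------

def _normalize_frame(
    frame: pd.DataFrame, schema: VariableSchema, bounds_source: str
) -> pd.DataFrame:
    out = frame.copy()
    for name in frame.columns:
        col = frame[name]
        if bounds_source == "schema":
            lo, hi = schema[name].min, schema[name].max
        else:
            lo, hi = col.min(skipna=True), col.max(skipna=True)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
            warnings.warn(
                f"variable {name!r} has zero observed range; normalized to 0",
                stacklevel=3,
            )
            out[name] = col.where(col.isna(), 0.0)
        else:
            out[name] = (col - lo) / (hi - lo)
    return out


def min_max_normalize(
    data: PhaseDataset | Cohort, bounds_source: str = "observed"
) -> PhaseDataset | Cohort:
    """Min-max scale every variable to [0, 1].

    ``bounds_source='observed'`` pools all rows (or all visits, for a
    cohort) of the object; ``'schema'`` uses the instrument ranges declared
    in the schema.  Missing values stay missing; zero-range variables map
    to 0 with a warning.
    """
    if bounds_source not in ("observed", "schema"):
        raise ValueError("bounds_source must be 'observed' or 'schema'")
    if isinstance(data, PhaseDataset):
        schema = None
        if bounds_source == "schema":
            raise_on = [c for c in data.frame.columns]
            # schema bounds need the schema; PhaseDataset stores columns only
            schema = default_schema(include_demographics=True)
            missing = [c for c in raise_on if c not in schema]
            if missing:
                raise KeyError(
                    f"no schema bounds for variables: {missing}; normalize "
                    "the cohort instead"
                )
        frame = _normalize_frame(data.frame, schema, bounds_source)
        return PhaseDataset(phase=data.phase, frame=frame, row_keys=data.row_keys)
    if isinstance(data, Cohort):
        frame = data.to_frame()
        values = _normalize_frame(
            frame[data.schema.names], data.schema, bounds_source
        )
        participants = []
        row = 0
        for p in data.participants:
            visits = []
            for v in p.visits:
                vals = {
                    n: float(values.iloc[row][n])
                    for n in data.schema.names
                    if not np.isnan(values.iloc[row][n])
                }
                visits.append(replace(v, values=vals))
                row += 1
            participants.append(replace(p, visits=tuple(visits)))
        return Cohort(schema=data.schema, participants=tuple(participants))
    raise TypeError(f"cannot normalize {type(data).__name__}")


def phase_summary_stats(
    datasets: dict[Phase | str, PhaseDataset], variables: list[str]
) -> pd.DataFrame:
    """Per-phase mean and sample standard deviation (n-1 denominator).

    Missing values are excluded per variable.  When fewer than two
    non-missing values exist the sd is reported as NaN.
    """
    records = []
    for phase, ds in datasets.items():
        phase = Phase(phase)
        for name in variables:
            if name not in ds.frame.columns:
                raise KeyError(f"variable {name!r} not in {phase.value} dataset")
            col = ds.frame[name].dropna()
            mean = float(col.mean()) if len(col) else np.nan
            sd = float(col.std(ddof=1)) if len(col) >= 2 else np.nan
            records.append(
                {
                    "phase": phase.value,
                    "variable": name,
                    "n": int(len(col)),
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def write_visits_csv(cohort: Cohort, path) -> None:
    """Write the long-format visits CSV (UTF-8, comma-separated)."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, lineterminator="\n")


def read_visits_csv(path, schema: VariableSchema | None = None) -> Cohort:
    """Read a long-format visits CSV into a :class:`Cohort`.

    Columns: ``participant_id, visit_index, months_since_baseline,
    diagnosis, sex, apoe4, age_at_baseline`` followed by variable columns.
    Empty cells are missing values.  Unknown variable columns raise unless a
    schema restricted to the file's columns can be formed.
    """
    frame = pd.read_csv(path)
    missing_meta = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise CohortValidationError(f"missing required columns: {missing_meta}")
    var_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    if schema is None:
        full = default_schema(include_demographics=True)
        unknown = [c for c in var_cols if c not in full]
        if unknown:
            raise CohortValidationError(
                f"unknown variable columns: {unknown}; pass an explicit schema"
            )
        schema = full.subset(var_cols)
    participants = []
    for pid, grp in frame.groupby("participant_id", sort=True):
        grp = grp.sort_values("visit_index")
        visits = []
        for _, row in grp.iterrows():
            try:
                dx = Diagnosis[str(row["diagnosis"])]
            except KeyError:
                raise CohortValidationError(
                    f"{pid}: bad diagnosis label {row['diagnosis']!r} "
                    "(expected CU, MCI or DEM)"
                ) from None
            values = {
                name: float(row[name])
                for name in schema.names
                if name in frame.columns and pd.notna(row[name])
            }
            visits.append(
                Visit(
                    participant_id=str(pid),
                    visit_index=int(row["visit_index"]),
                    months_since_baseline=float(row["months_since_baseline"]),
                    diagnosis=dx,
                    values=values,
                )
            )
        first = grp.iloc[0]
        participants.append(
            Participant(
                participant_id=str(pid),
                sex=str(first["sex"]),
                apoe4=str(first["apoe4"]).lower() in ("yes", "true", "1"),
                age_at_baseline=float(first["age_at_baseline"]),
                visits=tuple(visits),
            )
        )
    return Cohort(schema=schema, participants=tuple(participants))
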