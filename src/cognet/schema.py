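"""Canonical clinical variable schema.

The analysis operates on a fixed, ordered set of clinical variables observed
at every study visit: chronic conditions (binary diagnoses), cognitive and
functional severity scores (CDR global score, CDR sum of boxes, FAQ),
neuropsychiatric symptoms (NPI-Q item presence plus the Beck depression and
anxiety inventories) and APOE e4 carrier status.  The schema fixes variable
names, value ranges and measurement kind, and its order defines the layout
of every downstream matrix, graph node list and feature vector.

Two schema modes exist: the 26-variable network schema (the variables that
appear as network nodes) and an extended 29-variable mode that additionally
carries the demographic covariates Age, Sex and Education.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import yaml

__all__ = [
    "Group",
    "Kind",
    "SchemaEntry",
    "VariableSchema",
    "default_schema",
    "COGNITIVE_FUNCTIONAL",
]


class Group(str, enum.Enum):
    """Clinical grouping of a variable."""

    DEMOGRAPHIC = "demographic"
    GENOTYPE = "genotype"
    CHRONIC = "chronic"
    COGNITIVE_FUNCTIONAL = "cognitive_functional"
    NEUROPSYCHIATRIC = "neuropsychiatric"


class Kind(str, enum.Enum):
    """Measurement kind of a variable."""

    BINARY = "binary"
    ORDINAL = "ordinal"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    group: Group
    kind: Kind
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.kind is Kind.BINARY:
            if (self.min, self.max) != (0.0, 1.0):
                raise ValueError(
                    f"binary variable {self.name!r} must have range [0, 1], "
                    f"got [{self.min}, {self.max}]"
                )
        elif not self.min < self.max:
            raise ValueError(
                f"variable {self.name!r} needs min < max, "
                f"got [{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of :class:`SchemaEntry`.

    The entry order is canonical: matrices, graphs and feature vectors all
    follow it.  Names must be unique.
    """

    entries: tuple[SchemaEntry, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SchemaEntry]:
        return iter(self.entries)

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> SchemaEntry:
        return self.entries[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def subset(self, names: Iterable[str]) -> "VariableSchema":
        """Restrict to ``names``, preserving canonical order."""
        keep = set(names)
        unknown = keep - set(self._index)
        if unknown:
            raise KeyError(f"unknown variables: {sorted(unknown)}")
        return VariableSchema(tuple(e for e in self.entries if e.name in keep))

    def by_group(self, group: Group) -> list[str]:
        return [e.name for e in self.entries if e.group is group]

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": e.name,
                "group": e.group.value,
                "kind": e.kind.value,
                "min": float(e.min),
                "max": float(e.max),
            }
            for e in self.entries
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        entries = tuple(
            SchemaEntry(
                name=item["name"],
                group=Group(item["group"]),
                kind=Kind(item["kind"]),
                min=float(item["min"]),
                max=float(item["max"]),
            )
            for item in payload
        )
        return cls(entries)


def _b(name: str, group: Group) -> SchemaEntry:
    return SchemaEntry(name, group, Kind.BINARY, 0.0, 1.0)


# The 26 network variables, in canonical order.  NPI-Q items are recorded as
# symptom presence (0/1); the Beck inventories and the cognitive/functional
# scores keep their instrument ranges.
_NETWORK_ENTRIES: tuple[SchemaEntry, ...] = (
    _b("APOE4", Group.GENOTYPE),
    _b("MotorBehavior", Group.NEUROPSYCHIATRIC),
    SchemaEntry("BeckDepression", Group.NEUROPSYCHIATRIC, Kind.ORDINAL, 0.0, 63.0),
    SchemaEntry("BeckAnxiety", Group.NEUROPSYCHIATRIC, Kind.ORDINAL, 0.0, 63.0),
    SchemaEntry("CDRSum", Group.COGNITIVE_FUNCTIONAL, Kind.ORDINAL, 0.0, 18.0),
    SchemaEntry("CDRGlob", Group.COGNITIVE_FUNCTIONAL, Kind.ORDINAL, 0.0, 3.0),
    SchemaEntry("FAQ", Group.COGNITIVE_FUNCTIONAL, Kind.ORDINAL, 0.0, 30.0),
    _b("Depression", Group.NEUROPSYCHIATRIC),
    _b("Diabetes", Group.CHRONIC),
    _b("Dyslipidemia", Group.CHRONIC),
    _b("Delusion", Group.NEUROPSYCHIATRIC),
    _b("Hallucination", Group.NEUROPSYCHIATRIC),
    _b("Agitation", Group.NEUROPSYCHIATRIC),
    _b("Anxiety", Group.NEUROPSYCHIATRIC),
    _b("Apathy", Group.NEUROPSYCHIATRIC),
    _b("Disinhibition", Group.NEUROPSYCHIATRIC),
    _b("Appetite", Group.NEUROPSYCHIATRIC),
    _b("Irritability", Group.NEUROPSYCHIATRIC),
    _b("PeripheralVascular", Group.CHRONIC),
    _b("Euphoria", Group.NEUROPSYCHIATRIC),
    _b("Angina", Group.CHRONIC),
    _b("Hypertension", Group.CHRONIC),
    _b("CoronaryArtery", Group.CHRONIC),
    _b("MyocardialInfarction", Group.CHRONIC),
    _b("Stroke", Group.CHRONIC),
    _b("AtrialFibrillation", Group.CHRONIC),
)

_DEMOGRAPHIC_ENTRIES: tuple[SchemaEntry, ...] = (
    SchemaEntry("Age", Group.DEMOGRAPHIC, Kind.CONTINUOUS, 50.0, 105.0),
    _b("Sex", Group.DEMOGRAPHIC),
    SchemaEntry("Education", Group.DEMOGRAPHIC, Kind.ORDINAL, 0.0, 20.0),
)

#: The cognitive/functional severity scores that drive conversion.
COGNITIVE_FUNCTIONAL: tuple[str, ...] = ("CDRSum", "CDRGlob", "FAQ")


def default_schema(include_demographics: bool = False) -> VariableSchema:
    """Return the canonical variable schema.

    Parameters
    ----------
    include_demographics
        When True, append Age, Sex and Education (29 variables total);
        otherwise return the 26 network variables.
    """
    entries = _NETWORK_ENTRIES
    if include_demographics:
        entries = entries + _DEMOGRAPHIC_ENTRIES
    return VariableSchema(entries)
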