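"""Characterizing progression from MCI to dementia.

For every participant, community and follow-up visit, the Euclidean
distance between the community's feature vector at that visit and the same
vector at the participant's first MCI visit measures how far the
participant's clinical profile has travelled.  Large travelled distances
on the cognitive/functional community flag imminent or established
dementia; the distance axis is cut into risk bands (> 20 high, 10-20
moderate, <= 10 low), and an intercept-form decision line in the
(time-lapse, distance) plane separates the region where participants
typically remain in MCI.

Distances are computed on the raw clinical scales by default.  A
normalized mode (min-max by instrument range) is available; note that on
normalized scales a community of l variables bounds every distance by
sqrt(l), so the raw scale is the one on which the 10/20 band cutoffs are
meaningful.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Diagnosis, Participant
from .communities import CommunityPartition

__all__ = [
    "DistanceRecord",
    "BoundaryLine",
    "RiskBand",
    "community_distances",
    "boundary_line",
    "risk_band",
    "band_outcome_rates",
    "sex_stratified_summary",
    "match_communities",
    "records_to_frame",
    "frame_to_records",
    "find_community",
]


@dataclass(frozen=True)
class DistanceRecord:
    participant_id: str
    community_id: int
    visit_index_i: int  # first MCI visit
    visit_index_j: int  # later visit
    time_lapse_years: float
    distance: float
    diagnosis_at_tj: Diagnosis
    sex: str

    def __post_init__(self) -> None:
        if self.time_lapse_years < 0:
            raise ValueError("time_lapse_years must be non-negative")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


class RiskBand(str, enum.Enum):
    """Distance bands with their dementia-probability annotations."""

    HIGH = "high"  # distance > 20, annotated > 90% chance of dementia
    MODERATE = "moderate"  # 10 < distance <= 20, annotated ~70%
    LOW = "low"  # distance <= 10, no annotation

    @property
    def probability_note(self) -> str | None:
        return {"high": ">90%", "moderate": "70%", "low": None}[self.value]


def risk_band(distance: float) -> RiskBand:
    """Classify a travelled distance into its dementia-risk band."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance > 20:
        return RiskBand.HIGH
    if distance > 10:
        return RiskBand.MODERATE
    return RiskBand.LOW


@dataclass(frozen=True)
class BoundaryLine:
    """Intercept-form decision line x/a + y/b = 1, i.e. bx + ay = ab.

    ``a`` is the x-intercept (time-lapse, years) and ``b`` the y-intercept
    (distance units).
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("both intercepts must be positive")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """(b, a, ab) such that b*x + a*y = ab on the line."""
        return (self.b, self.a, self.a * self.b)

    def classify_side(self, x: float, y: float, tol: float = 1e-9) -> str:
        """'below', 'on' or 'above' relative to the line."""
        value = self.b * x + self.a * y - self.a * self.b
        scale = max(abs(self.a * self.b), 1.0)
        if abs(value) <= tol * scale:
            return "on"
        return "above" if value > 0 else "below"


def boundary_line(a: float, b: float) -> BoundaryLine:
    """Construct the decision line with x-intercept ``a``, y-intercept ``b``."""
    return BoundaryLine(a=a, b=b)


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def _first_index(p: Participant, dx: Diagnosis) -> int:
    return p.diagnoses().index(dx)


def _community_vector(
    visit_values: dict[str, float],
    variables: list[str],
    schema,
    scale: str,
) -> np.ndarray:
    vec = []
    for name in variables:
        x = visit_values.get(name, np.nan)
        if scale == "normalized" and not np.isnan(x):
            entry = schema[name]
            x = (x - entry.min) / (entry.max - entry.min)
        vec.append(x)
    return np.asarray(vec, dtype=float)


def community_distances(
    cohort: Cohort,
    partition: CommunityPartition,
    scale: str = "raw",
    pairing: str = "baseline",
) -> list[DistanceRecord]:
    """Per-participant, per-community travelled distances.

    For every visit strictly after the first MCI visit up to and including
    the first dementia visit, the Euclidean distance between the
    community's feature vector at that visit and its reference vector is
    recorded.  With ``pairing='baseline'`` (default) the reference is
    always the first MCI visit; ``pairing='consecutive'`` measures each
    visit against the immediately preceding one.

    Missing components are dropped pairwise from both vectors; a pair with
    no overlapping components is skipped with a warning.  ``scale='raw'``
    uses the clinical scales as recorded, ``'normalized'`` min-max scales
    each variable by its schema range first.
    """
    if scale not in ("raw", "normalized"):
        raise ValueError("scale must be 'raw' or 'normalized'")
    if pairing not in ("baseline", "consecutive"):
        raise ValueError("pairing must be 'baseline' or 'consecutive'")
    unknown = set().union(*partition.communities) - set(cohort.schema.names)
    if unknown:
        raise KeyError(
            f"partition references variables outside the cohort schema: "
            f"{sorted(unknown)}"
        )
    comm_vars = [sorted(c, key=cohort.schema.index) for c in partition.communities]
    records: list[DistanceRecord] = []
    for p in sorted(cohort.participants, key=lambda q: q.participant_id):
        first_mci = _first_index(p, Diagnosis.MCI)
        first_dem = _first_index(p, Diagnosis.DEM)
        base_visit = p.visits[first_mci]
        for cid, variables in enumerate(comm_vars):
            for t in range(first_mci + 1, first_dem + 1):
                visit = p.visits[t]
                ref_visit = base_visit if pairing == "baseline" else p.visits[t - 1]
                v_ref = _community_vector(
                    ref_visit.values, variables, cohort.schema, scale
                )
                v_now = _community_vector(
                    visit.values, variables, cohort.schema, scale
                )
                ok = ~(np.isnan(v_ref) | np.isnan(v_now))
                if not ok.any():
                    warnings.warn(
                        f"{p.participant_id} community {cid} visit "
                        f"{visit.visit_index}: no overlapping non-missing "
                        "components; record skipped",
                        stacklevel=2,
                    )
                    continue
                dist = float(np.linalg.norm(v_now[ok] - v_ref[ok]))
                records.append(
                    DistanceRecord(
                        participant_id=p.participant_id,
                        community_id=cid,
                        visit_index_i=ref_visit.visit_index,
                        visit_index_j=visit.visit_index,
                        time_lapse_years=(
                            visit.months_since_baseline
                            - base_visit.months_since_baseline
                        )
                        / 12.0,
                        distance=dist,
                        diagnosis_at_tj=visit.diagnosis,
                        sex=p.sex,
                    )
                )
    return records


def find_community(partition: CommunityPartition, variable: str) -> int:
    """Community index (canonical order) containing ``variable``."""
    for cid, comm in enumerate(partition.communities):
        if variable in comm:
            return cid
    raise KeyError(variable)


# --------------------------------------------------------------------------
# Band and sex-stratified summaries
# --------------------------------------------------------------------------

def band_outcome_rates(
    records: list[DistanceRecord], mode: str = "by_participant"
) -> pd.DataFrame:
    """Dementia outcome rates per distance band.

    ``mode='by_participant'`` (default): within each band, the fraction of
    distinct participants having a visit in that band who progress to
    dementia by the end of follow-up.  ``mode='by_visit'``: the fraction of
    the band's visit records whose diagnosis is already DEM.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if mode not in ("by_participant", "by_visit"):
        raise ValueError("mode must be 'by_participant' or 'by_visit'")
    converted = {
        pid
        for pid in {r.participant_id for r in records}
        if any(
            r.participant_id == pid and r.diagnosis_at_tj is Diagnosis.DEM
            for r in records
        )
    }
    rows = []
    for band in (RiskBand.HIGH, RiskBand.MODERATE, RiskBand.LOW):
        in_band = [r for r in records if risk_band(r.distance) is band]
        n_visits = len(in_band)
        if n_visits == 0:
            frac = np.nan
        elif mode == "by_visit":
            frac = sum(
                r.diagnosis_at_tj is Diagnosis.DEM for r in in_band
            ) / n_visits
        else:
            pids = {r.participant_id for r in in_band}
            frac = len(pids & converted) / len(pids)
        rows.append(
            {
                "band": band.value,
                "n_visits": n_visits,
                "fraction_dem": frac,
            }
        )
    return pd.DataFrame(rows)


def sex_stratified_summary(
    records: list[DistanceRecord],
    cutoff_years: float = 5.0,
    d_cut: float = 5.0,
) -> pd.DataFrame:
    """Sex- and community-stratified late-follow-up distance summary.

    Restricts to visits more than ``cutoff_years`` after the first MCI
    visit and reports, per sex and community: the number of such visits,
    the percentage with distance <= ``d_cut`` (little change), and the
    dementia fraction among visits with distance > ``d_cut``.  Empty strata
    produce a row with n = 0 and NaN percentages.
    """
    late = [r for r in records if r.time_lapse_years > cutoff_years]
    communities = sorted({r.community_id for r in records})
    rows = []
    for sex in ("F", "M"):
        for cid in communities:
            stratum = [
                r for r in late if r.sex == sex and r.community_id == cid
            ]
            n = len(stratum)
            if n == 0:
                pct_le = np.nan
            else:
                pct_le = 100.0 * sum(r.distance <= d_cut for r in stratum) / n
            above = [r for r in stratum if r.distance > d_cut]
            if not above:
                pct_dem = np.nan
            else:
                pct_dem = (
                    100.0
                    * sum(r.diagnosis_at_tj is Diagnosis.DEM for r in above)
                    / len(above)
                )
            rows.append(
                {
                    "sex": sex,
                    "community_id": cid,
                    "n_visits_after_cutoff": n,
                    "pct_distance_le_dcut": pct_le,
                    "pct_dem_given_d_gt_dcut": pct_dem,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cross-phase community matching
# --------------------------------------------------------------------------

def match_communities(
    p1: CommunityPartition, p2: CommunityPartition
) -> list[dict]:
    """Greedy maximal-Jaccard matching between two partitions.

    Both partitions must cover the same variable universe.  Pairs are
    matched in decreasing Jaccard order (ties broken lexicographically on
    the sorted community members); each community matches at most once and
    unmatched communities map to None.
    """
    if p1.nodes != p2.nodes:
        raise ValueError("partitions cover different variable universes")
    scored = []
    for i, c1 in enumerate(p1.communities):
        for j, c2 in enumerate(p2.communities):
            union = len(c1 | c2)
            jac = len(c1 & c2) / union if union else 0.0
            scored.append((jac, sorted(c1), sorted(c2), i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    matches: dict[int, tuple[int, float]] = {}
    for jac, _, _, i, j in scored:
        if jac <= 0 or i in used1 or j in used2:
            continue
        matches[i] = (j, jac)
        used1.add(i)
        used2.add(j)
    out = []
    for i, c1 in enumerate(p1.communities):
        j, jac = matches.get(i, (None, None))
        out.append(
            {
                "community_1": i,
                "members_1": sorted(c1),
                "community_2": j,
                "members_2": sorted(p2.communities[j]) if j is not None else None,
                "jaccard": jac,
            }
        )
    return out


# --------------------------------------------------------------------------
# Record <-> frame conversion
# --------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "participant_id",
    "community_id",
    "visit_index_i",
    "visit_index_j",
    "time_lapse_years",
    "distance",
    "diagnosis_at_tj",
    "sex",
]


def records_to_frame(records: list[DistanceRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": r.participant_id,
            "community_id": r.community_id,
            "visit_index_i": r.visit_index_i,
            "visit_index_j": r.visit_index_j,
            "time_lapse_years": r.time_lapse_years,
            "distance": r.distance,
            "diagnosis_at_tj": str(r.diagnosis_at_tj),
            "sex": r.sex,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DistanceRecord]:
    return [
        DistanceRecord(
            participant_id=str(row.participant_id),
            community_id=int(row.community_id),
            visit_index_i=int(row.visit_index_i),
            visit_index_j=int(row.visit_index_j),
            time_lapse_years=float(row.time_lapse_years),
            distance=float(row.distance),
            diagnosis_at_tj=Diagnosis[str(row.diagnosis_at_tj)],
            sex=str(row.sex),
        )
        for row in frame.itertuples(index=False)
    ]
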