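"""Synthetic longitudinal cohort generator.

The study data this package analyzes (a population-based aging cohort with
consensus diagnoses) is access-restricted, so the package ships a
generator that emulates its structure: 97 participants (49 female, 41
APOE e4 carriers), visits every 15 months, a cognitively-unimpaired
baseline visit followed by incident MCI and eventual dementia, with 2-7
visits from the first MCI diagnosis to the dementia diagnosis.

Values are drawn from a latent-Gaussian copula: per visit a multivariate
normal draw with a block correlation structure (three planted blocks —
cognitive/functional scores, chronic conditions, neuropsychiatric
symptoms — plus weak cross-block correlation) is mapped to each variable's
measurement kind: binary variables by a prevalence quantile threshold,
ordinal scores by an affine map rounded to the instrument's granularity
and clipped to its range.  Cognitive/functional scores accrue a per-visit
drift after MCI onset, and conversion to dementia is coupled to that
decline through a logistic hazard on the Euclidean distance of the
(CDRSum, CDRGlob, FAQ) vector from its value at the first MCI visit, so
large travelled distances predict conversion by construction.

The generator makes no attempt to match the source study's marginal
distributions beyond the demographic counts and the direction of decline;
it exists to realize the correlation and progression structure that the
downstream analysis assumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, Diagnosis, Participant, Visit, write_visits_csv
from .network import CorrelationMatrix, write_correlation_csv
from .schema import COGNITIVE_FUNCTIONAL, Kind, VariableSchema, default_schema

__all__ = [
    "Block",
    "Hazard",
    "GeneratorConfig",
    "generate_cohort",
    "plant_progression_labels",
    "two_block_matrix",
    "write_fixture_suite",
    "DEFAULT_BLOCKS",
    "DEFAULT_HAZARD",
]

_PHASES = ("MCI_V", "M2D_V", "DEM_V")


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class Block:
    """A set of variables sharing a common latent within-block correlation.

    An optional hub variable correlates with every other member at
    ``hub_r > within_r``, giving the block a core-spoke tier.  This mirrors
    how summary severity scores behave in clinical data (a sum score
    correlates more strongly with each domain than the domains do with each
    other) and gives thresholded networks a realistic disassortative
    backbone once weak edges are pruned.
    """

    name: str
    variables: tuple[str, ...]
    within_r: float
    hub: str | None = None
    hub_r: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.within_r < 1:
            raise ConfigurationError(
                f"block {self.name!r}: within_r must lie in (0, 1)"
            )
        object.__setattr__(self, "variables", tuple(self.variables))
        if (self.hub is None) != (self.hub_r is None):
            raise ConfigurationError(
                f"block {self.name!r}: hub and hub_r must be set together"
            )
        if self.hub is not None:
            if self.hub not in self.variables:
                raise ConfigurationError(
                    f"block {self.name!r}: hub {self.hub!r} not a member"
                )
            if not self.within_r < self.hub_r < 1:
                raise ConfigurationError(
                    f"block {self.name!r}: hub_r must lie in (within_r, 1)"
                )


@dataclass(frozen=True)
class Hazard:
    """Logistic conversion hazard: P(convert) = expit(alpha + beta * D)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigurationError(
                "hazard beta must be non-negative (a negative beta would "
                "invert the planted distance-conversion relationship)"
            )

    def probability(self, distance: float) -> float:
        return float(expit(self.alpha + self.beta * distance))


#: Planted correlation blocks (identical across the three phases).  Every
#: variable except the genotype belongs to a clinical domain: severity
#: scores travel together, cardiovascular/metabolic conditions cluster,
#: and neuropsychiatric symptoms co-occur.  Each block carries a hub — a
#: summary measure correlating more strongly with every member than the
#: members do with each other — so that pruning weak edges exposes a
#: star-like backbone, the regime in which a thresholded clinical network
#: turns disassortative.
DEFAULT_BLOCKS: tuple[Block, ...] = (
    Block(
        "cognitive_functional",
        ("CDRSum", "CDRGlob", "FAQ"),
        within_r=0.50,
        hub="CDRSum",
        hub_r=0.80,
    ),
    Block(
        "chronic",
        (
            "Hypertension",
            "Dyslipidemia",
            "Diabetes",
            "CoronaryArtery",
            "MyocardialInfarction",
            "AtrialFibrillation",
            "Stroke",
            "Angina",
            "PeripheralVascular",
        ),
        within_r=0.55,
        hub="Hypertension",
        hub_r=0.77,
    ),
    Block(
        "neuropsychiatric",
        (
            "BeckDepression",
            "BeckAnxiety",
            "Depression",
            "Anxiety",
            "Agitation",
            "Apathy",
            "Irritability",
            "Disinhibition",
            "Appetite",
            "MotorBehavior",
            "Delusion",
            "Hallucination",
            "Euphoria",
        ),
        within_r=0.50,
        hub="BeckDepression",
        hub_r=0.73,
    ),
)

#: Shipped logistic-hazard calibration; see scripts/calibrate_hazard.py for
#: the procedure that produced these constants.
DEFAULT_HAZARD = Hazard(alpha=-4.0, beta=0.3)

#: Per-visit mean shift applied to converters after MCI onset.
DEFAULT_DRIFT: dict[str, float] = {"CDRSum": 1.3, "CDRGlob": 0.18, "FAQ": 3.5}


@dataclass(frozen=True)
class _Marginal:
    prevalence: float | None = None  # binary variables
    mean: float = 0.0
    sd: float = 1.0
    granularity: float = 1.0  # ordinal rounding step


# Marginal parameters at the MCI stage.  Binary prevalences are kept in a
# moderate band (0.2-0.6) so that phi correlations retain usable signal at
# n ~ 100; they are design choices of the generator, not estimates of the
# source study's marginals (which the generator does not try to match).
DEFAULT_MARGINALS: dict[str, _Marginal] = {
    "MotorBehavior": _Marginal(prevalence=0.25),
    "BeckDepression": _Marginal(mean=8.0, sd=5.0),
    "BeckAnxiety": _Marginal(mean=6.0, sd=4.0),
    "CDRSum": _Marginal(mean=1.0, sd=1.0),
    "CDRGlob": _Marginal(mean=0.4, sd=0.25, granularity=0.5),
    "FAQ": _Marginal(mean=3.2, sd=4.6),
    "Depression": _Marginal(prevalence=0.40),
    "Diabetes": _Marginal(prevalence=0.30),
    "Dyslipidemia": _Marginal(prevalence=0.55),
    "Delusion": _Marginal(prevalence=0.25),
    "Hallucination": _Marginal(prevalence=0.25),
    "Agitation": _Marginal(prevalence=0.30),
    "Anxiety": _Marginal(prevalence=0.35),
    "Apathy": _Marginal(prevalence=0.35),
    "Disinhibition": _Marginal(prevalence=0.25),
    "Appetite": _Marginal(prevalence=0.25),
    "Irritability": _Marginal(prevalence=0.35),
    "PeripheralVascular": _Marginal(prevalence=0.25),
    "Euphoria": _Marginal(prevalence=0.25),
    "Angina": _Marginal(prevalence=0.25),
    "Hypertension": _Marginal(prevalence=0.60),
    "CoronaryArtery": _Marginal(prevalence=0.35),
    "MyocardialInfarction": _Marginal(prevalence=0.30),
    "Stroke": _Marginal(prevalence=0.25),
    "AtrialFibrillation": _Marginal(prevalence=0.30),
    "APOE4": _Marginal(prevalence=0.42),  # overwritten by exact carrier count
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-emulation configuration; the defaults are the study conditions."""

    n_participants: int = 97
    n_female: int = 49
    n_apoe4_pos: int = 41
    visit_interval_months: float = 15.0
    visits_mci_to_dem: tuple[int, int] = (2, 7)
    blocks: dict[str, tuple[Block, ...]] = field(
        default_factory=lambda: {p: DEFAULT_BLOCKS for p in _PHASES}
    )
    cross_block_r: float = 0.05
    drift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    hazard: Hazard = DEFAULT_HAZARD
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not 0 <= self.n_female <= self.n_participants:
            raise ConfigurationError("n_female must lie in [0, n_participants]")
        if not 0 <= self.n_apoe4_pos <= self.n_participants:
            raise ConfigurationError("n_apoe4_pos must lie in [0, n_participants]")
        lo, hi = self.visits_mci_to_dem
        if not 2 <= lo <= hi:
            raise ConfigurationError(
                "visits_mci_to_dem must be an increasing range with lo >= 2"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        schema = default_schema()
        for phase, blocks in self.blocks.items():
            seen: set[str] = set()
            for block in blocks:
                unknown = set(block.variables) - set(schema.names)
                if unknown:
                    raise ConfigurationError(
                        f"block {block.name!r}: unknown variables "
                        f"{sorted(unknown)}"
                    )
                overlap = seen & set(block.variables)
                if overlap:
                    raise ConfigurationError(
                        f"{phase}: blocks overlap on {sorted(overlap)}"
                    )
                seen |= set(block.variables)
                if block.within_r <= self.cross_block_r:
                    raise ConfigurationError(
                        f"block {block.name!r}: within_r must exceed "
                        f"cross_block_r={self.cross_block_r}"
                    )
            # construction-time positive-definiteness check
            sigma = _latent_sigma(schema, blocks, self.cross_block_r)
            eigmin = float(np.linalg.eigvalsh(sigma).min())
            if eigmin <= 1e-10:
                raise ConfigurationError(
                    f"{phase}: latent correlation matrix is not positive "
                    f"definite (min eigenvalue {eigmin:.3e}); offending "
                    f"blocks: {[b.name for b in blocks]}"
                )


def _latent_sigma(
    schema: VariableSchema, blocks: tuple[Block, ...], cross_r: float
) -> np.ndarray:
    p = len(schema)
    sigma = np.full((p, p), cross_r)
    np.fill_diagonal(sigma, 1.0)
    for block in blocks:
        idx = [schema.index(n) for n in block.variables]
        for i in idx:
            for j in idx:
                if i != j:
                    sigma[i, j] = block.within_r
        if block.hub is not None:
            h = schema.index(block.hub)
            for i in idx:
                if i != h:
                    sigma[h, i] = sigma[i, h] = block.hub_r
    return sigma


def plant_progression_labels(
    distances: list[float],
    hazard: Hazard,
    rng: np.random.Generator,
    max_mci_to_dem: int,
) -> list[Diagnosis]:
    """Assign post-onset diagnosis labels from a logistic conversion hazard.

    ``distances[j]`` is the travelled cognitive/functional distance of the
    j-th visit after MCI onset (j = 0 is the first MCI visit, distance 0).
    Conversion at visit j >= 1 occurs with probability
    ``expit(alpha + beta * distances[j])``; conversion is forced at
    j = max_mci_to_dem - 1 so the MCI-to-dementia visit count stays within
    the configured range.  Labels after the first DEM are not produced
    (follow-up ends at the dementia diagnosis).
    """
    labels = [Diagnosis.MCI]
    for j in range(1, max_mci_to_dem):
        forced = j == max_mci_to_dem - 1
        if forced or rng.random() < hazard.probability(distances[j]):
            labels.append(Diagnosis.DEM)
            return labels
        labels.append(Diagnosis.MCI)
    return labels


def _map_latent(
    name: str,
    z: float,
    schema: VariableSchema,
    marginals: dict[str, _Marginal],
    drift_shift: float,
) -> float:
    entry = schema[name]
    marg = marginals.get(name, _Marginal())
    if entry.kind is Kind.BINARY:
        return 1.0 if z > norm.ppf(1.0 - (marg.prevalence or 0.5)) else 0.0
    x = marg.mean + marg.sd * z + drift_shift
    if entry.kind is Kind.ORDINAL:
        step = marg.granularity
        x = round(x / step) * step
    return float(np.clip(x, entry.min, entry.max))


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Every generated participant follows CU -> MCI -> ... -> DEM and passes
    the study-sample selection criteria.  Visits are spaced exactly
    ``visit_interval_months`` apart.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    schema = default_schema()
    names = schema.names
    lo, hi = config.visits_mci_to_dem

    chol = {
        phase: np.linalg.cholesky(
            _latent_sigma(schema, config.blocks[phase], config.cross_block_r)
        )
        for phase in _PHASES
    }

    n = config.n_participants
    width = max(3, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    female = set(rng.choice(n, size=config.n_female, replace=False).tolist())
    apoe4 = set(rng.choice(n, size=config.n_apoe4_pos, replace=False).tolist())
    ages = np.clip(rng.normal(83.0, 5.5, size=n), 70.0, 95.0)

    participants = []
    cf = list(COGNITIVE_FUNCTIONAL)
    for i in range(n):
        k_max = int(rng.integers(lo, hi + 1))
        carrier = i in apoe4
        # draw post-onset visits sequentially; conversion truncates follow-up
        visit_values: list[dict[str, float]] = []
        distances: list[float] = [0.0]
        baseline_cf: np.ndarray | None = None

        def draw_visit(phase: str, drift_steps: int) -> dict[str, float]:
            z = chol[phase] @ rng.standard_normal(len(names))
            values = {}
            for idx, name in enumerate(names):
                shift = config.drift.get(name, 0.0) * drift_steps
                values[name] = _map_latent(
                    name, float(z[idx]), schema, DEFAULT_MARGINALS, shift
                )
            values["APOE4"] = 1.0 if carrier else 0.0
            return values

        # CU baseline, then first MCI visit
        visit_values.append(draw_visit("MCI_V", 0))
        first_mci = draw_visit("MCI_V", 0)
        visit_values.append(first_mci)
        baseline_cf = np.array([first_mci[v] for v in cf])
        # intermediate visits (drawn up to the forced-conversion horizon)
        for j in range(1, k_max):
            phase = "DEM_V" if j == k_max - 1 else "M2D_V"
            vals = draw_visit(phase, j)
            visit_values.append(vals)
            vec = np.array([vals[v] for v in cf])
            distances.append(float(np.linalg.norm(vec - baseline_cf)))

        labels = plant_progression_labels(
            distances, config.hazard, rng, max_mci_to_dem=k_max
        )
        dx_seq = [Diagnosis.CU] + labels
        visits = []
        for t, dx in enumerate(dx_seq):
            values = dict(visit_values[t])
            if config.missing_rate > 0:
                for name in names:
                    if name == "APOE4":
                        continue
                    if rng.random() < config.missing_rate:
                        values.pop(name, None)
            visits.append(
                Visit(
                    participant_id=ids[i],
                    visit_index=t + 1,
                    months_since_baseline=t * config.visit_interval_months,
                    diagnosis=dx,
                    values=values,
                )
            )
        participants.append(
            Participant(
                participant_id=ids[i],
                sex="F" if i in female else "M",
                apoe4=carrier,
                age_at_baseline=float(round(ages[i], 1)),
                visits=tuple(visits),
            )
        )
    return Cohort(schema=schema, participants=tuple(participants))


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

def two_block_matrix() -> CorrelationMatrix:
    """The 7-variable two-block test matrix.

    Block {A, B, C} with pairwise r = 0.6, block {D, E, F, G} with pairwise
    r = 0.3, and every cross-block r = 0.05.  At a 10% threshold the graph
    is the disjoint union of the two complete blocks.
    """
    variables = ("A", "B", "C", "D", "E", "F", "G")
    values = np.full((7, 7), 0.05)
    for idx, r in (([0, 1, 2], 0.6), ([3, 4, 5, 6], 0.3)):
        for i in idx:
            for j in idx:
                if i != j:
                    values[i, j] = r
    np.fill_diagonal(values, 1.0)
    n_pairs = np.full((7, 7), 0, dtype=int)
    return CorrelationMatrix(variables=variables, values=values, n_pairs=n_pairs)


def _tiny_cohort(trajectories: dict[str, list[Diagnosis]]) -> Cohort:
    schema = default_schema().subset(["CDRSum", "CDRGlob", "FAQ"])
    participants = []
    for pid, dxs in sorted(trajectories.items()):
        visits = tuple(
            Visit(
                participant_id=pid,
                visit_index=t + 1,
                months_since_baseline=t * 15.0,
                diagnosis=dx,
                values={"CDRSum": 1.0 + t, "CDRGlob": 0.5, "FAQ": 2.0 * t},
            )
            for t, dx in enumerate(dxs)
        )
        participants.append(
            Participant(
                participant_id=pid,
                sex="F",
                apoe4=False,
                age_at_baseline=80.0,
                visits=visits,
            )
        )
    return Cohort(schema=schema, participants=tuple(participants))


def write_fixture_suite(outdir, seed: int = 42) -> dict[str, str]:
    """Write the small named fixtures used across the test suite.

    Emits the two-block correlation matrix, three tiny cohorts exercising
    each study-selection rule, and the default 97-participant cohort CSV.
    Returns a name -> path map.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    path = os.path.join(outdir, "two_block_corr.csv")
    write_correlation_csv(two_block_matrix(), path)
    paths["two_block_corr"] = path

    CU, MCI, DEM = Diagnosis.CU, Diagnosis.MCI, Diagnosis.DEM
    tiny = {
        "eligible": {
            "T001": [CU, MCI, MCI, DEM],
            "T002": [CU, CU, MCI, MCI, MCI, DEM],
            "T003": [CU, MCI, DEM],
        },
        "baseline_impaired": {
            "T001": [MCI, DEM],
            "T002": [DEM, DEM],
            "T003": [MCI, MCI, DEM],
        },
        "never_converts": {
            "T001": [CU, MCI],
            "T002": [CU, MCI, MCI],
            "T003": [CU, CU, CU],
        },
    }
    for name, trajectories in tiny.items():
        path = os.path.join(outdir, f"{name}.csv")
        write_visits_csv(_tiny_cohort(trajectories), path)
        paths[name] = path

    path = os.path.join(outdir, "default_cohort.csv")
    write_visits_csv(generate_cohort(GeneratorConfig(seed=seed)), path)
    paths["default_cohort"] = path
    return paths
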