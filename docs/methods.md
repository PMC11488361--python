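# Methods

This note documents the models, parameter choices and numerical decisions
behind `cognet`, and what the synthetic-data tests do and do not
demonstrate about real cohort data.

## Cohort model and study-sample selection

A cohort is a set of participants, each with an ordered visit list carrying
a consensus diagnosis (CU < MCI < DEM), months since baseline, and the
clinical variable values of a fixed, ordered schema.  Diagnoses must be
monotone within a participant; non-monotone input is rejected at load time
with the offending visit numbers, on the grounds that consensus-diagnosed
trajectories are clean and silent repair would hide data errors.

The study sample keeps participants who are CU at their baseline visit,
later develop MCI, have at least two visits from the first MCI visit
onward, and progress to dementia after the first MCI visit.  An empty
result raises an explicit `NoEligibleParticipantsError` rather than letting
an empty table crash a downstream stage.  The variable filter drops a
variable when its missing fraction is *strictly* greater than the cutoff
(default 0.5): a variable missing in exactly half the rows is kept.

Three observation sets are extracted per participant: the first MCI visit
(`MCI_V`, one row), the visits strictly between first MCI and first
dementia (`M2D_V`, zero or more rows, pooled across participants), and the
first dementia visit (`DEM_V`, one row).  Pooling repeated M2D visits into
one sample is a deliberate choice; per-participant averaging is not
implemented.

The default schema holds the 26 network variables; an extended mode appends
Age, Sex and Education for 29.  Both counts are legitimate descriptions of
the variable panel (the demographic covariates are collected but are not
network nodes by default); the `include_demographics` flag switches modes.

Summary statistics use the sample standard deviation (n−1).  Min–max
normalization supports observed bounds (pooled over the object being
normalized) or the schema's instrument ranges; a zero-range variable maps
to 0 with a warning.

## Correlation networks and the threshold sweep

Correlations are standard Pearson product–moment coefficients over
pairwise-complete rows (the in-memory path is `pandas.DataFrame.corr`).
Pairs with fewer than 3 complete observations, or involving a constant
column, yield r = 0 with a warning: such pairs carry no usable association
signal, and 0 keeps them below any positive threshold.  Per-pair sample
sizes are recorded.

The graph at threshold Th connects i,j when r_ij ≥ Th/100 (ties included).
The default edge rule is *signed* (negative correlations never form
edges); an absolute-value rule is available behind a flag because the
choice is genuinely ambiguous in this style of analysis.  All variables
stay in the graph as nodes, so isolated variables are visible.

The sweep raises Th from 10% in 1% steps and stops at the first threshold
whose graph is not assortative, returning the previous threshold.  A graph
counts as assortative only when the degree-assortativity coefficient is
*defined and strictly positive*; undefined values (edgeless graphs, and
regular graphs with zero endpoint-degree variance) count as
non-assortative.  When the starting threshold itself is non-assortative
the search returns an explicit failure result carrying the full trace —
not an exception — and the pipeline records a failure marker; analysis can
proceed with a user-fixed threshold.  At n ≈ 100 observations the 10%
graph is dense with sampling-noise edges and its assortativity sign
genuinely fluctuates near zero: on the default generator roughly one seed
in eight fails at the start.  This is a property of the method at this
sample size, not of the implementation.

## Community detection

Girvan–Newman repeatedly removes a maximum-edge-betweenness edge
(raw/unnormalized betweenness; ties broken by lexicographically smallest
edge).  Candidate partitions are the connected-component sets at each
split level, including the initial one; the default stopping rule returns
the level maximizing Newman–Girvan modularity (ties favour fewer
communities), and a fixed-k rule returns the first level with exactly k
components.  CNM greedy agglomeration starts from singletons and merges
the pair with the largest modularity gain, breaking ties by the
lexicographically smallest pair of community labels (a community is
labelled by its smallest member), and stops when no gain is positive; its
modularity trace is strictly increasing by construction.  CNM is
implemented in-package because deterministic tie-breaking is a hard
requirement; networkx's greedy implementation serves as an independent
cross-check in the tests.  Modularity is unweighted throughout, and
isolated nodes become singleton communities.

## Progression distances, bands and the boundary line

For every participant, community, and visit T_j after the first MCI visit
up to and including the first dementia visit, the distance record holds
the Euclidean norm of the difference between the community's feature
vector at T_j and at the first MCI visit (components missing on either
side are dropped pairwise; a pair with no overlap is skipped with a
warning).  Time lapse is (months_j − months_MCI)/12 years.

Distances default to the **raw clinical scales**.  A normalized mode
(min–max by instrument range) exists, but on normalized scales a
community of l variables bounds every distance by √l, which is
incompatible with band cutoffs at 10 and 20 — those cutoffs are only
meaningful on raw scales, where FAQ (0–30) and CDR sum of boxes (0–18)
dominate.  Both modes ship; raw is the default and the band analysis
assumes it.

Bands: distance > 20 high (annotated > 90% probability of dementia),
10 < d ≤ 20 moderate (annotated 70%), d ≤ 10 low.  Band outcome rates are
computed per participant by default ("people who progressed"): within each
band, the fraction of distinct participants having a visit in the band who
carry a dementia diagnosis by end of follow-up; a per-visit mode reports
the fraction of the band's visits already labelled DEM.  The boundary line
x/a + y/b = 1 is stored as coefficients (b, a, ab) — for the defaults
a = 9, b = 25 this is 25x + 9y = 225 — with a point classifier that is
invariant under positive rescaling of the coefficients.

The baseline for distances is always the first MCI visit; a
consecutive-visit pairing is available behind a flag for analyses of
between-visit change.  Sex-stratified summaries restrict to visits more
than `cutoff_years` (default 5) after the first MCI visit and report, per
sex and community, the percentage of visits with distance ≤ `d_cut`
(default 5) and the dementia fraction among the rest; empty strata produce
n = 0 rows with undefined percentages.

## The synthetic cohort generator

The motivating cohort is access-restricted, so the generator exists to
realize — not to estimate — the structure the analysis assumes: 97
participants (49 female, 48 male, 41 APOE e4 carriers), visits exactly 15
months apart, one CU baseline visit, then 2–7 visits from first MCI to
first dementia, monotone trajectories throughout, block-correlated
variables, and cognitive/functional scores that worsen toward conversion.
Durations follow the counting convention that k MCI-to-dementia visits
span k x 15 months.

**Latent-Gaussian copula.**  Each visit draws a 26-dimensional normal
vector with unit variances and a planted correlation structure, then maps
each coordinate to its variable's kind: binary variables by a
prevalence-quantile threshold, ordinal scores by an affine map rounded to
the instrument granularity (0.5 for CDR global, 1 otherwise) and clipped
to the schema range.  APOE4 is overwritten by an exact-count carrier
assignment.  The discretization *attenuates* correlations: a latent r of
0.55 between two binary variables with prevalences near 0.3 realizes as a
phi coefficient near 0.35.  Tests of correlation fidelity therefore
compare sample correlations against a Monte-Carlo oracle of the mapped
correlation (and against the latent value directly only for the
lightly-discretized score pairs).

**Planted blocks with hubs.**  Three domain blocks cover every variable
except the genotype: cognitive/functional (CDRSum, CDRGlob, FAQ; member
r = 0.50, hub CDRSum at 0.80), chronic cardiovascular/metabolic (9
variables; member r = 0.55, hub Hypertension at 0.77), neuropsychiatric
(13 variables; member r = 0.50, hub BeckDepression at 0.73), with 0.05
between blocks.  The hub tier — a summary measure correlating more
strongly with each member than members do with each other — mirrors how
sum scores behave in clinical panels, and it is what makes the
assortativity-bounded sweep well-posed on synthetic data: as the threshold
rises past the member–member strengths each block becomes a star, the
graph turns disassortative, and the sweep stops while every member is
still attached to its hub.  Design experiments with exchangeable
(hub-free) blocks showed the opposite: the graph stays assortative while
blocks disintegrate edge by edge, the sweep overshoots, and the planted
partition is unrecoverable.  Hub strengths sit just under the
positive-definiteness cap h² < w + (1−w)/m for an m-member block; the
configured matrix is eigenvalue-checked at construction.

**Marginals.**  Binary prevalences (0.25–0.6) and score means/sds are
design choices, not estimates of the source cohort: prevalences below
~0.2 produce heavy-tailed phi noise at n = 97 (a single chance
co-occurrence of two rare symptoms yields a large spurious correlation)
that destabilizes the threshold sweep.  Missingness defaults to 0; tests
of the missing-data paths inject it explicitly.

**Progression and conversion.**  After MCI onset the cognitive/functional
scores drift per visit (CDRSum +1.3, CDRGlob +0.18, FAQ +3.5), so
dementia-visit means land near (CDRSum ≈ 4–6, CDRGlob ≈ 0.9–1.0,
FAQ ≈ 13–15) — worsening monotonically across MCI_V, M2D_V, DEM_V.
Conversion at each post-onset visit (from the second onward) occurs with
probability expit(α + β·D), where D is the raw-scale distance of the
(CDRSum, CDRGlob, FAQ) vector from the first-MCI visit; conversion is
forced at the participant's drawn maximum (uniform 2–7), keeping the
visit-count range exact.  The shipped calibration α = −4.0, β = 0.30
(grid search, `scripts/calibrate_hazard.py`) makes every high-band visit
(D > 20) carry the dementia label and about 62% of moderate-band visits,
over seeds 1–10.  With β = 0 conversion decouples from distance; negative
β is rejected as it would invert the planted relationship.

All randomness flows through one seeded generator; the same seed yields
byte-identical CSV output.

## What passing tests show — and what they don't

The generator plants exactly the structure the pipeline is built to find:
monotone trajectories, three correlation blocks, decline coupled to
conversion.  Passing tests therefore demonstrate the *correctness and
determinism of the machinery* (selection, correlation, sweep, detection,
distances, bands), and that the pipeline recovers planted structure at the
study's sample size — mean adjusted Rand ≥ 0.9 across seeds for both
community methods.  They do not demonstrate that real clinical data
contain such blocks, that real thresholded networks are assortative at
10%, or that the 10/20 band cutoffs are clinically calibrated.  Real data
also carry features the generator omits: within-participant autocorrelation
beyond the planted drift, informative missingness, measurement error
correlated with severity, and APOE-genotype effects.

## Numerical choices and edge cases

- Tie-breaking is lexicographic on variable names everywhere (edge
  removal, CNM merges, community ordering), making every output
  deterministic given a seed.
- Floating-point modularity comparisons use a 1e-12 tolerance.
- Undefined quantities are explicit: `None`/NaN markers for assortativity
  of regular or edgeless graphs, modularity of edgeless graphs, sd with
  n < 2, and percentages of empty strata — never silent zeros.
- The sweep trace is always returned/written for audit, including on
  failure.
- Problem sizes in the test suite: the full pipeline runs at the study
  scale (97 participants); correlation-convergence checks use a 5000-
  participant cohort; recovery properties average over seeds 1–20.

## Known limitations

- The threshold sweep's start (10%) sits in a noise-dense regime at
  n ≈ 100; its failure rate there is inherent (see above), and the M2D_V
  and DEM_V networks — whose pooled rows mix drift levels — can select
  very high thresholds or fail, leaving only the strongest block.
- CNM greedy agglomeration occasionally merges across blocks through a
  single spurious edge (a known pathology of the greedy heuristic on
  sparse graphs); Girvan–Newman, which cuts bridges first, is the default.
- Band probabilities on synthetic data are planted by calibration, not
  emergent; only their direction and ordering are meaningful.
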