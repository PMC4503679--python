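# Methods

This note documents the models, parameter choices and numerical
conventions behind `rangerisk`, and what the synthetic experiments do
and do not demonstrate.

## The assessment procedure

The package operationalises a threshold-only application of two IUCN
Red List criteria to presence-only data:

* **Criterion B1** classifies by extent of occurrence (EOO):
  CR < 100 km², EN < 5 000 km², VU < 20 000 km², otherwise LC. No
  subcriteria (fragmentation, continuing decline) are evaluated.
* **Criterion A3** classifies by *projected future population
  reduction*: VU ≥ 30 %, EN ≥ 50 %, CR ≥ 80 %. Population reduction is
  proxied by the projected proportional decline of EOO, i.e. abundance
  is assumed linear in range area. Declines below 30 % map to LC (not
  NT), and a projected *expansion* counts as zero decline — criterion
  A3 concerns reductions only; raw (possibly negative) declines are
  still reported in outputs. A species whose current EOO is zero has an
  undefined decline and is routed to Data Deficient, prominently
  logged: a zero denominator is unclassifiable by A3, not Critically
  Endangered.
* Generation-time bookkeeping (three generations ≈ 70 years, scenario
  horizon 2080–2100) is metadata only; no demographic model is run.

EOO is computed in four nested modes, each an intersection refinement
of the last: the geodesic area of the minimum convex polygon (MCP) of
the records; the area of the binarized model range; that range
restricted to suitable habitat (forest AND elevation ≥ 1500 m); and the
precautionary mode clipping the result to the *current* MCP, which
assumes no migration beyond present range boundaries. Intersections are
computed on the analysis lattice by cell-centre membership (boundary
centres count as inside), which makes clipping idempotent, commutative
and resolution-consistent.

The Red List Index is RLI = (M − T)/M with weights LC=0, NT=1, VU=2,
EN=3, CR=4 and W_EX=5, M = 5N. By default Data Deficient species remain
in N with weight 0 (`dd_policy="weight_zero"`); `"exclude"` drops them
from N. The weight-zero policy is the package default because it is the
only one of the two that reproduces the standard worked example for the
129-species assessment (0.6589 → 0.66; exclusion gives 0.6452). The
combination of a present-day and a climate-change assessment takes the
more severe category, a lattice join on the severity order with DD as
the identity.

## Distribution models

All three families are binary presence/background classifiers on the
four bioclimatic covariates, trained on the species' records against
1 000 background points drawn uniformly over the study window's cells.

* `smooth_additive` (the family used downstream): an additive logistic
  model — a cubic B-spline basis per covariate (8 knots) with an L2
  penalty on the coefficients (inverse strength C = 1). The ridge
  penalty keeps the fit defined when a specialised montane species is
  perfectly separable from background, a routine occurrence that breaks
  unpenalized IRLS fitting.
* `recursive_partition`: a CART classification tree with minimum leaf
  size 7 (mirroring rpart's default `minbucket`).
* `kernel_classifier`: an RBF support-vector machine with Platt-scaled
  probabilities; the kernel bandwidth follows the median heuristic
  (γ = 1/(2 m²), m the median pairwise distance of standardized
  covariates, estimated on ≤ 500 points).

Prediction clips covariates to the range seen in training: projections
are never extrapolated beyond the fitted support, a deliberate caution
when pushing models 3 °C outside the calibration climate. Scenario
projection reuses the fitted object — there is no refit.

Validation splits the records at the median presence latitude (ties go
north), fits on the northern half and scores held-out southern
presences against southern background by ROC/AUC (Mann–Whitney with
ties counted ½ — exact, and tested against the all-pairs count).
Two background schemes are scored: region-wide, and confined to the
species' MCP. The within-MCP scheme is systematically harder (on the
default synthetic suite: mean AUC 0.53–0.68 vs 0.97–0.99), because
inside the occupied range the climate of presences and background
largely coincides. Background points are drawn once per species per
scheme with a recorded seed and reused across methods, so method
comparisons are paired. Class imbalance is left unweighted.

**Binarization.** A continuous suitability surface becomes a range map
via a sensitivity threshold: the cutoff is the largest suitability such
that at least 90 % of the training presences score at or above it
(configurable `sensitivity=0.9`); cells at or above the cutoff are
presence. Lowering the sensitivity can only shrink the range. This is
one concrete reading of "an accuracy threshold of 0.9" — the mapping
from an AUC-style accuracy target to a cutoff is underdetermined, so
the package documents and exposes this choice rather than hiding it.
The final model for projection is always fitted on all records.

## The synthetic study system

The generator's defaults define the study conditions; they are chosen
once to emulate an upper-montane tropical system, not tuned per
experiment.

* **Terrain**: an elongated north–south massif with exponential
  (cone-like) flanks on a 64×64 lattice of 0.045° (~5 km, ≈ 25 km²)
  cells over a window in the equatorial Andes; summit 1.05 × 4000 m,
  lowland minimum −100 m. The closed, convex-ish contours give two
  properties real cordilleras share and the recovery experiment needs:
  land area per elevation band strictly decreases towards the summit,
  and the convex hull of points spread around an elevation band
  contains the band and everything above it — so an up-slope shift
  within the hull is a hypsometric net loss.
* **Climate**: mean annual temperature = 26 °C − 0.0055 °C/m × elevation
  plus a smooth noise field (SD 0.3 °C); diurnal range and the two
  precipitation layers are smooth fields (precipitation carries a
  west–east gradient). With zero noise, warming by ΔT lifts every
  isotherm by exactly ΔT/lapse ≈ 545 m for the +3 °C scenario.
* **Scenarios**: uniform warming of +3.0 °C ("A2-like") and +2.2 °C
  ("B2-like"); precipitation scale factors default to 1.0 because the
  emissions narratives quantify only the temperature signal here.
  Warming shifts the mean-annual-temperature layer only — the diurnal
  range is a temperature *difference* and is invariant under a uniform
  shift.
* **Species**: 13 planted niches (matching the size of a typical
  validation subset of well-recorded species), Gaussian in the four
  covariates, centred on the climates of random cells between 2400 and
  3900 m. They are *thermally specialised*: temperature breadth is 0.25
  regional SD (≈ 1.2 °C, a narrow elevational band), the other
  variables 1.0 SD — the narrow-thermal-tolerance profile attributed to
  upper-montane trees. Each species contributes 40 presence records
  sampled with probability proportional to suitability within forest,
  jittered within cells; country labels come from fixed longitudinal
  bands so the multi-country filter is deterministic.
* **Forest and reserves**: a smooth random field thresholded at 85 %
  cover; protected areas are dissolved cell-rectangles over randomly
  chosen montane cells hitting a 20 % coverage target to within one
  cell.
* **Filter fixture**: the candidate-selection bookkeeping runs at full
  regional scale — 3 750 candidate species of which 917 lack
  georeferenced records, 1 287 are single-country, 1 400 dip below
  1 500 m, 17 are synonyms, leaving 129; of the survivors, 9 have < 3
  unique records and 16 have 3–4, so 25 are excluded from modelling.
  All counts are constructor arguments; these are the defaults.

Every stochastic step draws from a seed derived deterministically from
one configured seed, so a run is bit-reproducible.

**What the generator does not emulate**: collection-effort bias and
spatial autocorrelation of sampling (herbarium data are partial and
biased in ways this fixture does not mimic), future land-cover change,
dispersal limitation or biotic interactions, and real GCM spatial
structure (scenarios are spatially uniform deltas). Passing recovery
tests therefore demonstrates that the *pipeline machinery* — modelling,
thresholding, masking, clipping, classification, index arithmetic — is
correct under its own assumptions, not that the method is robust to the
data pathologies of real occurrence archives.

## Ground truth and the recovery experiment

For each planted species the "true range" at the evaluation step is the
set of cells whose noise-free Gaussian suitability lies at or above the
quantile matched to the size of the modelled current range; the same
threshold, applied to scenario-shifted true suitability, projects it
forward. (With a perfectly ranking model, matched-quantile truth and
model ranges coincide exactly, so the comparison isolates ranking
error.) The default-seed experiment checks that mean region-wide AUC
across the three families exceeds 0.8, that every species with thermal
optimum above the mid-elevation isotherm has a non-negative projected
decline under +3 °C with MCP clipping, and that A3 categories from the
model match truth in ≥ 10 of 13 species. Across other seeds the
agreement typically lands between 9 and 13 of 13; the coarse 30/50/80 %
bins mean a species whose true decline sits near a boundary can flip on
estimation noise of a few percentage points.

## Numerical conventions

* **Areas**: raster areas sum per-cell (111.195 · cellsize)² · cos φ on
  the authalic sphere (R = 6371.0088 km); polygon areas use a
  cylindrical equal-area projection of the same sphere, which is
  area-exact for spherical quadrilaterals. The two agree within ~2 % at
  5-km cells for rasterized polygons.
* **Grids**: rows run north→south; a point belongs to the cell whose
  half-open interval [west, east) × (south, north] contains it, so
  shared edges never double-count. Rasters serialize as ESRI ASCII
  grids with nodata −9999.
* **Deduplication** rounds coordinates to 6 decimals (~0.1 m) and keeps
  the first record; it is idempotent and order-stable.
* **Degenerate inputs**: fewer than three non-collinear points raise
  `DegenerateHull` and route the species to DD; a constant covariate in
  a model design is rejected naming the offending variable; an
  all-constant suitability surface cannot be binarized; an empty range
  has undefined protected coverage (logged, not zero).
* **Exclusion order** in candidate selection is fixed (no
  georeference → single country → altitude → taxonomy) and each species
  is attributed to the first rule it fails, so per-rule counts are
  path-dependent but the surviving set is order-independent.
* Analysis-grid aggregation is block-mean for continuous layers and
  majority (≥ 50 %) for binary layers, complete blocks only.

## Problem sizes

The default configuration models 13 species on a 64×64 grid with 1 000
background points; the filter fixture carries 3 750 species with ~10⁴
records. A full default run, including two scenarios, three model
families and two validation schemes, completes in a few seconds on one
CPU; the whole test suite, including the recovery experiment and oracle
sweeps, runs in well under a minute.

## Known limitations

* Criterion coverage is deliberately partial: A1/A2/A4, B2 (area of
  occupancy), C, D and E are out of scope; the "formal" all-criteria
  assessment enters only as an input category table.
* The B1/A3 thresholds are applied without subcriteria, so categories
  here are "meets the numeric threshold", not full Red List
  assessments.
* The synthetic world's single massif cannot represent
  multi-cordillera disjunct ranges; MCPs of disjunct ranges would
  overestimate EOO in ways the fixture never exercises.
* Protected-area coverage uses cell-centre overlay at the analysis
  resolution; slivers smaller than a cell are invisible.
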