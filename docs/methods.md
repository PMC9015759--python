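# Methods

## The problem

Electronic health record (EHR) data can only be shared openly after
aggressive de-identification, yet environmental-health questions need
patient-level linkage between clinical events and exposures that vary over
space and time. `openexposures` implements a desk-scale version of that
compromise: clinical extracts are linked to daily pollutant surfaces,
roadway proximity, and census block-group attributes via each patient's
residential geocode and the study year; the linked values are then reduced
to coarse bins (exposure estimates are "secondary" protected information
because they derive from geocodes and dates); and the only openly exposed
artifact is a per-study-year *feature table* of bin labels, recoded
categories, and small annual counts, explored through a chi-square
association battery.

## Cohort selection

A patient enters the asthma cohort through the union of four rules:
(1) asthma diagnosis + asthma medication; (2) non-asthma respiratory
diagnosis + asthma medication; (3) non-asthma pulmonary diagnosis + an
asthma-management test/procedure (laboratory-measure criteria are folded
into this code set); (4) non-asthma respiratory diagnosis + "frequent" ED
visits in the study year with a nebulizer medication administered. Code
sets are configuration; the shipped default is a synthetic vocabulary,
because real terminologies are licensed and no public code list exists for
these criteria. "Frequent" is operationalized as >= 2 ED visits per study
year (configurable) — the threshold is not defined in the source
literature, so it is a parameter rather than a constant.

## Exposure integration

* **PM2.5** — arithmetic mean of the daily average concentration (ug/m3) of
  the grid cell containing the geocode, over the days of the calendar year
  present in the surface. Days absent from the surface are skipped, not
  imputed (the simplest defensible average).
* **Ozone** — same construction over daily *maximum* concentrations (ppb).
* **Roadway proximity** — minimum Euclidean point-to-segment distance (m)
  over all major-roadway segments, computed with shapely. Geometry is
  planar (synthetic meters); a haversine hook exists for geodetic input but
  is not the default.
* **Census attributes** — residential density class (<2500 persons per
  block group = rural; 2500–50,000 = urban cluster; >50,000 = urbanized),
  probability of no health insurance, and median household income, joined
  by block-group id when present, else point-in-extent.

Missingness propagates: a missing geocode leaves every geography-derived
field missing; a geocode outside surface coverage yields missing, not an
error. Point-in-rectangle ties on shared cell edges resolve to the lowest
cell id for determinism.

## De-identification by binning

Bins follow the HIPAA Safe Harbor approach. Age on day 1 of the study year
is binned <5, 5-17, 18-44, 45-64, 65-89; ages above 89 (the oldest
permissible age) are excluded by default (a cap-to-top-bin policy is
available, since the handling of older patients is a genuine design
choice). The shipped default schemes carry the published edges:

* income quintiles 7,470 / 36,635 / 46,750 / 59,566 / 78,355 / 250,001 US$;
* insurance-probability quartiles 0 / 0.0637 / 0.1121 / 0.1644 / 0.5548;
* PM2.5 3.27 / 6.30 / 7.81 / 10.83 ug/m3; ozone 27.80 / 39.00 / 42.73 /
  46.45 ppb;
* roadway distance 0-49 / 50-99 / 100-149 / 150-199 / 200-249 / >=250 m.

Closure: the first interval is closed on both ends, later intervals are
left-open/right-closed (so 6.30 closes the first PM2.5 bin); integer
roadway bins are left-closed `[a, a+50)`. The published PM2.5/ozone edges
are attributed to a distribution-based cut but are not equal-width, so they
ship as explicit edges; the generic fitted strategies remain available:
frequency (quantile) binning with linear-interpolation quantiles — the
common default of frequency-binning tools — and equal-width value binning.
Heavily tied data merge duplicate quantile edges with a warning; fewer
distinct values than bins is a degenerate input, not a silent fallback.
Small-cell suppression in exposed tables is available as a configurable
threshold and off by default.

## The association battery

A cohort is a conjunction of (feature, operator, value) constraints with a
stable opaque `COHORT:<hash>` identifier. An outcome is a count feature
dichotomized by a constraint (e.g. `TotalEDInpatientVisits = 0` versus the
complement). Each eligible feature (every binned/categorical feature other
than the outcome's source; count features are outcome sources, not test
features) is crossed with the dichotomy; rows missing either value are
excluded and tallied. The test is Pearson's chi-square **without continuity
correction** — required to reproduce the published statistics from their
counts — with all-zero rows/columns pruned first and df = (r-1)(c-1)
afterwards (df is returned even though the original service omitted it).
Bonferroni uses m = the number of features that actually produced a valid
test, so skipped degenerate features do not inflate the correction; with
alpha = .05 and a 50-feature battery the adjusted threshold is .001.
Contiguous ordinal bins can be collapsed (summed) before testing; the
operation preserves row marginals and the grand total. Ties in the p-value
ordering break lexicographically by feature name.

## The synthetic generator

The generator emulates the published cohort structure (N≈157,410; outcome
prevalences 16.73% ED/inpatient and 10.84% prednisone; the published
age/sex/race marginals and bin occupancies) on a planar 100 km x 100 km
region: a 20x20 block-group tiling (rural fraction 0.696 of block groups,
populations uniform within class), a 10x10 pollutant grid whose daily
values are a seasonal sinusoid plus Gaussian noise with per-cell annual
means drawn from clipped normals (PM2.5 ~ N(7.1, 0.55) clipped to
[3.5, 10.6]; ozone ~ N(40.55, 1.1) clipped to [28.2, 46.0]) so every cell
mean lands inside the published bin ranges, and 60 random roadway
segments with patients placed as a mixture (45% within 250 m of a road,
10% within 250–1500 m, the rest uniform) to approximate the published
proximity distribution.

Outcomes are drawn from a logistic model on the patient's *binned*
features — the same bins the pipeline reconstructs — so planted effects are
exactly recoverable by the chi-square battery. Per-bin log-odds offsets are
mean-centered and the intercept is then calibrated by 1-D root finding so
the expected prevalence equals the configured value exactly (centering
alone leaves a Jensen bias on the probability scale). The default effect
specification is derived at run time from the published per-bin outcome
rates (offset = logit(per-bin rate) − logit(overall prevalence)); the
prednisone outcome shares the non-age effects with the ED outcome, whose
published results were consistent across outcomes apart from the age
pattern. Zero-effect and single-planted-effect configurations are one
constructor call (`SimulationConfig.null`, `SimulationConfig.planted`), and
`extra_null_features` adds outcome-independent categorical columns for
false-positive auditing.

Missingness is missing-completely-at-random at its natural source: patient
geocodes (default 10.42%, matching the published pollutant-bin missing
fraction, and propagating to every geography-derived field) and
block-group-level census suppression (defaults tuned to the published extra
missing fractions for density, insurance, and income). Roadway-distance
missingness therefore equals geocode missingness; the much larger published
missing fraction for roadway proximity (29.66%) stemmed from the original
transportation-data linkage and cannot arise in a purely geocode-driven
integration — a known, deliberate divergence.

What the generator does **not** emulate: real diagnosis/medication
vocabularies, geodetic coordinates, informative (non-random) missingness,
spatial autocorrelation between census attributes and pollution, or
within-patient temporal correlation of visits. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and statistics on
data with the published structure, not epidemiological validity on real
EHR data.

## Numerical and design notes

* Determinism: one integer seed drives a single `numpy` PCG64 generator;
  identical configurations produce byte-identical written bundles (fixed
  float formats, fixed column order, stable sorts).
* The chi-square statistic is computed with `scipy.stats.chi2_contingency`
  (correction disabled); the test suite checks it against an independent
  direct-formula oracle to 1e-9 on a thousand random tables.
* Quantile edges use linear interpolation between order statistics
  (`numpy.quantile`'s default).
* Percentages in summaries are rounded half-up to two decimals, matching
  the published presentation (5638/157,410 prints as 3.58).
* Degenerate inputs fail loudly: empty outcome dichotomies, all-constant
  features (skipped per-feature inside the battery, fatal as direct calls),
  all-identical values under fitted binning.
* Problem sizes in the shipped checks: unit tests simulate 1,500–30,000
  patients; the end-to-end planted-recovery check uses 150,000 patients
  with a 0.3 log-odds offset on sex and 20 extra null features, which the
  battery must flag uniquely at the Bonferroni threshold. Bonferroni
  controls the family-wise error rate at ~5%, so across seeds roughly 1 run
  in 20 legitimately flags one null feature alongside the planted one.

## Known limitations

* The service holds feature tables in memory and is single-process; it is a
  faithful interaction model, not a deployment artifact (no auth, no rate
  limiting).
* Only bivariate chi-square exploration is supported — no multivariate
  models, no Fisher exact test for sparse tables.
* One published statistic (the age x ED/inpatient-visit chi-square) is not
  reproducible from its own published per-bin counts; the package reports
  the faithfully recomputed value.
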