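# Methods

## Units of analysis

The census tract is the smallest input unit; it carries population,
total monthly income, household-head counts (total, earning 0–3 minimum
wages, below ½ minimum wage), persons aged 7+ and illiterate among
them, and persons with inadequate sanitation. Neighborhoods aggregate
tracts: population and income are summed; the 0–3 minimum-wage head
proportion is **pooled** (sum of numerators over sum of denominators);
the three deprivation indicators are computed per tract and then
**averaged unweighted** over the neighborhood's tracts, mirroring how
tract-level index values are usually carried up to coarser units.
Schools are the row unit of all cross-tabulations and inherit every
neighborhood attribute.

## Inequality indices

**Income terciles.** Per-capita income is total neighborhood income
over population. Boundaries are the empirical 33⅓/66⅔ percentiles of
the neighborhood distribution with linear interpolation between order
statistics ((n−1)-position rule); a value equal to a boundary falls in
the lower tercile. A degenerate (constant) distribution is an error.

**Segregation (Gi\*).** The self-inclusive Getis–Ord local statistic
(not the self-excluding Gi variant) with binary weights, w_ii = 1, no
row standardization, over first-order rook contiguity: areal units are
neighbors when they share a boundary segment of positive length
(corner contact excluded). The global mean and **population** standard
deviation (divide by n) enter the standardization, matching the
derivation under which each Gi\* is asymptotically standard normal —
which is what the fixed ±1.96/0 category cutpoints presume. Categories:
High (Z ≥ 1.96), Medium (0 ≤ Z < 1.96), Low (Z < 0).

The default computes Gi\* at the neighborhood level on neighborhood
adjacency. A tract-level mode (`segregation_level: tract`) computes
tract Z-scores on tract adjacency and assigns each neighborhood the
majority tract category, with ties broken by the category of the
neighborhood's mean tract Z; it exists because area-level workflows
differ on which resolution the cutpoints are applied at, and the two
modes let users compare.

**Deprivation.** No single canonical combination formula exists for
the three-indicator composite; this package z-standardizes each
indicator across neighborhoods (population SD) and averages them,
the approach of the Brazilian area-deprivation index family. The
combination rule is an explicit `method` argument so alternatives can
be added without changing category logic. Categories at the score mean
± ½ SD: above → High, below → Low, else Medium. With a standard-normal
score this yields expected shares 30.9% / 38.3% / 30.9%. An indicator
that is constant across neighborhoods is an error (zero variance).

## Food environment

Establishments map from activity code to one of 13 subcategories by
longest-prefix match (unmatched codes are logged and counted
`non_food`), grouped as in natura (butchery, seafood, fruits &
vegetables), ultraprocessed (street vendor, bar, cafeteria/snack bar,
convenience, candy) and mixed (hyper/supermarket, general food store,
mini market, bakery, restaurant). The prefix table ships as an
editable YAML file because registries differ in their coding; the
taxonomy, not the codes, is the fixed content.

* **Desert**: healthy density (10,000 × (in natura + mixed) /
  population) **strictly below** the city-wide 25th percentile (linear
  interpolation, computed over all neighborhoods present in the input,
  not only school-containing ones). With all densities equal there are
  no deserts.
* **Swamp**: swamp-subcategory sum **strictly greater than four**. The
  swamp set defaults to convenience stores, cafeterias (snack bars),
  mini markets and candy shops; "grocery stores" in the source
  methodology is read as mini markets, and the set is overridable in
  the YAML because that identification is not certain.
* **mRFEI**: 100 × healthy / (healthy + ultraprocessed); undefined
  (NaN, never zero) when the denominator is empty.

## Tabulation and tests

Prevalences are reported to 1 decimal. Chi-square tests are Pearson,
school-level, without Yates continuity correction — the uncorrected
statistic reproduces the published both-flags-by-sector p of 0.098,
the corrected one does not — with p-values to 3 decimals and values
below 0.0005 rendered "< 0.001". The published swamp-by-stratum
p-values (0.016, 0.231, 0.079) are **not** reproducible as school-level
Pearson tests on the published counts (those give p < 0.001, plausibly
because the original tests were run at neighborhood level); this
package reports school-level tests and leaves that discrepancy
documented rather than imitated.

Median/IQR (p25–p75) establishment-count summaries use the
(n+1)-position linear interpolation quantile (the descriptives default
of classic statistics packages, e.g. {0,0,1,2,3} → IQR (0, 2.5)),
deliberately different from the (n−1) rule used for tercile and
density percentiles; both conventions are pinned by tests.

The study-sample filter removes, in order and each school once:
professional-education-only schools, special-education-only schools,
and schools missing any inherited index category, and returns an audit
count per reason (on the published accounting: 3,238 → 38 + 7 + 34
excluded → 3,159 retained).

## Synthetic city generator

The generator emulates the statistical structure of a large Brazilian
city at neighborhood resolution; it is the test bed for every
downstream stage.

* **Geometry**: neighborhoods on a rectangular lattice (default
  10×10), tracts as strips within each cell (default 5), rook
  adjacency exact by construction. Real polygon input (GeoJSON)
  remains supported through the I/O layer.
* **Income**: household-head incomes are lognormal (scale σ = 0.8)
  with the neighborhood's 0–3 minimum-wage share p fixed analytically:
  μ = ln(3·MW) − σ·Φ⁻¹(p), MW = 510 (the 2010 statutory monthly
  minimum wage in BRL). Background p = 0.5; planted low-income
  cluster cells use p = 0.85 (test scenarios use 0.3 vs 0.9). Incomes
  are treated as unitless by the pipeline; no currency conversion is
  performed.
* **Population**: Poisson around 1,000 persons per tract; household
  heads binomial with rate ⅓.
* **Deprivation indicators**: illiteracy and sanitation rates rise
  linearly with p plus tract-level noise, so income clusters are also
  deprivation clusters.
* **Establishments**: independent Poisson counts per subcategory per
  neighborhood — the simplest count model consistent with the skewed,
  zero-inflated distributions such registries show. Default rates are
  round numbers on the scale of a large city's neighborhood counts
  (e.g. 20 cafeterias, 12 mini markets, 5 butcheries, 0.5 convenience
  stores); an optional per-stratum rate table gives the low-income
  cluster sparser retail. Desert/swamp planting rewrites per-cell
  rates (healthy rates × 0; ultraprocessed swamp rates rescaled to a
  target sum, leaving mixed-class swamp categories untouched so a cell
  can be planted as both desert and swamp).
* **Schools**: a fixed number per neighborhood (default 3), public
  with probability 0.55.
* **Randomness**: one scenario seed expands into independent
  substreams (population/indicators, incomes, establishments,
  schools), so changing establishment rates never perturbs the school
  roster. Identical config + seed ⇒ bit-identical city.

What the generator does **not** emulate: real street geometry or
travel-time access, point coordinates, spatial autocorrelation of
establishment counts beyond the planted strata, correlation between
school sector and neighborhood income, or registry miscoding. Passing
tests therefore demonstrate that the pipeline's arithmetic and
inference behave as specified under controlled conditions — not that
the sociological associations would be recovered from any real city's
data.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small
configurations — 5×5 lattices with 2 tracts of ~300 people per
neighborhood for Monte-Carlo loops (50 seeds), the 10×10 default city
for end-to-end runs, 10⁵ replicates for the multinomial permutation
null — chosen so the full suite completes in seconds while keeping
every planted-effect margin wide (cluster contrast 0.9 vs 0.3 gives
center-cell Z far above 1.96).

Degenerate inputs error loudly rather than silently: constant x for
Gi\*, constant indicators for deprivation, constant incomes for
terciles, zero expected cells for chi-square, zero population
anywhere. Saturated flags (e.g. a city where every neighborhood is a
swamp) are reported with an empty p-value rather than a test. CSV
round trips use round-trip float parsing so write → read is
bit-identical, which the end-to-end determinism tests rely on.

## Known limitations

* The Rio-level quantities that depend on the full registry (the 27.35
  density threshold, tercile dollar boundaries, citywide composition)
  cannot be recomputed without the non-deposited registry; the package
  verifies the tabulation arithmetic on the published counts instead.
* Only binary rook contiguity is implemented (no queen, distance-band
  or kernel weights; no higher-order contiguity), and no inference for
  Gi\* beyond the fixed cutpoints.
* No regression modelling or multiple-testing adjustment — the
  analysis is deliberately descriptive, as in the source methodology.
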