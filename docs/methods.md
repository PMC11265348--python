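# Methods

## Data model

The atomic unit is a **county-year record**: county id, province, prefecture
(the city or autonomous prefecture containing the county), year, poverty
status, permanent population `P_i` (persons), land area `A_i` (km²), and two
resource stocks `HR_i` — medical personnel and beds in medical institutions.
Two different parent regions are deliberate: Gini and Theil statistics are
computed within a **province**, while agglomeration degrees are defined
relative to the county's **prefecture**.  Panels enforce unique
(county, year) keys and constant static attributes (province, prefecture,
poverty status) across years.  Resource counts may be fractional — every
statistic is ratio-based — and a missing count is an explicit `None`, never
zero.

The comparability indicator is the density per 1000 capita,
`1000 · HR_i / P_i`.  Trend summaries use the **median** over counties of a
(province, poverty group, year) cell; the median of an even-sized set is the
mean of the two central values.

**Missing-data policy: propagate, never impute or drop.**  Any statistic
whose input set contains a missing cell is reported as *not computable* with
a reason naming the offending counties.  Silently dropping counties would
change population shares and bias the decomposition; imputation would invent
data.  Failures are isolated per cell, so one blanked province-year-resource
block (the pattern an unpublished yearbook volume leaves) affects exactly
its own rows in every output table.

## Gini coefficient

Counties are weighted units: the weight is the denominator of the equality
concept — population for demographic equality ("by population"), land area
for geographic equality ("by area", i.e. inequality of resource per km²) —
and the amount is the resource stock.  Units are sorted by ascending density
(ties broken by county id, so the result is permutation-invariant) and the
Gini coefficient is 1 − 2 × the trapezoidal area under the weighted Lorenz
curve.  This is the standard estimator in the health-resource equality
literature; it equals the weighted pairwise mean-difference form
`Σᵢⱼ wᵢwⱼ|xᵢ − xⱼ| / (2x̄)` exactly, which the tests verify to 1e−10 against
an independent implementation.  No small-sample correction (no `n/(n−1)`
factor) is applied.  An unweighted variant (equal-weight counties over their
densities) is available as a flag, since survey write-ups often do not state
which estimator was used; the weighted form is the default.

Band classification: `< 0.2` absolute even, `[0.2, 0.3)` relatively average,
`[0.3, 0.4)` intermediate, `[0.4, 0.5)` large gap, `≥ 0.5` huge gap, with
0.4 the conventional warning line.  The customary band definitions use
strict inequalities that leave boundary points and the (0.3, 0.4) range
unlabeled; half-open intervals closed on the left make classification total,
and exact boundary hits are measure-zero in floating point.

## Theil-L decomposition

The Theil-L (mean log deviation) index of a county set weights counties by
population share.  Natural logarithms are the default; a configurable base
only rescales all indices and leaves contribution rates unchanged.  The
decomposition over a grouping variable (poverty status by default, but any
record-to-label function) is computed per (province, year, resource) and
satisfies `I = I_L + Σₖ Gₖ·Iₖ` exactly; the implementation computes the terms
independently and the tests confirm additivity and agreement with the
directly pooled one-level index to 1e−10.

Contribution rates divide by the overall index, so when `I = 0` (perfectly
equal data) they are reported as *undefined* rather than zero.  A county
with zero resource makes the logarithm undefined; the whole cell becomes not
computable rather than dropping the county.  On strictly positive inputs
every within/between term is non-negative, so negative printed values in
published tables of this kind can only arise from input anomalies — the
package surfaces such inputs as data-quality diagnostics instead of
producing negative indices.

## Agglomeration degrees

`HRAD_i = (HR_i/A_i)/(HR_n/A_n)` and `PAD_i = (P_i/A_i)/(P_n/A_n)` compare a
county's resource (population) density per km² with its prefecture's.  Both
are dimensionless — converting the area unit leaves them unchanged — and
when counties exactly partition the prefecture the area-weighted means of
both equal one.  `HRAD/PAD` equals the county-vs-prefecture per-capita
density ratio, so `sign(HRAD − PAD)` matches the sign of the per-capita
density difference.

Parent totals `HR_n, P_n, A_n` are by default the sums over the panel's
counties of the prefecture; a mapping of official prefecture totals can be
supplied instead, because a sampled panel may not cover the whole
prefecture and published analyses typically use full yearbook totals.

Verdicts use a tolerance band (default 1e−9) around the thresholds:
HRAD vs 1 → rich / balanced / short; HRAD − PAD vs 0 → surplus /
meets-needs / deficit.  Exact equality branches are measure-zero, so a
numeric convention is required; 1e−9 is far above accumulated rounding error
and far below any practically meaningful difference.

## Synthetic panel generator

The generator emulates the structure of a stratified multi-province county
survey: 5 provinces with paired poverty groups of matched sizes
(12, 11, 4, 2, 5 counties per group — 68 counties in total), years
2015–2019, and one blanked (province 5, 2019, personnel) block by default.

Each county draws a static population ~ Uniform(30 000, 400 000) and area
~ Uniform(500, 15 000) km², and one base density per resource from a
lognormal: log-median log(6.0) for personnel and log(5.0) for beds per 1000
capita (plausible county-level magnitudes of the study period), shape
σ = 0.35 for impoverished and 0.45 for non-impoverished counties (within-
group inequality is reported higher among non-impoverished counties), a
multiplicative poverty deficit 0.8 on the impoverished-group median, and a
deterministic annual growth trend (1.05 personnel, 1.03 beds — personnel
growing faster).  Counties are assigned round-robin to prefectures of ~4
counties, the smallest parent giving non-trivial HRAD partitions.  All draws
come from one `numpy` generator, so a seed fully determines the panel.

The lognormal model is chosen because resource densities are positive and
right-skewed, and because it yields closed forms for the large-n unweighted
limits — `Gini = 2Φ(σ/√2) − 1` and `Theil-L = σ²/2` — used as independent
truths in recovery tests.  A multiplicative group deficit rescales every
density in a group, so it shifts only between-group inequality and leaves
the within-group indices distribution-identical, which the tests exploit.
Collapsing `population_range` to a point makes the weighted and unweighted
estimators coincide, isolating weighting decisions.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring counties, correlation of density with population size or
poverty geography, yearly idiosyncratic shocks (growth is deterministic),
integer-valued counts, and migration.  Passing tests therefore demonstrate
correctness of the estimators and pipeline plumbing under a known model, not
fidelity of any particular inequality level to real yearbook data.

## Numerical choices and problem sizes

- Lorenz ties are broken by county id, making all tables permutation-
  invariant and byte-identically reproducible from the provenance (config
  echo + SHA-256 input digest) recorded in each report bundle.
- Oracle agreement (Gini pairwise form, pooled Theil) is asserted at 1e−10;
  algebraic invariances (scale, replication, permutation, area-unit,
  partition closure, share closure) at 1e−12.
- Recovery checks use 5 000 counties per group and 10 seeds, giving a
  seed-averaged standard error near 1% of the truth against a 3% band.
  Randomised oracle-equivalence checks use 1 000 instances of 2–12 counties.
  The whole suite runs in a few seconds on one CPU.
- Gini values within 1e−15 of zero are clamped to exactly zero so degenerate
  scenarios classify as absolutely even.

## Limitations

- Single-level grouping only: no nested province → prefecture → county
  Theil decomposition, and no Theil-T variant.
- Point estimates only; no bootstrap confidence intervals.
- No map rendering or distance-based accessibility modelling; HRAD − PAD is
  a proportional-share criterion, not a travel-time one.
- The personnel count is taken as a single pre-aggregated cadre total;
  splitting by profession is out of scope.
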