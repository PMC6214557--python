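# Methods

## Model

The package estimates the number of patients served by a medical donation
program from four quantities per reporting unit (facility, country or
region): donated course treatments C, destruction rate d ∈ [0, 1], pooled
CTX-per-visit prescribing indicator c̄ > 0, and revisit rate r ≥ 1. The
point estimator is

    P = C (1 − d) / (c̄ r),

a ratio-of-means (pooled-ratio) estimator: c̄ is total CTX prescribed
divided by total visits in the sample — the WHO/INRUD "average medicines per
encounter" convention, *not* a mean of per-patient ratios — and r is total
visits divided by unique patients over the observation window. Both
conventions reproduce the pilot clinic's arithmetic exactly (c̄ = 288/843,
r = 843/100 = 8.43).

Beneficiaries are counted per treated condition. Chronic and acute donations
are converted separately with stratum-specific (c̄, r); their sum is the
total-beneficiary estimate, and unique patients divide the total by the mean
number of conditions treated per patient, estimated in-sample as
(unique chronic + unique acute) / unique patients (a comorbid patient
appears in both stratum counts but once in the denominator). At country
level, unique patients are additionally computed directly from total CTX
with the overall (non-stratified) parameters, which is what the per-country
validation against the published intervals exercises.

Estimates are carried as reals end to end; rounding to whole patients
(round-half-up) happens only in reporting layers, so downstream sums are
reproducible.

### Known divergences in the published worked example

The published pilot figures (4,633 and 3,512 patients) sit ≈0.2% and ≈0.1%
away from the values this estimator produces from the same printed inputs
(4,624.7 and 3,514.7); the original analysis evidently rounded
intermediates. Tests and the validation targets therefore accept ±0.5% on
these two numbers and nothing else. Similarly, the published per-country
tables contain a handful of internally inconsistent cells (a CI bound
printed below its mean; stratum counts exceeding a total; a Total-row
chronic/acute split disagreeing with its own column sum). The packaged
fixtures store every cell verbatim and enumerate these cells in
`fixtures.KNOWN_INCONSISTENCIES`; consistency checks exempt exactly that
list.

## Aggregation and pooling

Facility statistics come from sampled visit records: pooled per-visit means
with standard errors SD/√n over visits, stratified by disease type.
Country parameters are unweighted averages across the country's sample
facilities — the natural reading of "average across sample facilities" —
with a visit-weighted option, since the study's printed cross-country means
(2.68 medications, 2.63 CTX) are not reproducible from its per-country
table under any single obvious weighting and are therefore never used as
oracles here. SEs of pooled means propagate as √(Σ wᵢ² seᵢ²).

Zero reported destruction rates are treated as under-reporting: they are
replaced by the mean reported rate of configured proxy countries from the
same region (Ghana ← Tanzania; Peru ← mean of Nicaragua and El Salvador;
West Bank ← Tanzania, the region's only available proxy). Imputation never
touches a nonzero report and cannot leave [0, 1].

Region projections pool member-country parameters with weights proportional
to each country's CTX donations — the only weight observable for every
member — and apply the estimator to the region's CTX total. Countries
outside the sample implicitly inherit the pooled parameters; the result
carries an `extrapolated_beyond_sample` flag when that happens. Facility
counts are metadata only and never enter the estimator.

## Uncertainty analysis

**One-way (tornado):** each parameter is swept alone over a (low, high)
range with the others at base; rows are sorted by swing |f(high) − f(low)|.
On the pilot configuration the destruction rate (swept over its full 0–40%
plausible range) and the revisit rate dominate, matching the pilot study's
qualitative finding. Because c̄ and r enter identically as 1/x, symmetric
relative ranges give them identical swings — a useful algebraic check.

**Probabilistic (PSA):** all parameters are drawn simultaneously each
iteration — beta for probabilities, normal (truncated to the parameter's
domain by resampling) for everything else — and the model is re-evaluated;
the 95% credible interval is the empirical 2.5th/97.5th percentile range of
the outputs. Spread resolution, in order of precedence: an explicit SE; a
(min, max) range with SD = (max − min)/(2·1.96); a relative half-width
(default ±20%) mapped the same way. Beta parameters come from method of
moments on (mean, SD); a central value at 0 or 1, or zero spread, collapses
to the degenerate fixed value. Percentiles use the nearest-rank definition
(element ⌈qn⌉ of the sorted draws): deterministic and trivially checkable
against a brute-force sort. Defaults: 10,000 iterations, single integer
seed, one `numpy` Generator stream, parameters drawn in listed order — the
same seed yields bit-identical results.

The pilot PSA fixes C (an inventory fact), gives d a beta centred at 0.24
with the stated 0–0.40 range, and gives c̄ and r truncated normals at the
default ±20% (their within-sample SEs are not retained at this level of
aggregation). The published pilot bounds (2,810–4,215) are treated as a
containment property — the interval must cover the EMR truth of 3,071 —
rather than exact targets, because the original analysis does not state
which parameters were varied or its beta parameterization. The interval this
package produces ([≈2,305, ≈5,167] at seed 1) is somewhat wider, consistent
with spreads on all three varied parameters.

## Synthetic-data generator

The generator emulates the pipeline's inputs with known truth: patients are
assigned chronic, acute or both conditions (comorbidity probability m,
chronic fraction f among the rest); each condition produces 1 + NB visits (a
*shifted* negative binomial — the ≥1-visit floor is respected while the
configured mean is preserved exactly, unlike truncation); each visit draws
medication and CTX counts from NB-style distributions with variance
μ + φμ² (dispersion φ = 0 collapses to a degenerate constant, making
zero-noise recovery tests exact). The donation inventory is sized from the
*configured expected* totals, donated = E[prescribed]/(1 − d), rather than
from the realized records: with realized sizing the pipeline recovers the
patient count as an algebraic identity, whereas expectation-based sizing
makes end-to-end recovery a genuine statistical check of the ratio
estimator. Default study conditions mirror the sampled facilities: ~2.5 CTX
and ~2.7 medications per visit, ~3 visits per condition, 35% chronic, 10%
comorbidity, 10% destruction.

What the generator does **not** emulate: seasonality, disease-specific
epidemiology, informative sampling of patients within facilities,
self-report bias in destruction rates, and the mixing of donated with
self-procured stock at real facilities. Passing recovery tests therefore
demonstrate internal consistency of the estimator under the generative
assumptions, not robustness to those real-data features.

## Problem sizes and tolerances

The default verification runs use one facility of 1,000 patients with 50
pipeline replicates for recovery (|relative bias| < 2%; the total-CTX
coefficient of variation at that size is ≈2.4%, so the bound is comfortably
above the Jensen-term bias of order CV² while still catching implementation
errors), 10,000 Monte Carlo draws for credible intervals, and a 200,000-draw
brute-force oracle when checking the percentile machinery. Floating-point
identities (conversion-factor inverse, estimator consistency) are asserted
at 1e−12.

## Limitations

Beyond the generator's idealizations: destruction rates are facility
self-reports; the revisit rate is window-dependent (a year here) and not
transportable across windows; country and region projections inherit the
representativeness of a handful of high-volume sample facilities; and the
published region-level headline figures depend on region CTX totals,
facility censuses and population data that are not part of the packaged
tables, so the region machinery is exercised on synthetic and
fixture-derived inputs only.
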