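# ctximpact

Estimate how many patients a medical donation program actually serves.

International donation programs ship medicines in bulk — pills, vials,
boxes — but report their reach in *course treatments* (CTX): the standard
amount of a medicine needed to treat one patient for one condition for a
defined period (e.g. 20 × 500 mg clarithromycin tablets = 1 CTX). A CTX
count still is not a patient count: some donated medicine is destroyed or
expires, a single visit typically yields several course treatments, and a
single patient makes several visits. `ctximpact` implements the conversion
algorithm, validated against an EMR-instrumented pilot clinic, that bridges
that gap, plus the machinery around it: facility-level prescribing
statistics, country/region extrapolation, one-way (tornado) and Monte Carlo
probabilistic sensitivity analysis, and a synthetic-data generator with
known ground truth for end-to-end testing.

It is written for monitoring-and-evaluation analysts at donation programs
and for health-services researchers who want a reproducible, testable
implementation of the method.

## The estimator

With C donated course treatments, destruction rate d (proportion destroyed,
expired or unused), pooled prescribing indicator c̄ (mean CTX per
prescription visit, the WHO/INRUD convention) and revisit rate r (mean
visits per unique patient over the window):

    usable CTX                U = C · (1 − d)
    prescription visits       V = U / c̄
    unique patients           P = V / r = U / (c̄ · r)

1/(c̄·r) is the **conversion factor**: patients served per usable CTX.
Patients treated for several conditions benefit once per condition, so
**total beneficiaries** are estimated per chronic/acute stratum with
stratum-specific (c̄, r) and summed; unique patients divide that total by
the mean number of conditions treated per patient. Parameter uncertainty is
propagated by Monte Carlo (beta distributions for probabilities, truncated
normals elsewhere; 10,000 draws by default), reporting the 2.5th–97.5th
percentile range as a 95% credible interval.

## Worked example

The pilot clinic received 13,319 CTX; a 100-patient sample shows 288 CTX
prescribed over 843 visits (c̄ = 288/843 ≈ 0.342, r = 8.43), and the
clinic's EMR independently counted 3,071 unique patients.

```python
>>> from ctximpact.pilot import pilot_point_estimate, run_pilot_psa
>>> pilot_point_estimate(destruction_rate=0.0)
4624.652777777777
>>> pilot_point_estimate()          # 24% destruction, the U.S.-site average
3514.7361111111113
>>> psa = run_pilot_psa(n_iter=10_000, seed=1)
>>> (round(psa.lower), round(psa.upper), psa.contains(3071))
(2305, 5167, True)
```

Assuming no wastage, the algorithm over-counts (≈4,625 vs 3,071 in the
EMR); revising the destruction rate to the 24% U.S.-site average brings the
point estimate to ≈3,515, and the Monte Carlo credible interval around that
base case covers the EMR truth — the validation logic of the method.

Longer narrative walk-throughs live in `examples/`:

* `pilot_validation.py` — the pilot estimate, tornado analysis, PSA;
* `country_projection.py` — all ten study countries projected from the
  packaged published tables, checked against the printed credible intervals;
* `synthetic_recovery.py` — parameter recovery on generated data with known
  ground truth.

A thin CLI mirrors the library stage by stage
(`ctximpact estimate|simulate|summarize|pool|project|psa|tornado|fixtures|run`);
`ctximpact run` executes the whole pipeline from CSV inputs and writes a
seed-stamped manifest.

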