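# Methods

## The modelling problem

The observation unit is a pair (destination territory, year): a nonnegative
integer count of detected distribution lines from one origin (Greater
London, formed by summing the Metropolitan Police and City of London
territories' raw population and covariates before any rate is computed).
Flows are single-origin: each model predicts the allocation of the observed
yearly outflow `T_i` across the 37 destination territories, never the total
itself. All three families therefore share the outflow constraint
`Σ_j T_ij = T_i`, implemented as an explicit normalisation, which also makes
every model invariant to a common rescaling of its weights (gravity under
distance-unit changes, retail under a common benefit factor).

## Model conventions

* **Gravity.** `T_ij ∝ m_j^b d_ij^c` with `c` an unconstrained real. The
  exponent multiplies distance in the numerator; a negative `c` gives the
  usual distance decay, a positive one the opposite. Both signs are left
  admissible because the data, not a prior, should decide.
* **Retail.** Utilities `Σ_n α_n log w_j^(n) − β c_ij` are computed in log
  space with a max-shift before exponentiation (identity-preserving,
  avoids overflow). Covariates entering a logarithm must be strictly
  positive; the error message names the covariate and the territory. The
  denominator runs over all destinations `k ≠ i`; there is no self-flow.
* **Radiation.** Opportunities are proportional to population,
  `n = ρ·population`. The intervening opportunities `n_ij` sum territories
  *strictly* closer to the origin than the destination (ties excluded,
  endpoints excluded) — the standard radiation circle. The denominator uses
  each destination's own intervening count `n_ik`: a destination-specific
  `n_ij` inside a sum over `k` would be ill-formed. The absorption
  probability is evaluated in log space (`log1p`/`logaddexp`) because at
  territory scale `(n_i+n_j+n_ij)^r` overflows double precision long before
  the probability itself degenerates; the log-space form agrees with the
  naive formula to ~1e−12 relative error at moderate scale (tested).

## Covariate normalisation

Raw covariates are yearly territory totals. The default normalisation is
per 100 000 inhabitants for all five benefits. A second mode divides the
two hospital-admissions covariates by daytime beds per capita instead
(admissions/(beds/population)); it is a configuration switch
(`admissions_mode`) rather than the default, because the headline variable
description in the source data is population-normalised. Zero raw values
are storable but rejected at model-build time whenever that covariate
enters a retail logarithm.

## Calibration

Losses, for `N` destinations:

* Gaussian: `(1/2N) Σ_j (T_j^data − T_j^model)² + λ‖θ‖²`
* Poissonian: `(1/N) Σ_j (T_j^model − T_j^data log T_j^model) + λ‖θ‖²`

λ = 1 throughout, applied to the whole free-parameter vector including β.
Zero observed counts are fine in both losses (the Poisson term degenerates
to the model mean).

Optimisation is a deterministic multi-start: a fixed coarse grid of
starting points per family (gravity: b ∈ {0, ½, 1} × c ∈ {−1, 0, 1};
retail: all-zero α with β ∈ {0, 0.01, 0.05} plus one all-negative-α start;
radiation: six (ρ, r) pairs spanning [0.5, 4] × [0.5, 2]), each refined
with bounded L-BFGS-B (ftol 1e−12) on the smooth penalised loss, keeping
the best final value and never accepting a refinement that ends above its
own start. Radiation is optimised in (log ρ, log r) to enforce positivity
while the ridge penalty is evaluated on the natural parameters. Parameter
boxes: |b|, |c| ≤ 5; |α| ≤ 2; |β| ≤ 1; ρ, r ∈ [1e−3, 1e3]. If no start
reports convergence the result is flagged (`converged=False`) and the CLI
exits with code 3; it is never silently dropped.

Identifiability caveat: when every opportunity count satisfies `n^r ≫ 1`
the radiation probability is nearly homogeneous of degree zero in ρ, so ρ
is weakly identified and the ridge term dominates, pulling ρ toward small
values on flat likelihood directions. This is a property of the model at
large populations, not an optimiser defect; the same mechanism pins the
gravity exponents at zero when destinations are exactly exchangeable.

## Model selection

The retail lattice enumerates all 2⁵ = 32 covariate subsets (β always
free); with one gravity and one radiation model the grid is 34 specs per
(loss, training year). Twofold cross-validation trains on one year and
validates on the other — the two folds are the two years, chosen over
k-fold splitting because the radiation model couples destinations through
the intervening-opportunity circles and cannot be sliced freely.

Reported per fit: validation Sørensen–Dice `S`, validation log-MSE
`(1/N) Σ (log(d+1) − log(m+1))²` (offset 1 admits zero counts; offset 0
with zero-pair exclusion is available), and `BIC = 2 log M − 2 log L̂` with
`M` the whole modelled sample (both years, default 74 observations) and
`log L̂` the unpenalised log-likelihood at the optimum — Poisson including
the log-factorial term, Gaussian with unit observation variance (the loss
is the unit-variance negative log-likelihood up to constants; no σ is
estimated). The printed two-parameter-free BIC form is deliberate; a
conventional `k log M` variant exists behind the `k` argument but is never
the default. Rankings sort ascending in log-MSE/BIC, descending in S, ties
broken toward fewer covariates then lexicographic spec id. The
minimal-variable filter keeps, of the 32 retail rows, only the subsets of
the best-ranked variant's covariate set (with two active covariates:
both, each alone, none — four rows), passing non-retail rows through.

## Synthetic studies

The generator emulates the statistical shape of the England dataset, not
its map. Defaults (chosen once as field-plausible magnitudes):

| quantity | law / value | rationale |
|---|---|---|
| destinations | 37 (+1 origin) | territory count of the real system |
| origin population | 8.9e6 | Greater London scale |
| destination population | log-normal, median 1.1e6, σ_log 0.45 | English territory range ~0.5–3M |
| misuse admissions | log-normal rate, median 80/100k, σ_log 0.5 | NHS admissions scale |
| poisoning admissions | median 40/100k, σ_log 0.5 | ~half misuse |
| police officers | median 220/100k, σ_log 0.25 | England FTE rates |
| gdhi | median 20 000 per head, σ_log 0.15 | regional income spread |
| knife crime | median 70/100k, σ_log 0.6 | widest regional variation |
| hospital beds | median 250/100k, σ_log 0.3 | daytime beds |
| geography | uniform in a 450 km box, Euclidean distances | England's span |
| travel time | distance / (1 km/min) × log-normal noise σ 0.15, symmetrised | ~60 km/h road average |
| truth | retail, α_misuse = −7.74e−3, α_knife = −0.013, β = 0.014/min | realistic magnitudes for recovery tests |
| outflow | 1e5 expected lines/year | recovery-test operating point |

Counts are independent Poisson draws per destination and year around the
truth-model expectations (two years = two i.i.d. draws; no between-year
drift, no take-down dynamics, no spatially autocorrelated 'north–south'
border). The 16 destinations nearest the origin are tagged `south` so
concentration-share analyses have a region subset. Because the generator's
only stochastic count mechanism is Poisson, passing recovery tests shows
the estimator chain is correct under the model's own assumptions — it says
nothing about overdispersion, detection bias or year-to-year dependence in
real police data.

At the default operating point the travel-cost β is recovered essentially
exactly (its Fisher information is large: travel times spread over
hundreds of minutes at 1e5 counts), while the benefit exponents are small
(|α| ~ 0.01) against a log-covariate spread of order 0.5, so single-study
estimates carry visible sampling noise; recovery is therefore assessed on
medians across seeds, and shrinking error with growing outflow is the
consistency check.

## Problem sizes

Default test and reporting runs use 37-destination studies; the comparison
drivers fit 34 specs per training year with the Poisson loss, and the
recovery analyses use 10–20 independent seeds. Smaller instances (6–10
destinations) back the optimiser-oracle and orchestration tests.

## Known limitations

* The Gaussian likelihood fixes σ = 1, so Gaussian BIC values are
  comparable among themselves but not against a variance-estimating fit.
* ρ in the radiation model is weakly identified at realistic population
  scales (see above); its fitted value leans on the ridge penalty.
* `difference_map` exports attribute-annotated GeoJSON only; cartographic
  styling is out of scope.
* Boundary files in the examples are synthetic square cells, labelled as
  such; they carry no real administrative geometry.
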