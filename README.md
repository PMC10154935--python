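# countylines

Spatial-interaction modelling of "county lines" drug distribution: how many
detected supply lines run from a hub city (Greater London) into each of the
surrounding police force territories, and which model of spatial flow best
explains their geography.

The package is aimed at quantitative criminologists and spatial
epidemiologists who have origin–destination count data at a coarse areal
resolution (one origin, ~40 destinations) and want to compare mechanistic
flow models under proper likelihood-based calibration rather than ad-hoc
curve fitting.

## Models

All models allocate a fixed origin outflow `T_i` (the observed yearly total
of detected lines) across destinations `j`, so `Σ_j T_ij = T_i` holds by
construction.

**Gravity** — flow scales with destination population and a power of
distance:

    T_ij = T_i · m_j^b d_ij^c / Σ_k m_k^b d_ik^c

**Radiation** — a particle leaving `i` is absorbed by the opportunities it
meets on the way; with opportunities `n = ρ·population` and `n_ij` the
opportunities of territories closer to the origin than `j`:

    P(1|n_i, n_j, n_ij) = [(n_i+n_j+n_ij)^r − (n_i+n_ij)^r](n_i^r + 1)
                          / {[(n_i+n_ij)^r + 1][(n_i+n_j+n_ij)^r + 1]}
    T_ij = T_i · P(1|n_i, n_j, n_ij) / Σ_k P(1|n_i, n_k, n_ik)

**Retail** — an entropy-maximising (softmax) balance of benefits against
travel cost, with per-100k social covariates `w_j^(n)` (hospital admissions
by drug misuse/poisoning, police officers, disposable household income,
knife crime) and travel time `c_ij` in minutes:

    T_ij = T_i · exp{Σ_n α_n log w_j^(n) − β c_ij}
               / Σ_k exp{Σ_n α_n log w_k^(n) − β c_ik}

Each covariate subset of the five benefits is a separate retail variant
(2⁵ = 32, β always free). Calibration minimises a Gaussian (mean-square) or
Poissonian loss plus an L2 ridge `λ‖θ‖²` (λ = 1), and model selection uses
twofold cross-validation (train one year, validate the other), the
Sørensen–Dice index `S = 2Σ min(data, model)/(Σ data + Σ model)`, `BIC =
2 log M − 2 log L̂`, and the mean squared error of log counts.

A synthetic-study generator draws territory systems with known ground-truth
parameters so the whole pipeline is testable without the police dataset;
see `docs/methods.md` for the generative assumptions.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
generated dataset (written under `results/analysis/`):

```
python analysis/01_simulate.py
python analysis/02_fit_headline_models.py
python analysis/03_crossvalidate_rank.py
python analysis/04_concentration_and_maps.py
```

`02_fit_headline_models.py` prints, for the generated study:

```
retail[knife_crimes+misuse_admissions]-poisson-2019
  theta: {alpha_knife_crimes=-0.01879, alpha_misuse_admissions=-0.008431, beta=0.014}
  validation S (2020): 0.9931
retail recovery vs truth:
  alpha_knife_crimes: fitted -0.01879, truth -0.013 (+44.5%)
  alpha_misuse_admissions: fitted -0.008431, truth -0.00774 (+8.9%)
  beta: fitted 0.014, truth 0.014 (+0.0%)
```

i.e. the travel-cost β is recovered essentially exactly, while the small
benefit exponents carry visible single-draw Poisson noise (they average out
across seeds; the acceptance script reports the across-seed medians). The
cross-validation driver then ranks all 68 Poisson fits and reports the best
model family, and the concentration driver reports that ~88% of the
generated lines fall in the 16 'south' destinations nearest the origin.

The same machinery is exposed as a CLI: `clm simulate`, `clm fit`,
`clm evaluate`, `clm rank`, `clm map`, `clm run` (exit codes: 0 ok,
2 validation error, 3 convergence failure).

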