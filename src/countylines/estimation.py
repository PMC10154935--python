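"""Penalised-loss calibration of flow models and twofold cross-validation.

Each model family is fitted by minimising a per-destination loss plus an
L2 ridge penalty lambda * ||theta||^2 (lambda = 1 by default, applied to
every free parameter including the travel-cost beta):

* Gaussian loss   (1/2N) Σ_j (T_j^data - T_j^model)^2
* Poissonian loss (1/N)  Σ_j (T_j^model - T_j^data log T_j^model)

Optimisation is a deterministic multi-start: a fixed coarse grid of
starting points per family, each refined with bounded L-BFGS-B, keeping
the best penalised loss (the losses are smooth in the parameters). The
radiation parameters (rho, r) are optimised in log space to enforce
positivity; the penalty is evaluated on the natural parameters.

The retail covariate lattice enumerates every subset of the five benefit
covariates (2^5 = 32 variants, travel-time cost beta always free), and a
twofold cross-validation trains on one year and validates on the other.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .data_model import BENEFIT_NAMES, LineCounts, Study, normalise_covariates
from .errors import ValidationError
from .evaluation import bic, log_mse, sorensen_dice
from .flow_models import (
    FlowVector,
    GravityParams,
    RadiationParams,
    RetailParams,
    gravity_flows,
    radiation_flows,
    retail_flows,
)

FAMILIES = ("gravity", "radiation", "retail")
LOSSES = ("gaussian", "poisson")


@dataclass(frozen=True)
class ModelSpec:
    """A model family + retail covariate subset + loss + training year."""

    family: str
    covariates: tuple[str, ...] = ()
    loss: str = "poisson"
    train_year: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if self.loss not in LOSSES:
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.covariates and self.family != "retail":
            raise ValidationError("covariates only apply to the retail family")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValidationError(f"duplicate covariates in {self.covariates}")
        if len(self.covariates) > 5:
            raise ValidationError("at most 5 benefit covariates")

    @property
    def spec_id(self) -> str:
        cov = "+".join(self.covariates)
        return f"{self.family}[{cov}]-{self.loss}-{self.train_year}"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "gravity":
            return ("b", "c")
        if self.family == "radiation":
            return ("rho", "r")
        return tuple(f"alpha_{c}" for c in self.covariates) + ("beta",)


@dataclass
class FitResult:
    """A calibrated model: fitted parameters, losses, likelihood and
    per-year predicted flow vectors."""

    spec: ModelSpec
    theta_hat: dict[str, float]
    train_loss: float
    loglik_hat: float
    predictions: dict[str, FlowVector]
    converged: bool = True
    start_log: list[dict] = field(default_factory=list)

    def params(self):
        return _params_from_theta(self.spec, np.array(list(self.theta_hat.values())))


# ---------------------------------------------------------------------------
# losses and likelihoods


def _aligned_arrays(data, flows) -> tuple[np.ndarray, np.ndarray]:
    d = data.counts if isinstance(data, LineCounts) else pd.Series(data, dtype=float)
    m = flows.flows if isinstance(flows, FlowVector) else pd.Series(flows, dtype=float)
    if set(d.index) != set(m.index):
        raise ValidationError("data and model cover different destination sets")
    m = m.reindex(d.index)
    return d.to_numpy(dtype=float), m.to_numpy(dtype=float)


def gaussian_loss(data, flows, theta=(), lam: float = 1.0) -> float:
    """Mean-square loss (1/2N) Σ (data - model)² + lam ||theta||²."""
    d, m = _aligned_arrays(data, flows)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return float(np.sum((d - m) ** 2) / (2 * len(d)) + lam * np.sum(theta**2))


def poisson_loss(data, flows, theta=(), lam: float = 1.0) -> float:
    """Poissonian deviance-style loss (1/N) Σ (model - data·log model)
    + lam ||theta||². Zero-count destinations contribute just the model
    mean; a nonpositive model flow where data are positive is an error."""
    d, m = _aligned_arrays(data, flows)
    if np.any((m <= 0) & (d > 0)):
        raise ValidationError("nonpositive model flow at a destination with observed lines")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    terms = m.copy()
    pos = d > 0
    terms[pos] -= d[pos] * np.log(m[pos])
    return float(terms.sum() / len(d) + lam * np.sum(theta**2))


def log_likelihood(data, flows, loss: str) -> float:
    """Unpenalised log-likelihood at the fitted flows.

    Poisson: Σ (d log m - m - log d!). Gaussian: unit observation variance,
    -(1/2) Σ (d - m)² - (N/2) log 2π.
    """
    d, m = _aligned_arrays(data, flows)
    if loss == "poisson":
        if np.any((m <= 0) & (d > 0)):
            raise ValidationError("nonpositive model flow with positive count")
        ll = -m.sum() - gammaln(d + 1).sum()
        pos = d > 0
        ll += float(np.sum(d[pos] * np.log(m[pos])))
        return float(ll)
    if loss == "gaussian":
        return float(-0.5 * np.sum((d - m) ** 2) - 0.5 * len(d) * np.log(2 * np.pi))
    raise ValidationError(f"unknown loss {loss!r}")


LOSS_FUNCTIONS = {"gaussian": gaussian_loss, "poisson": poisson_loss}


# ---------------------------------------------------------------------------
# parameter vector plumbing

#: Fixed multi-start grids per family (natural parameters).
GRAVITY_STARTS: tuple[tuple[float, float], ...] = tuple(
    (b, c) for b in (0.0, 0.5, 1.0) for c in (-1.0, 0.0, 1.0)
)
RADIATION_STARTS: tuple[tuple[float, float], ...] = (
    (0.5, 1.0),
    (1.0, 1.0),
    (2.0, 1.0),
    (1.0, 0.5),
    (1.0, 2.0),
    (4.0, 1.5),
)
RETAIL_BETA_STARTS: tuple[float, ...] = (0.0, 0.01, 0.05)
RETAIL_ALPHA_START: float = -0.05

#: Parameter boxes for the bounded refinement.
GRAVITY_BOUNDS = [(-5.0, 5.0), (-5.0, 5.0)]
RETAIL_ALPHA_BOUNDS = (-2.0, 2.0)
RETAIL_BETA_BOUNDS = (-1.0, 1.0)
RADIATION_LOG_BOUNDS = [(np.log(1e-3), np.log(1e3))] * 2


def _params_from_theta(spec: ModelSpec, theta: np.ndarray):
    if spec.family == "gravity":
        return GravityParams(b=float(theta[0]), c=float(theta[1]))
    if spec.family == "radiation":
        return RadiationParams(rho=float(theta[0]), r=float(theta[1]))
    alphas = dict(zip(spec.covariates, (float(a) for a in theta[:-1])))
    return RetailParams(alphas=alphas, beta=float(theta[-1]))


def _starts(spec: ModelSpec) -> list[np.ndarray]:
    if spec.family == "gravity":
        return [np.array(s) for s in GRAVITY_STARTS]
    if spec.family == "radiation":
        return [np.array(s) for s in RADIATION_STARTS]
    k = len(spec.covariates)
    starts = [np.r_[np.zeros(k), b0] for b0 in RETAIL_BETA_STARTS]
    if k:
        starts.append(np.r_[np.full(k, RETAIL_ALPHA_START), 0.01])
    return starts


def _bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    if spec.family == "gravity":
        return GRAVITY_BOUNDS
    if spec.family == "radiation":
        return RADIATION_LOG_BOUNDS
    k = len(spec.covariates)
    return [RETAIL_ALPHA_BOUNDS] * k + [RETAIL_BETA_BOUNDS]


def predict_flows(
    spec: ModelSpec,
    theta: np.ndarray,
    study: Study,
    T_i: float,
    benefits: pd.DataFrame | None = None,
    destinations: Sequence[str] | None = None,
) -> FlowVector:
    """Expected flows for parameter vector ``theta`` (natural scale) at
    origin outflow ``T_i``."""
    origin = study.origin
    dests = list(destinations) if destinations is not None else study.destination_ids
    params = _params_from_theta(spec, theta)
    if spec.family == "gravity":
        return gravity_flows(
            T_i,
            study.population().loc[dests],
            study.distances.row(origin, dests),
            params,
            origin=origin,
        )
    if spec.family == "radiation":
        pops = study.population()
        return FlowVector(
            origin=origin,
            flows=radiation_flows(
                T_i, pops, study.distances.to_frame(), params, origin
            ).flows.reindex(dests),
        )
    if benefits is None:
        benefits = normalise_covariates(study.territories, study.covariates)
    return retail_flows(
        T_i, benefits.loc[dests], study.travel_times.row(origin, dests), params, origin=origin
    )


def fit_model(
    spec: ModelSpec,
    study: Study,
    lam: float = 1.0,
    admissions_mode: str = "per_100k",
) -> FitResult:
    """Calibrate ``spec`` on its training year by deterministic multi-start
    penalised-loss minimisation.

    Returns a :class:`FitResult` carrying the fitted parameters, the
    penalised training loss, the unpenalised log-likelihood at the optimum
    and predictions for every year in the study (each scaled to that
    year's observed outflow). Non-convergence of every start is flagged on
    the result rather than raised.
    """
    if spec.train_year not in study.lines:
        raise ValidationError(
            f"training year {spec.train_year!r} not among {sorted(study.lines)}"
        )
    data = study.lines[spec.train_year]
    dests = list(data.counts.index)
    T_i = data.total
    loss_fn = LOSS_FUNCTIONS[spec.loss]
    benefits = (
        normalise_covariates(study.territories, study.covariates, admissions_mode)
        if spec.family == "retail"
        else None
    )
    log_space = spec.family == "radiation"

    def natural(x: np.ndarray) -> np.ndarray:
        return np.exp(x) if log_space else x

    def objective(x: np.ndarray) -> float:
        theta = natural(x)
        try:
            flows = predict_flows(spec, theta, study, T_i, benefits, dests)
            return loss_fn(data, flows, theta, lam)
        except (ValidationError, FloatingPointError, OverflowError):
            return 1e300  # large finite sentinel keeps finite differences defined

    best = None
    start_log: list[dict] = []
    any_success = False
    for x0 in _starts(spec):
        x0 = np.log(x0) if log_space else x0
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=_bounds(spec),
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        # guard against a refinement ending above its own start
        f0 = objective(x0)
        cand = (res.fun, res.x) if res.fun <= f0 else (f0, x0)
        start_log.append(
            {
                "start": natural(x0).tolist(),
                "final": natural(cand[1]).tolist(),
                "loss": float(cand[0]),
                "success": bool(res.success),
            }
        )
        any_success = any_success or res.success
        if best is None or cand[0] < best[0]:
            best = cand

    theta_hat = natural(best[1])
    train_loss = float(best[0])
    if not np.isfinite(train_loss) or train_loss >= 1e299:
        raise ValidationError(
            f"{spec.spec_id}: loss not finite at any start (invalid data for family?)"
        )
    flows_hat = predict_flows(spec, theta_hat, study, T_i, benefits, dests)
    loglik = log_likelihood(data, flows_hat, spec.loss)
    predictions = {
        year: predict_flows(
            spec, theta_hat, study, lc.total, benefits, list(lc.counts.index)
        )
        for year, lc in study.lines.items()
    }
    return FitResult(
        spec=spec,
        theta_hat=dict(zip(spec.param_names, (float(t) for t in theta_hat))),
        train_loss=train_loss,
        loglik_hat=float(loglik),
        predictions=predictions,
        converged=any_success,
        start_log=start_log,
    )


# ---------------------------------------------------------------------------
# variant enumeration and cross-validation


def enumerate_retail_variants(
    covariate_names: Sequence[str] = BENEFIT_NAMES,
    loss: str = "poisson",
    train_year: str | None = None,
) -> list[ModelSpec]:
    """All retail covariate subsets (including the empty, travel-time-only
    model); the travel-cost beta is free in every variant. Five covariates
    give 2^5 = 32 specs."""
    names = tuple(covariate_names)
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate covariate names in {names}")
    specs = []
    for k in range(len(names) + 1):
        for combo in itertools.combinations(names, k):
            specs.append(
                ModelSpec(family="retail", covariates=combo, loss=loss, train_year=train_year)
            )
    return specs


def full_spec_grid(
    loss: str,
    train_year: str | None = None,
    covariate_names: Sequence[str] = BENEFIT_NAMES,
) -> list[ModelSpec]:
    """One gravity + one radiation + the 32 retail variants (34 specs)."""
    return [
        ModelSpec(family="gravity", loss=loss, train_year=train_year),
        ModelSpec(family="radiation", loss=loss, train_year=train_year),
        *enumerate_retail_variants(covariate_names, loss, train_year),
    ]


def total_log_likelihood(fit: FitResult, study: Study) -> tuple[float, int]:
    """Log-likelihood of the whole modelled sample (every year) at the
    fitted parameters, and its size M."""
    ll, M = 0.0, 0
    for year, lc in study.lines.items():
        ll += log_likelihood(lc, fit.predictions[year], fit.spec.loss)
        M += len(lc.counts)
    return float(ll), M


def crossvalidate(
    specs: Iterable[ModelSpec],
    study: Study,
    lam: float = 1.0,
    admissions_mode: str = "per_100k",
    log_mse_offset: float = 1.0,
) -> pd.DataFrame:
    """Twofold cross-validation: each spec is trained on its training year
    and validated on the other year; specs without a training year are
    expanded into both folds.

    Returns one row per (spec, fold) with the fitted parameters, the
    penalised training loss, validation Sørensen–Dice and log-MSE, and the
    BIC computed over the whole modelled sample (both years)."""
    years = sorted(study.lines)
    if len(years) != 2:
        raise ValidationError(f"twofold cross-validation needs exactly 2 years, got {years}")
    expanded: list[ModelSpec] = []
    for spec in specs:
        if spec.train_year is None:
            expanded.extend(
                ModelSpec(spec.family, spec.covariates, spec.loss, y) for y in years
            )
        else:
            if spec.train_year not in years:
                raise ValidationError(f"unknown training year {spec.train_year!r}")
            expanded.append(spec)

    rows = []
    for spec in expanded:
        val_year = next(y for y in years if y != spec.train_year)
        fit = fit_model(spec, study, lam=lam, admissions_mode=admissions_mode)
        val_data = study.lines[val_year]
        val_pred = fit.predictions[val_year]
        ll_all, M = total_log_likelihood(fit, study)
        rows.append(
            {
                "spec_id": spec.spec_id,
                "family": spec.family,
                "covariates": "+".join(spec.covariates),
                "loss": spec.loss,
                "train_year": spec.train_year,
                "val_year": val_year,
                "n_params": len(spec.param_names),
                "theta": dict(fit.theta_hat),
                "train_loss": fit.train_loss,
                "loglik_hat": fit.loglik_hat,
                "bic": bic(M, ll_all),
                "S": sorensen_dice(val_data, val_pred),
                "log_mse": log_mse(val_data, val_pred, offset=log_mse_offset),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
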