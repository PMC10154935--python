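"""Expected single-origin flows under the gravity, radiation and retail
spatial-interaction models.

All three models allocate a fixed origin outflow ``T_i`` across the
destination territories, so every flow vector satisfies the outflow
constraint sum_j T_ij = T_i by construction:

* **gravity** — share proportional to ``m_j^b * d_ij^c`` with destination
  mass ``m_j`` (population) and distance ``d_ij``; ``c`` is an
  unconstrained real, so both decaying and growing distance dependence are
  representable.
* **retail** — entropy-maximising (softmax) share with utility
  ``sum_n alpha_n * log w_j^(n) - beta * c_ij`` built from normalised
  benefit covariates ``w`` and travel times ``c_ij`` in minutes.
* **radiation** — share proportional to the probability that a "particle"
  leaving the origin is absorbed exactly at the destination, given the
  opportunities ``n = rho * population`` at the origin, the destination,
  and in between (territories strictly closer to the origin than the
  destination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class GravityParams:
    """Gravity exponents: destination mass ``b`` and distance ``c``."""

    b: float
    c: float

    def as_dict(self) -> dict[str, float]:
        return {"b": self.b, "c": self.c}


@dataclass(frozen=True)
class RetailParams:
    """Retail benefit exponents ``alpha_n`` per covariate plus the
    travel-time cost ``beta`` (per minute)."""

    alphas: Mapping[str, float] = field(default_factory=dict)
    beta: float = 0.0

    def as_dict(self) -> dict[str, float]:
        out = {f"alpha_{k}": float(v) for k, v in self.alphas.items()}
        out["beta"] = float(self.beta)
        return out


@dataclass(frozen=True)
class RadiationParams:
    """Radiation parameters: opportunities per person ``rho`` (n_i = rho * p_i)
    and absorption exponent ``r``; both strictly positive."""

    rho: float
    r: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.r <= 0:
            raise ValidationError(f"rho and r must be > 0, got {self.rho}, {self.r}")

    def as_dict(self) -> dict[str, float]:
        return {"rho": self.rho, "r": self.r}


@dataclass(frozen=True)
class FlowVector:
    """Expected lines from one origin to each destination; entries are
    nonnegative and sum to the supplied outflow."""

    origin: str
    flows: pd.Series

    def __post_init__(self) -> None:
        if (self.flows.to_numpy() < 0).any():
            raise ValidationError("flows must be >= 0")

    @property
    def total(self) -> float:
        return float(self.flows.sum())


def _normalised_allocation(origin: str, log_weights: pd.Series, T_i: float) -> FlowVector:
    # max-shift before exponentiation: identity-preserving, numerically safe
    shifted = np.exp(log_weights - log_weights.max())
    return FlowVector(origin=origin, flows=T_i * shifted / shifted.sum())


def gravity_flows(
    T_i: float,
    masses: pd.Series,
    distances: pd.Series,
    params: GravityParams,
    origin: str = "origin",
) -> FlowVector:
    """Gravity allocation T_ij = T_i * m_j^b d_ij^c / sum_k m_k^b d_ik^c.

    ``masses`` and ``distances`` are indexed by destination id (the origin
    itself is excluded); all masses and distances must be positive.
    """
    masses, distances = masses.align(distances, join="inner")
    if (masses <= 0).any():
        raise ValidationError("gravity masses must be > 0")
    if (distances <= 0).any():
        raise ValidationError("gravity distances must be > 0 (origin excluded)")
    log_w = params.b * np.log(masses) + params.c * np.log(distances)
    return _normalised_allocation(origin, log_w, T_i)


def retail_utilities(
    benefits: pd.DataFrame, travel_times: pd.Series, params: RetailParams
) -> pd.Series:
    """Destination utilities sum_n alpha_n log w_j^(n) - beta c_ij."""
    util = -params.beta * travel_times.astype(float)
    for name, alpha in params.alphas.items():
        if name not in benefits.columns:
            raise ValidationError(f"benefit covariate {name!r} not in table")
        w = benefits[name].reindex(travel_times.index)
        bad = w.index[(w <= 0) | w.isna()]
        if len(bad):
            raise ValidationError(
                f"covariate {name!r} must be > 0 to enter a logarithm; "
                f"offending territories {list(bad)}"
            )
        util = util + alpha * np.log(w)
    return util


def retail_flows(
    T_i: float,
    benefits: pd.DataFrame,
    travel_times: pd.Series,
    params: RetailParams,
    origin: str = "origin",
) -> FlowVector:
    """Entropy-maximising retail allocation: softmax of the destination
    utilities scaled to the origin outflow."""
    if (travel_times <= 0).any():
        raise ValidationError("travel times must be > 0 (origin excluded)")
    return _normalised_allocation(
        origin, retail_utilities(benefits, travel_times, params), T_i
    )


def intervening_population(
    populations: pd.Series,
    distances: pd.DataFrame,
    origin: str,
    destination: str,
) -> float:
    """Population p_ij intervening between ``origin`` and ``destination``:
    the summed population of every territory k (excluding both endpoints)
    strictly closer to the origin than the destination is. Ties are
    excluded."""
    if origin == destination:
        raise ValidationError("origin and destination must differ")
    d_ij = distances.loc[origin, destination]
    row = distances.loc[origin]
    closer = row.index[(row < d_ij) & (row.index != origin) & (row.index != destination)]
    return float(populations.loc[closer].sum())


def absorption_probability(
    n_i: float | np.ndarray,
    n_j: float | np.ndarray,
    n_ij: float | np.ndarray,
    r: float,
) -> float | np.ndarray:
    """Probability that a particle emitted at i is absorbed at j, given
    the opportunities at the origin (n_i), the destination (n_j) and in
    between (n_ij), with absorption exponent r > 0."""
    n_i, n_j, n_ij = np.asarray(n_i, float), np.asarray(n_j, float), np.asarray(n_ij, float)
    if np.any(n_i < 0) or np.any(n_j < 0) or np.any(n_ij < 0):
        raise ValidationError("opportunity counts must be >= 0")
    # evaluated in log space: with territory-scale opportunity counts the
    # powers (n_i + n_j + n_ij)^r overflow double precision long before the
    # probability itself degenerates
    with np.errstate(divide="ignore", invalid="ignore"):
        log_a = r * np.log(n_i + n_ij)  # log (n_i + n_ij)^r
        log_b = r * np.log(n_i + n_j + n_ij)
        log_ni_r = r * np.log(n_i)
        # log(e^b - e^a) = b + log1p(-e^(a-b)); a == b (n_j = 0) gives -inf
        log_diff = log_b + np.log1p(-np.exp(np.minimum(log_a - log_b, 0.0)))
        log_num = log_diff + np.logaddexp(log_ni_r, 0.0)
        log_den = np.logaddexp(log_a, 0.0) + np.logaddexp(log_b, 0.0)
        p = np.where(np.isfinite(log_diff), np.exp(log_num - log_den), 0.0)
    return p if p.ndim else float(p)


def radiation_flows(
    T_i: float,
    populations: pd.Series,
    distances: pd.DataFrame,
    params: RadiationParams,
    origin: str,
) -> FlowVector:
    """Radiation allocation with opportunities n = rho * population and
    intervening opportunities n_ij accumulated over territories closer to
    the origin than each destination."""
    if (populations <= 0).any():
        raise ValidationError("populations must be > 0")
    if origin not in populations.index:
        raise ValidationError(f"origin {origin!r} not among territories")
    dests = [i for i in populations.index if i != origin]
    n_i = params.rho * populations.loc[origin]
    n_j = params.rho * populations.loc[dests].to_numpy()
    n_ij = np.array(
        [
            params.rho * intervening_population(populations, distances, origin, j)
            for j in dests
        ]
    )
    probs = absorption_probability(n_i, n_j, n_ij, params.r)
    total = probs.sum()
    if total <= 0:
        raise ValidationError("degenerate geography: all absorption probabilities zero")
    return FlowVector(origin=origin, flows=pd.Series(T_i * probs / total, index=dests))
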