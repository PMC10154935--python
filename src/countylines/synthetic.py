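"""Synthetic two-year studies with known ground truth.

The generator emulates the statistical shape of the England detected-lines
dataset: one high-population origin plus ~37 destination territories,
log-normal populations and per-100k covariate rates, planar geography with
Euclidean distances and travel times roughly proportional to distance, and
yearly line counts drawn independently from Poisson distributions whose
means follow a ground-truth flow model scaled to a fixed total outflow.
The two year labels are i.i.d. draws from a single truth; between-year
drift and police take-downs are not modelled.

The sixteen destinations nearest the origin are tagged ``south`` (the rest
``north``) so concentration-share analyses have a region subset to work
with; the generator makes no attempt to reproduce the real 'north--south'
border geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import (
    BENEFIT_NAMES,
    COVARIATE_NAMES,
    CovariateTable,
    LineCounts,
    LONDON_ID,
    ODMatrix,
    Study,
    Territory,
    normalise_covariates,
)
from .errors import ValidationError
from .estimation import ModelSpec, predict_flows
from .flow_models import FlowVector, GravityParams, RadiationParams, RetailParams

#: Log-normal laws for per-100k covariate rates: name -> (median, sigma of log).
DEFAULT_COVARIATE_LAWS: dict[str, tuple[float, float]] = {
    "misuse_admissions": (80.0, 0.5),
    "poisoning_admissions": (40.0, 0.5),
    "police_officers": (220.0, 0.25),
    "gdhi": (20000.0, 0.15),  # per-head income; stored as a territory total
    "knife_crimes": (70.0, 0.6),
    "hospital_beds": (250.0, 0.3),
}

#: Ground-truth retail parameters: benefit exponents for hospital misuse
#: admissions and knife crime (both mild costs) and a per-minute travel cost.
DEFAULT_TRUTH = RetailParams(
    alphas={"misuse_admissions": -7.74e-3, "knife_crimes": -0.013}, beta=0.014
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Populations and covariate rates are log-normal; ``population_law`` and
    each covariate law are (median, sigma-of-log) pairs. ``speed`` is km
    per minute (1.0 ~ 60 km/h average road speed); ``time_noise`` is the
    sigma of multiplicative log-normal noise on travel times.
    ``total_outflow`` is the expected number of detected lines leaving the
    origin per year.
    """

    seed: int = 0
    n_destinations: int = 37
    box_km: float = 450.0
    origin_population: float = 8.9e6
    population_law: tuple[float, float] = (1.1e6, 0.45)
    covariate_laws: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LAWS)
    )
    speed: float = 1.0
    time_noise: float = 0.15
    truth_family: str = "retail"
    truth_params: RetailParams | GravityParams | RadiationParams = DEFAULT_TRUTH
    total_outflow: float = 1e5
    years: tuple[str, str] = ("2019", "2020")
    n_south: int = 16

    def __post_init__(self) -> None:
        if self.n_destinations < 2:
            raise ValidationError("need at least 2 destinations")
        if self.total_outflow <= 0:
            raise ValidationError("total_outflow must be > 0")
        if self.speed <= 0:
            raise ValidationError("speed must be > 0")
        missing = set(COVARIATE_NAMES) - set(self.covariate_laws)
        if missing:
            raise ValidationError(f"covariate laws missing {sorted(missing)}")


@dataclass
class SyntheticStudy(Study):
    """A generated study plus its ground-truth record."""

    truth: dict = field(default_factory=dict)
    expected_flows: FlowVector | None = None


def _dest_ids(n: int) -> list[str]:
    return [f"t{i:02d}" for i in range(1, n + 1)]


def generate_geography(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[Territory], ODMatrix, ODMatrix]:
    """Sample territory centroids in a planar box and derive both OD
    matrices: Euclidean distances and travel times d/speed with
    multiplicative log-normal noise (symmetrised)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_destinations
    coords = rng.uniform(0.0, config.box_km, size=(n + 1, 2))
    ids = [LONDON_ID] + _dest_ids(n)

    mu = np.log(config.population_law[0])
    pops = np.r_[
        config.origin_population,
        np.exp(rng.normal(mu, config.population_law[1], size=n)),
    ]

    dist = cdist(coords, coords)
    # nearest-to-origin destinations form the synthetic 'south' region
    order = np.argsort(dist[0, 1:])
    south = {ids[1 + k] for k in order[: config.n_south]}

    noise = np.exp(rng.normal(0.0, config.time_noise, size=dist.shape))
    noise = np.sqrt(noise * noise.T)  # keep travel times symmetric
    times = dist / config.speed * noise
    np.fill_diagonal(times, 0.0)

    territories = [
        Territory(
            id=tid,
            name=tid.upper(),
            population=float(p),
            lon=float(x),
            lat=float(y),
            region_tag="origin" if tid == LONDON_ID else ("south" if tid in south else "north"),
        )
        for tid, p, (x, y) in zip(ids, pops, coords)
    ]
    return (
        territories,
        ODMatrix(ids=tuple(ids), values=dist, kind="distance"),
        ODMatrix(ids=tuple(ids), values=times, kind="travel_time"),
    )


def generate_covariates(
    territories: list[Territory],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> CovariateTable:
    """Draw per-100k rates from the configured log-normal laws and convert
    them to raw territory totals (rate * population / 1e5)."""
    pops = pd.Series({t.id: t.population for t in territories})
    raw = pd.DataFrame(index=pops.index)
    for name in COVARIATE_NAMES:
        median, sigma = config.covariate_laws[name]
        rates = np.exp(rng.normal(np.log(median), sigma, size=len(pops)))
        raw[name] = rates * pops.to_numpy() / 1e5
    return CovariateTable(raw)


def sample_line_counts(
    flows: FlowVector | pd.Series,
    seed: int | np.random.Generator,
    origin: str = LONDON_ID,
    year: str = "2019",
) -> LineCounts:
    """Independent Poisson draws around the expected flows."""
    means = flows.flows if isinstance(flows, FlowVector) else pd.Series(flows, dtype=float)
    origin = flows.origin if isinstance(flows, FlowVector) else origin
    if (means.to_numpy() < 0).any():
        raise ValidationError("Poisson means must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(means.to_numpy().astype(float))
    return LineCounts(
        origin=origin, year=year, counts=pd.Series(counts, index=means.index, dtype=float)
    )


def _truth_theta(config: SyntheticConfig, spec: ModelSpec) -> np.ndarray:
    p = config.truth_params
    if isinstance(p, GravityParams):
        return np.array([p.b, p.c])
    if isinstance(p, RadiationParams):
        return np.array([p.rho, p.r])
    return np.array([p.alphas[c] for c in spec.covariates] + [p.beta])


def make_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full two-year synthetic study.

    Expected flows come from the configured ground-truth model scaled to
    ``total_outflow`` (so they sum to it exactly); each year's line counts
    are an independent Poisson draw around those expectations. The truth
    record is stored for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    territories, dist, times = generate_geography(config, rng)
    covariates = generate_covariates(territories, config, rng)

    covs = (
        tuple(sorted(config.truth_params.alphas))
        if isinstance(config.truth_params, RetailParams)
        else ()
    )
    spec = ModelSpec(family=config.truth_family, covariates=covs, loss="poisson")
    study = Study(
        territories=territories,
        covariates=covariates,
        distances=dist,
        travel_times=times,
        lines={},
        origin=LONDON_ID,
    )
    benefits = normalise_covariates(territories, covariates)
    if isinstance(config.truth_params, RetailParams):
        bad = [
            c for c in covs if (benefits[c].loc[study.destination_ids] <= 0).any()
        ]
        if bad:
            raise ValidationError(f"zero covariate under a log-covariate truth: {bad}")
    expected = predict_flows(
        spec, _truth_theta(config, spec), study, config.total_outflow, benefits
    )

    lines = {
        year: sample_line_counts(expected, rng, year=year) for year in config.years
    }
    truth = {
        "family": config.truth_family,
        "params": config.truth_params.as_dict(),
        "total_outflow": config.total_outflow,
        "seed": config.seed,
    }
    return SyntheticStudy(
        territories=territories,
        covariates=covariates,
        distances=dist,
        travel_times=times,
        lines=lines,
        origin=LONDON_ID,
        truth=truth,
        expected_flows=expected,
    )
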