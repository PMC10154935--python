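"""Model-selection metrics and reporting.

Validation compares an observed line-count vector with a modelled flow
vector over the same destinations using the Sørensen–Dice overlap index,
an information criterion (BIC) on the training log-likelihood, and the
mean squared error of log counts. Rankings and a minimal-variable filter
reproduce the style of the headline model-comparison table; geographic
reporting annotates a boundary GeoJSON with observed/modelled/difference
attributes per territory.
"""

from __future__ import annotations

import copy
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import LineCounts
from .errors import ValidationError
from .flow_models import FlowVector


def _as_series(x) -> pd.Series:
    if isinstance(x, LineCounts):
        return x.counts.astype(float)
    if isinstance(x, FlowVector):
        return x.flows.astype(float)
    return pd.Series(x, dtype=float)


def _aligned(data, model) -> tuple[pd.Series, pd.Series]:
    d, m = _as_series(data), _as_series(model)
    if set(d.index) != set(m.index):
        raise ValidationError("data and model cover different destination sets")
    return d, m.reindex(d.index)


def sorensen_dice(data, model) -> float:
    """Sørensen–Dice overlap S = 2 Σ_j min(d_j, m_j) / (Σ_j d_j + Σ_j m_j).

    S is 1 exactly when the two vectors coincide element-wise and 0 when
    their supports are disjoint; undefined (error) when both totals vanish.
    """
    d, m = _aligned(data, model)
    denom = d.sum() + m.sum()
    if denom == 0:
        raise ValidationError("Sørensen–Dice undefined: both totals are zero")
    return float(2.0 * np.minimum(d, m).sum() / denom)


def bic(M: int, loglik_hat: float, k: int | None = None) -> float:
    """Information criterion 2 log M - 2 log L-hat for sample size M.

    The default has no parameter-count factor. Passing ``k`` switches to
    the conventional k log M - 2 log L-hat penalised form.
    """
    if M < 1:
        raise ValidationError(f"sample size must be >= 1, got {M}")
    factor = 2.0 if k is None else float(k)
    return float(factor * np.log(M) - 2.0 * loglik_hat)


def log_mse(data, model, offset: float = 1.0) -> float:
    """Mean squared error of log counts:
    (1/N) Σ_j (log(d_j + offset) - log(m_j + offset))².

    The additive offset (default 1) admits zero counts. With ``offset=0``
    destination pairs where either side is zero are excluded, since their
    logarithm is undefined.
    """
    d, m = _aligned(data, model)
    if (d < 0).any() or (m < 0).any():
        raise ValidationError("log-MSE requires nonnegative entries")
    if offset == 0:
        keep = (d > 0) & (m > 0)
        d, m = d[keep], m[keep]
        if len(d) == 0:
            raise ValidationError("log-MSE with offset=0: no strictly positive pairs")
    return float(np.mean((np.log(d + offset) - np.log(m + offset)) ** 2))


def concentration_share(lines: LineCounts, subset: Iterable[str]) -> float:
    """Fraction of the total observed lines falling in ``subset`` of the
    destinations (e.g. the 'south' territory set)."""
    subset = list(subset)
    extra = set(subset) - set(lines.counts.index)
    if extra:
        raise ValidationError(f"subset territories not among destinations: {sorted(extra)}")
    total = lines.counts.sum()
    if total == 0:
        raise ValidationError("concentration share undefined: zero total lines")
    return float(lines.counts.loc[subset].sum() / total)


_RANK_KEYS = {"log_mse": True, "bic": True, "S": False}  # key -> ascending


def rank_models(metrics: pd.DataFrame, key: str = "log_mse") -> pd.DataFrame:
    """Rank a metrics table by ``key`` (ascending for log_mse/bic,
    descending for S). Ties break toward fewer covariates, then by
    lexicographic spec id. Adds a 1-based ``rank`` column."""
    if key not in _RANK_KEYS:
        raise ValidationError(f"unknown ranking key {key!r}; use one of {sorted(_RANK_KEYS)}")
    if metrics.empty:
        raise ValidationError("cannot rank an empty metrics table")
    df = metrics.copy()
    df["_n_cov"] = df["covariates"].map(
        lambda c: 0 if not c or (isinstance(c, float) and np.isnan(c)) else len(str(c).split("+"))
    )
    df = df.sort_values(
        [key, "_n_cov", "spec_id"],
        ascending=[_RANK_KEYS[key], True, True],
        kind="mergesort",
    ).drop(columns="_n_cov")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def filter_minimal_variants(
    metrics: pd.DataFrame, active: Iterable[str] | None = None, key: str = "log_mse"
) -> pd.DataFrame:
    """Keep only the retail variants with the minimum number of variables.

    ``active`` names the covariates that matter (default: those of the
    best-ranked retail row under ``key``); retail rows whose covariate set
    is a subset of ``active`` are retained — with two active covariates
    that is exactly four rows (both, each alone, none). Non-retail rows
    always pass through.
    """
    retail = metrics[metrics["family"] == "retail"]
    if active is None:
        if retail.empty:
            return metrics.copy()
        best = rank_models(retail, key=key).iloc[0]
        active = set(str(best["covariates"]).split("+")) if best["covariates"] else set()
    active = set(active)

    def _keep(cov: str) -> bool:
        names = set(str(cov).split("+")) if cov else set()
        return names <= active

    keep_mask = (metrics["family"] != "retail") | metrics["covariates"].map(_keep)
    return metrics[keep_mask].reset_index(drop=True)


def difference_map(
    data: LineCounts,
    model: FlowVector,
    boundaries: Mapping,
) -> dict:
    """Annotate a boundary FeatureCollection with observed, modelled and
    difference (model - data) attributes per territory.

    The sign convention is positive = overestimated by the model.
    Territories without a matching geometry produce a warning and an
    attribute-only feature (null geometry) so totals still reconcile.
    """
    d, m = _aligned(data, model)
    out = copy.deepcopy(dict(boundaries))
    if out.get("type") != "FeatureCollection":
        raise ValidationError("boundaries must be a GeoJSON FeatureCollection")
    seen: set[str] = set()
    features = []
    for feat in out.get("features", []):
        props = feat.setdefault("properties", {})
        tid = props.get("id") or feat.get("id")
        if tid in d.index:
            props.update(
                id=tid,
                observed=float(d.loc[tid]),
                modelled=float(m.loc[tid]),
                difference=float(m.loc[tid] - d.loc[tid]),
            )
            seen.add(tid)
        features.append(feat)
    for tid in d.index:
        if tid not in seen:
            warnings.warn(f"territory {tid!r} has no boundary geometry", stacklevel=2)
            features.append(
                {
                    "type": "Feature",
                    "geometry": None,
                    "properties": {
                        "id": tid,
                        "observed": float(d.loc[tid]),
                        "modelled": float(m.loc[tid]),
                        "difference": float(m.loc[tid] - d.loc[tid]),
                    },
                }
            )
    out["features"] = features
    return out
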