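"""Hierarchical aggregation of indicators into the vulnerability index.

The aggregation follows the rank-transform-weight recipe of the English
IMD family of indices:

1. within each sub-domain, every metric is rank-normalised across areas
   (respecting its polarity), the normalised ranks are averaged with the
   sub-domain's metric weights, and the weighted means are re-ranked and
   pushed through the exponential transform to a 0-100 sub-domain score;
2. each domain score is the weighted mean of its sub-domain scores;
3. domain scores are rank-normalised, exponentially transformed again
   (switchable via ``PipelineConfig.second_transform``) and combined with
   the registry's domain weights into the overall 0-100 index, which is
   then ranked and split into terciles.

Missing metrics are handled by renormalising weights over the non-missing
members; an area missing an entire sub-domain gets a missing domain and a
missing overall index, and is reported rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RegistryValidationError, SchemaError
from .indicators import AREA_ID
from .ranking import exponential_transform, rank_normalise, tercile_classify
from .registry import Domain, MetricRegistry, PipelineConfig, SubDomain

__all__ = [
    "VulnerabilityResult",
    "aggregate_subdomain",
    "aggregate_domain",
    "compose_index",
    "vulnerability_index",
]


@dataclass
class VulnerabilityResult:
    """Per-area vulnerability scores at every level of the hierarchy.

    ``table`` has one row per area with columns: ``rank_<metric_id>``
    (normalised metric ranks), ``sd_<sub_domain_id>`` and ``dom_<domain_id>``
    (0-100 scores), ``vulnerability_index`` (0-100), ``index_rank``
    (normalised, 1 = most vulnerable) and ``index_tercile`` (1..3).
    ``excluded_areas`` lists areas whose index is missing because a whole
    domain was missing.
    """

    table: pd.DataFrame
    excluded_areas: list

    @property
    def index(self) -> pd.Series:
        return self.table.set_index(AREA_ID)["vulnerability_index"]

    @property
    def tercile(self) -> pd.Series:
        return self.table.set_index(AREA_ID)["index_tercile"]


def _metric_ranks(values: pd.Series, polarity: int) -> pd.Series:
    """Normalised ranks of one metric; an entirely-missing metric stays missing."""
    if values.notna().sum() == 0:
        return pd.Series(np.nan, index=values.index)
    return rank_normalise(values, direction=polarity).rank


def _weighted_mean_renormalised(cols: pd.DataFrame, weights: dict[str, float]) -> pd.Series:
    """Row-wise weighted mean with weights renormalised over non-missing cells."""
    w = pd.Series(weights, dtype=float).reindex(cols.columns)
    vals = cols.to_numpy(dtype=float)
    wmat = np.broadcast_to(w.to_numpy(), vals.shape).copy()
    wmat[np.isnan(vals)] = 0.0
    denom = wmat.sum(axis=1)
    num = np.nansum(vals * wmat, axis=1)
    out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(out, index=cols.index)


def aggregate_subdomain(
    indicators: pd.DataFrame, sub_domain: SubDomain, registry: MetricRegistry
) -> pd.Series:
    """0-100 sub-domain score per area.

    Rank-normalise each member metric with its polarity, take the weighted
    mean of the normalised ranks (weights renormalised over non-missing
    metrics), re-rank the means across areas and apply the exponential
    transform.
    """
    members = registry.metrics_of(sub_domain.sub_domain_id)
    if not members:
        raise RegistryValidationError(f"sub-domain {sub_domain.sub_domain_id!r} has no metrics")
    missing = [m.metric_id for m in members if m.metric_id not in indicators.columns]
    if missing:
        raise SchemaError(
            f"indicator table lacks metrics {missing} of sub-domain {sub_domain.sub_domain_id!r}"
        )
    ranks = pd.DataFrame(index=indicators.index)
    for m in members:
        ranks[m.metric_id] = _metric_ranks(indicators[m.metric_id], m.polarity)
    mean_rank = _weighted_mean_renormalised(ranks, sub_domain.metric_weights)
    rr = rank_normalise(mean_rank, direction=1).rank
    score = exponential_transform(rr, scale=registry.transform_scale)
    score.name = f"sd_{sub_domain.sub_domain_id}"
    return score


def aggregate_domain(sub_scores: pd.DataFrame, domain: Domain) -> pd.Series:
    """Weighted mean of member sub-domain scores (0-100 scale preserved).

    An area missing any member sub-domain score gets a missing domain score
    (missing whole sub-domains are not renormalised away: their absence is
    treated as unknown vulnerability, not zero weight).
    """
    cols = [f"sd_{sid}" for sid in domain.sub_domain_weights]
    missing = [c for c in cols if c not in sub_scores.columns]
    if missing:
        raise RegistryValidationError(
            f"domain {domain.domain_id!r}: sub-domain score columns missing: {missing}"
        )
    w = np.array([domain.sub_domain_weights[sid] for sid in domain.sub_domain_weights])
    vals = sub_scores[cols].to_numpy(dtype=float)
    out = vals @ w  # NaN in any member propagates
    score = pd.Series(out, index=sub_scores.index, name=f"dom_{domain.domain_id}")
    return score


def compose_index(
    domain_scores: pd.DataFrame,
    registry: MetricRegistry,
    second_transform: bool = True,
) -> pd.DataFrame:
    """Combine per-domain scores into the overall index, rank and tercile.

    Each domain score is rank-normalised and (by default) exponentially
    transformed before the weighted combination, mirroring how the IMD
    combines its domains.  Returns columns ``vulnerability_index``,
    ``index_rank`` and ``index_tercile`` indexed like ``domain_scores``.
    """
    cols = {did: f"dom_{did}" for did in registry.domain_weights}
    missing = [c for c in cols.values() if c not in domain_scores.columns]
    if missing:
        raise RegistryValidationError(f"domain score columns missing: {missing}")
    transformed = pd.DataFrame(index=domain_scores.index)
    for did, col in cols.items():
        r = rank_normalise(domain_scores[col], direction=1).rank
        transformed[did] = (
            exponential_transform(r, scale=registry.transform_scale) if second_transform else 100.0 * r
        )
    vals = transformed.to_numpy(dtype=float)
    w = np.array([registry.domain_weights[did] for did in cols])
    index = pd.Series(vals @ w, index=domain_scores.index)  # NaN domain -> NaN index
    out = pd.DataFrame(index=domain_scores.index)
    out["vulnerability_index"] = index
    if index.notna().any():
        out["index_rank"] = rank_normalise(index, direction=1).rank
        out["index_tercile"] = tercile_classify(index)
    else:
        out["index_rank"] = np.nan
        out["index_tercile"] = pd.array([pd.NA] * len(index), dtype="Int64")
    return out


def vulnerability_index(
    indicators: pd.DataFrame,
    registry: MetricRegistry,
    config: PipelineConfig | None = None,
) -> VulnerabilityResult:
    """Run the full hierarchy on an indicator table.

    Returns per-area metric ranks, sub-domain scores, domain scores, the
    overall 0-100 index, its normalised rank and its tercile.
    """
    config = config or PipelineConfig()
    if AREA_ID not in indicators.columns:
        raise SchemaError(f"indicator table lacks {AREA_ID!r}")
    body = indicators.reset_index(drop=True)
    table = pd.DataFrame({AREA_ID: body[AREA_ID]})

    for m in registry.metrics:
        table[f"rank_{m.metric_id}"] = _metric_ranks(body[m.metric_id], m.polarity)

    sub_scores = pd.DataFrame(index=body.index)
    for sd in registry.sub_domains:
        sub_scores[f"sd_{sd.sub_domain_id}"] = aggregate_subdomain(body, sd, registry)
    dom_scores = pd.DataFrame(index=body.index)
    for d in registry.domains:
        dom_scores[f"dom_{d.domain_id}"] = aggregate_domain(sub_scores, d)

    composed = compose_index(dom_scores, registry, second_transform=config.second_transform)
    table = pd.concat([table, sub_scores, dom_scores, composed], axis=1)
    excluded = table.loc[table["vulnerability_index"].isna(), AREA_ID].tolist()
    return VulnerabilityResult(table=table, excluded_areas=excluded)
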