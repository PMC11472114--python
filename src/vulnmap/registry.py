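"""Metric registry: the hierarchy of metrics, sub-domains and domains.

The vulnerability index is a three-level hierarchy modelled on the English
Indices of Multiple Deprivation: small-area census/IMD count metrics are
grouped into sub-domains, sub-domains into four domains (sensitivity,
adaptive capacity, health, living environment), and domains into a single
index.  The default registry ships as package data
(``data/default_registry.yaml``) and holds 33 metrics: 31 indexed across
9 sub-domains, plus two separate layers (% female, population density)
that are mapped alongside but do not enter the index.

Weights are stored already normalised to sum to one within each level.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import RegistryValidationError

__all__ = [
    "MetricDefinition",
    "SubDomain",
    "Domain",
    "MetricRegistry",
    "FloodScenario",
    "PipelineConfig",
    "default_registry",
    "load_registry",
    "loads_registry",
    "dump_registry",
    "validate_registry",
]


@dataclass(frozen=True)
class MetricDefinition:
    """One small-area count metric (numerator over a population/household base)."""

    metric_id: str
    label: str
    numerator_field: str
    denominator_field: str
    sub_domain_id: str | None
    polarity: int = 1  # +1: larger proportion = more vulnerable
    source_tag: str = "census2021"
    is_proportion: bool = True  # False for rates such as residents per km2


@dataclass(frozen=True)
class SubDomain:
    sub_domain_id: str
    label: str
    domain_id: str
    metric_weights: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Domain:
    domain_id: str
    label: str
    sub_domain_weights: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class FloodScenario:
    """Metadata describing which flood grid is being consumed.

    ``role`` distinguishes the planning baseline (a 1-in-100-year event under
    RCP 8.5 in 2050) from the low-probability "disaster" grid (1 in 1000).
    """

    return_period_years: int = 100
    climate_pathway: str = "RCP8.5"
    horizon_year: int = 2050
    role: str = "typical"  # "typical" | "disaster"

    def __post_init__(self):
        if self.return_period_years < 1:
            raise RegistryValidationError(
                f"return_period_years must be >= 1, got {self.return_period_years}"
            )
        if self.role not in ("typical", "disaster"):
            raise RegistryValidationError(f"unknown scenario role {self.role!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the exposure and classification stages."""

    flood_depth_threshold_m: float = 0.10
    heat_exceedance_threshold_c: float = 15.0
    season_months: frozenset[int] = frozenset({6, 7, 8})
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    n_deciles: int = 10
    n_terciles: int = 3
    rng_seed: int = 0
    scenario: FloodScenario = field(default_factory=FloodScenario)
    #: apply the exponential transform again when combining domain scores
    second_transform: bool = True
    #: which heat metric feeds the risk matrix: "tmax" or "exceedance"
    heat_matrix_metric: str = "tmax"

    def __post_init__(self):
        if self.flood_depth_threshold_m <= 0:
            raise RegistryValidationError("flood_depth_threshold_m must be positive")
        if not set(self.season_months) <= set(range(1, 13)):
            raise RegistryValidationError("season_months must be within 1..12")
        if len(self.season_months) == 0:
            raise RegistryValidationError("season_months must not be empty")
        if self.heat_matrix_metric not in ("tmax", "exceedance"):
            raise RegistryValidationError(
                f"heat_matrix_metric must be 'tmax' or 'exceedance', got {self.heat_matrix_metric!r}"
            )


@dataclass(frozen=True)
class MetricRegistry:
    domains: tuple[Domain, ...]
    sub_domains: tuple[SubDomain, ...]
    metrics: tuple[MetricDefinition, ...]
    separate_metrics: tuple[MetricDefinition, ...]
    domain_weights: dict[str, float]
    transform_scale: float = 23.0

    # -- lookup helpers -------------------------------------------------
    def metric(self, metric_id: str) -> MetricDefinition:
        for m in self.metrics + self.separate_metrics:
            if m.metric_id == metric_id:
                return m
        raise KeyError(metric_id)

    def sub_domain(self, sub_domain_id: str) -> SubDomain:
        for s in self.sub_domains:
            if s.sub_domain_id == sub_domain_id:
                return s
        raise KeyError(sub_domain_id)

    def domain(self, domain_id: str) -> Domain:
        for d in self.domains:
            if d.domain_id == domain_id:
                return d
        raise KeyError(domain_id)

    def metrics_of(self, sub_domain_id: str) -> list[MetricDefinition]:
        return [m for m in self.metrics if m.sub_domain_id == sub_domain_id]

    @property
    def metric_ids(self) -> list[str]:
        return [m.metric_id for m in self.metrics]

    @property
    def separate_metric_ids(self) -> list[str]:
        return [m.metric_id for m in self.separate_metrics]


def _normalise(weights: dict[str, float], owner: str) -> dict[str, float]:
    for k, w in weights.items():
        if w < 0:
            raise RegistryValidationError(f"{owner}: negative weight for {k!r}: {w}")
    total = sum(weights.values())
    if total <= 0:
        raise RegistryValidationError(f"{owner}: weights sum to {total}, cannot normalise")
    if abs(total - 1.0) < 1e-12:  # already normalised; keep values bit-exact
        return dict(weights)
    return {k: w / total for k, w in weights.items()}


def _metric_from_dict(d: dict, sub_domain_id: str | None) -> MetricDefinition:
    return MetricDefinition(
        metric_id=d["metric_id"],
        label=d.get("label", d["metric_id"]),
        numerator_field=d["numerator_field"],
        denominator_field=d["denominator_field"],
        sub_domain_id=sub_domain_id,
        polarity=int(d.get("polarity", 1)),
        source_tag=d.get("source_tag", "census2021"),
        is_proportion=bool(d.get("is_proportion", True)),
    )


def loads_registry(text: str) -> MetricRegistry:
    """Parse a nested YAML registry document and return a validated registry.

    Weights are normalised to sum to one within each level; any structural
    violation raises :class:`RegistryValidationError` naming the offender.
    """
    doc = yaml.safe_load(text)
    domains: list[Domain] = []
    sub_domains: list[SubDomain] = []
    metrics: list[MetricDefinition] = []
    domain_weights: dict[str, float] = {}
    for dd in doc.get("domains", []):
        did = dd["domain_id"]
        domain_weights[did] = float(dd.get("weight", 1.0))
        sd_weights: dict[str, float] = {}
        for sd in dd.get("sub_domains", []):
            sid = sd["sub_domain_id"]
            sd_weights[sid] = float(sd.get("weight", 1.0))
            m_weights: dict[str, float] = {}
            for md in sd.get("metrics", []):
                m = _metric_from_dict(md, sid)
                metrics.append(m)
                m_weights[m.metric_id] = float(md.get("weight", 1.0))
            if not m_weights:
                raise RegistryValidationError(f"sub-domain {sid!r} has no metrics")
            sub_domains.append(
                SubDomain(sid, sd.get("label", sid), did, _normalise(m_weights, f"sub-domain {sid!r}"))
            )
        if not sd_weights:
            raise RegistryValidationError(f"domain {did!r} has no sub-domains")
        domains.append(Domain(did, dd.get("label", did), _normalise(sd_weights, f"domain {did!r}")))
    separate = tuple(_metric_from_dict(md, None) for md in doc.get("separate_metrics", []))
    registry = MetricRegistry(
        domains=tuple(domains),
        sub_domains=tuple(sub_domains),
        metrics=tuple(metrics),
        separate_metrics=separate,
        domain_weights=_normalise(domain_weights, "domain level"),
        transform_scale=float(doc.get("transform_scale", 23.0)),
    )
    violations = validate_registry(registry)
    if violations:
        raise RegistryValidationError("; ".join(violations))
    return registry


def load_registry(path) -> MetricRegistry:
    """Load a registry from a YAML file on disk."""
    with open(path, encoding="utf-8") as fh:
        return loads_registry(fh.read())


def dump_registry(registry: MetricRegistry) -> str:
    """Serialise a registry back to the nested YAML document form."""
    doc: dict = {"transform_scale": registry.transform_scale, "domains": [], "separate_metrics": []}
    for d in registry.domains:
        dd = {"domain_id": d.domain_id, "label": d.label,
              "weight": registry.domain_weights[d.domain_id], "sub_domains": []}
        for s in registry.sub_domains:
            if s.domain_id != d.domain_id:
                continue
            sd = {"sub_domain_id": s.sub_domain_id, "label": s.label,
                  "weight": d.sub_domain_weights[s.sub_domain_id], "metrics": []}
            for m in registry.metrics_of(s.sub_domain_id):
                sd["metrics"].append({
                    "metric_id": m.metric_id, "label": m.label,
                    "numerator_field": m.numerator_field,
                    "denominator_field": m.denominator_field,
                    "polarity": m.polarity, "weight": s.metric_weights[m.metric_id],
                    "source_tag": m.source_tag, "is_proportion": m.is_proportion,
                })
            dd["sub_domains"].append(sd)
        doc["domains"].append(dd)
    for m in registry.separate_metrics:
        doc["separate_metrics"].append({
            "metric_id": m.metric_id, "label": m.label,
            "numerator_field": m.numerator_field, "denominator_field": m.denominator_field,
            "polarity": m.polarity, "source_tag": m.source_tag, "is_proportion": m.is_proportion,
        })
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


_DEFAULT_CACHE: MetricRegistry | None = None


def default_registry() -> MetricRegistry:
    """The shipped default hierarchy: 33 metrics (31 indexed + 2 separate),
    9 sub-domains, 4 domains, equal weights at every level."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = (
            importlib.resources.files("vulnmap") / "data" / "default_registry.yaml"
        ).read_text(encoding="utf-8")
        _DEFAULT_CACHE = loads_registry(text)
    return copy.deepcopy(_DEFAULT_CACHE)


def validate_registry(registry: MetricRegistry) -> list[str]:
    """Return a list of invariant violations (empty iff the registry is valid).

    Each violation names the offending entity and the rule it breaks.
    """
    v: list[str] = []
    sd_ids = {s.sub_domain_id for s in registry.sub_domains}
    d_ids = {d.domain_id for d in registry.domains}

    seen: set[str] = set()
    for m in registry.metrics + registry.separate_metrics:
        if m.metric_id in seen:
            v.append(f"metric {m.metric_id!r}: duplicate metric_id")
        seen.add(m.metric_id)
        if m.polarity not in (1, -1):
            v.append(f"metric {m.metric_id!r}: polarity must be +1 or -1")
        if m.numerator_field == m.denominator_field:
            v.append(f"metric {m.metric_id!r}: numerator equals denominator field")
    for m in registry.metrics:
        if m.sub_domain_id not in sd_ids:
            v.append(f"metric {m.metric_id!r}: unresolved sub_domain_id {m.sub_domain_id!r}")
    for m in registry.separate_metrics:
        if m.sub_domain_id is not None:
            v.append(f"separate metric {m.metric_id!r}: must not belong to a sub-domain")

    for s in registry.sub_domains:
        if s.domain_id not in d_ids:
            v.append(f"sub-domain {s.sub_domain_id!r}: unresolved domain_id {s.domain_id!r}")
        members = {m.metric_id for m in registry.metrics_of(s.sub_domain_id)}
        if not members:
            v.append(f"sub-domain {s.sub_domain_id!r}: has no metrics")
        if set(s.metric_weights) != members:
            v.append(f"sub-domain {s.sub_domain_id!r}: metric_weights keys do not match members")
        for mid, w in s.metric_weights.items():
            if w < 0:
                v.append(f"sub-domain {s.sub_domain_id!r}: negative weight for {mid!r}")
        if s.metric_weights and abs(sum(s.metric_weights.values()) - 1.0) > 1e-9:
            v.append(f"sub-domain {s.sub_domain_id!r}: weights do not sum to 1")

    for d in registry.domains:
        members = {s.sub_domain_id for s in registry.sub_domains if s.domain_id == d.domain_id}
        if not members:
            v.append(f"domain {d.domain_id!r}: has no sub-domains")
        if set(d.sub_domain_weights) != members:
            v.append(f"domain {d.domain_id!r}: sub_domain_weights keys do not match members")
        for sid, w in d.sub_domain_weights.items():
            if w < 0:
                v.append(f"domain {d.domain_id!r}: negative weight for {sid!r}")
        if d.sub_domain_weights and abs(sum(d.sub_domain_weights.values()) - 1.0) > 1e-9:
            v.append(f"domain {d.domain_id!r}: weights do not sum to 1")

    if set(registry.domain_weights) != d_ids:
        v.append("registry: domain_weights keys do not match domains")
    for did, w in registry.domain_weights.items():
        if w < 0:
            v.append(f"registry: negative domain weight for {did!r}")
    if registry.transform_scale <= 0:
        v.append("registry: transform_scale must be positive")
    return v
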