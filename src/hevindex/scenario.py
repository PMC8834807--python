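"""Scenario application and area-/network-based impact views.

A scenario couples a storyline's hazard levels (already normalized, possibly
zone-specific) with response overrides — e.g. a desirable storyline in which
adaptive-capacity deficits are eliminated and working systems are moved out
of flood-prone positions.  Applying a scenario never mutates the input
dataset.

Views:

* **facility** — one facility, full bottom-up evaluation;
* **area** — the equal-weighted mean of facility-level indicator values,
  the "(on average)" city perspective;
* **network** — host-only, units-average, and combined results for a
  hospital-led CUP (Contracting Unit of Primary Care) service network.

The hazard pillar is scenario-driven, not measure-driven: under the
conservative assumption that city-wide mitigation cannot be guaranteed,
trend and desirable storylines share identical hazard levels.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .catalog import IndicatorCatalog, PILLARS
from .scoring import (
    DomainError,
    ImpactResult,
    NoDataError,
    PillarScore,
    WeightScheme,
    aggregate_additive,
    class_severity,
    normalize_distance_to_target,
    score_pillar,
)
from .survey import FacilityRecord, SurveyDataset

logger = logging.getLogger(__name__)


class ScenarioError(ValueError):
    """A scenario or network specification does not validate."""


class PillarDataError(ValueError):
    """An entity has no data at all for one pillar subtree."""

    def __init__(self, pillar: str, entity: str = ""):
        self.pillar = pillar
        super().__init__(f"no data for pillar {pillar!r}"
                         + (f" of entity {entity!r}" if entity else ""))


_SELECTOR_KEYS = ("facility_id", "type", "zone", "cup_role")


@dataclass(frozen=True)
class Override:
    """One scenario measure: replace or scale responses on matching facilities.

    ``select`` addresses facilities by id, type, zone or CUP role (empty =
    all facilities); ``node`` is a sub-indicator or an indicator (expanded
    to all its sub-indicators).  Exactly one of ``value`` (replacement) or
    ``scale`` (multiplier in [0, 1], guaranteed non-increasing) is given.
    """

    node: str
    value: float | None = None
    scale: float | None = None
    select: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if (self.value is None) == (self.scale is None):
            raise ScenarioError(
                f"override on {self.node!r}: give exactly one of value/scale"
            )
        if self.value is not None and self.value < 0:
            raise ScenarioError(f"override value must be >= 0, got {self.value}")
        if self.scale is not None and not (0.0 <= self.scale <= 1.0):
            raise ScenarioError(f"override scale must be in [0, 1], got {self.scale}")
        unknown = set(self.select) - set(_SELECTOR_KEYS)
        if unknown:
            raise ScenarioError(f"unknown selector key(s) {sorted(unknown)}")

    def matches(self, record: FacilityRecord) -> bool:
        for key, wanted in self.select.items():
            actual = getattr(record, key)
            if key == "zone":
                actual = int(actual)
            options = wanted if isinstance(wanted, (list, tuple, set)) else (wanted,)
            if key == "zone":
                options = [int(o) for o in options]
            if actual not in options:
                return False
        return True


@dataclass(frozen=True)
class ScenarioSpec:
    """A named storyline: hazard levels plus response overrides.

    ``hazard_levels`` maps hazard sub-indicator ids to normalized hazard
    values; a value may be a plain number (all zones) or a mapping
    zone -> value.
    """

    name: str
    hazard_levels: Mapping[str, float | Mapping[int, float]] = field(default_factory=dict)
    overrides: tuple[Override, ...] = ()
    narrative: str = ""

    def hazard_level(self, sub_id: str, zone: int) -> float | None:
        level = self.hazard_levels.get(sub_id)
        if level is None:
            return None
        if isinstance(level, Mapping):
            value = level.get(int(zone))
            return None if value is None else float(value)
        return float(level)


@dataclass(frozen=True)
class NetworkSpec:
    """A service network: one host facility and its member units."""

    name: str
    host: str
    units: tuple[str, ...]

    def __post_init__(self):
        if self.host in self.units:
            raise ScenarioError(f"network {self.name!r}: host cannot also be a unit")


@dataclass(frozen=True)
class TargetBandwidth:
    """Acceptability bandwidth: acceptable class under trend, desirable target.

    The published bandwidth is acceptable = "low", desirable = "very_low".
    """

    acceptable: str = "low"
    desirable: str = "very_low"

    def __post_init__(self):
        if class_severity(self.desirable) > class_severity(self.acceptable):
            raise ScenarioError(
                "desirable class must not be more severe than acceptable class"
            )

    def status(self, klass: str) -> str:
        """'desirable', 'acceptable' or 'neither' for a result class."""
        sev = class_severity(klass)
        if sev <= class_severity(self.desirable):
            return "desirable"
        if sev <= class_severity(self.acceptable):
            return "acceptable"
        return "neither"


@dataclass(frozen=True)
class EngineConfig:
    """Per-pillar weighting schemes (indicator layer) and scale overrides."""

    weights: Mapping[str, WeightScheme] = field(default_factory=dict)
    scales: Mapping[str, float] = field(default_factory=dict)

    def weight_scheme(self, pillar: str) -> WeightScheme:
        return self.weights.get(pillar, WeightScheme.equal())

    def scale(self, pillar: str, catalog: IndicatorCatalog) -> float:
        return float(self.scales.get(pillar, catalog.scale(pillar)))


def validate_scenario(scenario: ScenarioSpec, catalog: IndicatorCatalog) -> None:
    """Raise :class:`ScenarioError` if the scenario references unknown nodes
    or carries negative hazard levels."""
    hazard_subs = set(catalog.sub_indicator_ids("hazard"))
    for sub_id, level in scenario.hazard_levels.items():
        if sub_id not in hazard_subs:
            raise ScenarioError(
                f"scenario {scenario.name!r}: hazard level for unknown "
                f"hazard sub-indicator {sub_id!r}"
            )
        values = level.values() if isinstance(level, Mapping) else [level]
        if any(v < 0 for v in values):
            raise ScenarioError(
                f"scenario {scenario.name!r}: hazard level for {sub_id!r} "
                "must be >= 0"
            )
    for ov in scenario.overrides:
        if ov.node not in catalog:
            raise ScenarioError(
                f"scenario {scenario.name!r}: override on unknown node {ov.node!r}"
            )


def _override_sub_ids(node_id: str, catalog: IndicatorCatalog) -> list[str]:
    node = catalog.node(node_id)
    if node.layer == "sub-indicator":
        return [node_id]
    if node.layer == "indicator":
        return [s.id for s in catalog.sub_indicators(node_id)]
    raise ScenarioError(f"override node {node_id!r} must be an indicator or sub-indicator")


def apply_scenario(dataset: SurveyDataset, scenario: ScenarioSpec) -> SurveyDataset:
    """Apply a scenario's overrides, returning a new dataset.

    The original dataset is untouched.  Every applied override is logged;
    a selector matching zero facilities is a warning, not an error.
    """
    validate_scenario(scenario, dataset.catalog)
    responses = {r.facility_id: dict(r.responses) for r in dataset.records}
    for ov in scenario.overrides:
        matched = [r for r in dataset.records if ov.matches(r)]
        if not matched:
            _warnings.warn(
                f"scenario {scenario.name!r}: override on {ov.node!r} "
                f"matched no facilities (select={dict(ov.select)})",
                stacklevel=2,
            )
            continue
        sub_ids = _override_sub_ids(ov.node, dataset.catalog)
        for rec in matched:
            for sid in sub_ids:
                current = responses[rec.facility_id].get(sid)
                if ov.value is not None:
                    new = float(ov.value)
                elif current is None:
                    continue
                else:
                    new = current * ov.scale
                responses[rec.facility_id][sid] = new
                logger.info(
                    "scenario %s: facility %s %s: %s -> %s",
                    scenario.name, rec.facility_id, sid, current, new,
                )
    new_records = [
        replace(r, responses=responses[r.facility_id]) for r in dataset.records
    ]
    return replace(
        dataset,
        records=tuple(new_records),
        provenance=dataset.provenance + f" | scenario {scenario.name!r} applied",
    )


# ---------------------------------------------------------------------------
# bottom-up evaluation
# ---------------------------------------------------------------------------

def facility_indicator_values(
    record: FacilityRecord,
    scenario: ScenarioSpec,
    catalog: IndicatorCatalog,
) -> dict[str, float | None]:
    """Indicator-layer values for one facility (flat map indicator id -> value).

    Hazard indicators are evaluated from the scenario's (zone-resolved)
    hazard levels; exposure and vulnerability indicators from the
    facility's distance-to-target-normalized responses, averaging
    equal-weighted over each indicator's present sub-indicators.
    """
    values: dict[str, float | None] = {}
    for pillar in PILLARS:
        for ind in catalog.indicators(pillar):
            subs = catalog.sub_indicators(ind.id)
            if pillar == "hazard":
                sub_vals = [scenario.hazard_level(s.id, record.zone) for s in subs]
            else:
                sub_vals = [
                    normalize_distance_to_target(record.responses.get(s.id), s.target)
                    for s in subs
                ]
            try:
                values[ind.id] = aggregate_additive(sub_vals)
            except NoDataError:
                values[ind.id] = None
    return values


def _result_from_indicator_values(
    values: Mapping[str, float | None],
    catalog: IndicatorCatalog,
    config: EngineConfig,
    entity: str,
    scenario_name: str,
    view: str,
) -> ImpactResult:
    pillar_scores = {}
    for pillar in PILLARS:
        ind_values = {n.id: values.get(n.id) for n in catalog.indicators(pillar)}
        try:
            pillar_scores[pillar] = score_pillar(
                ind_values,
                weights=config.weight_scheme(pillar),
                scale=config.scale(pillar, catalog),
                pillar=pillar,
            )
        except NoDataError:
            raise PillarDataError(pillar, entity) from None
    return ImpactResult(
        entity=entity,
        scenario=scenario_name,
        view=view,
        hazard=pillar_scores["hazard"],
        exposure=pillar_scores["exposure"],
        vulnerability=pillar_scores["vulnerability"],
    )


def facility_impact(
    record: FacilityRecord,
    scenario: ScenarioSpec,
    catalog: IndicatorCatalog,
    config: EngineConfig | None = None,
) -> ImpactResult:
    """Full bottom-up evaluation of one facility under a scenario."""
    config = config or EngineConfig()
    values = facility_indicator_values(record, scenario, catalog)
    return _result_from_indicator_values(
        values, catalog, config, record.facility_id, scenario.name, "facility"
    )


def dataset_indicator_values(
    dataset: SurveyDataset, scenario: ScenarioSpec
) -> dict[str, dict[str, float | None]]:
    """Per-facility indicator values for a whole (scenario-applied) dataset."""
    return {
        r.facility_id: facility_indicator_values(r, scenario, dataset.catalog)
        for r in dataset.records
    }


def _mean_indicator_values(
    per_facility: Sequence[Mapping[str, float | None]]
) -> dict[str, float | None]:
    if not per_facility:
        raise ScenarioError("no facilities to aggregate")
    keys = list(per_facility[0].keys())
    out: dict[str, float | None] = {}
    for k in keys:
        vals = [m.get(k) for m in per_facility]
        try:
            out[k] = aggregate_additive(vals)
        except NoDataError:
            out[k] = None
    return out


def area_view(
    values_by_facility: Mapping[str, Mapping[str, float | None]],
    catalog: IndicatorCatalog,
    config: EngineConfig | None = None,
    scenario_name: str = "",
    entity: str = "area",
) -> ImpactResult:
    """Area-based perspective: equal-weighted mean of facility indicator
    values per indicator, then pillar aggregation and the impact product."""
    config = config or EngineConfig()
    mean_values = _mean_indicator_values(list(values_by_facility.values()))
    return _result_from_indicator_values(
        mean_values, catalog, config, entity, scenario_name, "area"
    )


def network_view(
    values_by_facility: Mapping[str, Mapping[str, float | None]],
    network: NetworkSpec,
    catalog: IndicatorCatalog,
    config: EngineConfig | None = None,
    scenario_name: str = "",
) -> dict[str, ImpactResult]:
    """Network-based perspective for a CUP service network.

    Returns host-only (``network-host``), unit-average (``network-units``)
    and combined host+units (``network``) results, each facility entering
    the combined mean with equal weight.
    """
    config = config or EngineConfig()
    if network.host not in values_by_facility:
        raise ScenarioError(
            f"network {network.name!r}: host {network.host!r} has no data"
        )
    unit_values = [
        values_by_facility[u] for u in network.units if u in values_by_facility
    ]
    host_values = values_by_facility[network.host]
    results = {
        "network-host": _result_from_indicator_values(
            host_values, catalog, config, network.name, scenario_name, "network-host"
        )
    }
    if unit_values:
        results["network-units"] = _result_from_indicator_values(
            _mean_indicator_values(unit_values), catalog, config,
            network.name, scenario_name, "network-units",
        )
    # a host-only network degenerates to the host result
    results["network"] = _result_from_indicator_values(
        _mean_indicator_values([host_values] + unit_values), catalog, config,
        network.name, scenario_name, "network",
    )
    return results


def impact_from_pillars(
    h: float, e: float, v: float,
    entity: str = "", scenario_name: str = "", view: str = "",
) -> ImpactResult:
    """Build an :class:`ImpactResult` directly from three pillar values
    (used when pillar values are given, e.g. the published worked example)."""
    return ImpactResult(
        entity=entity,
        scenario=scenario_name,
        view=view,
        hazard=PillarScore("hazard", h),
        exposure=PillarScore("exposure", e),
        vulnerability=PillarScore("vulnerability", v),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Trend-vs-desirable comparison of two results for the same entity/view."""

    entity: str
    view: str
    scenario_a: str
    scenario_b: str
    pillar_deltas: Mapping[str, float]
    impact_delta: float
    transition: tuple[str, str]
    status_a: str
    status_b: str
    desirable_met: bool
    acceptable_met: bool

    def as_dict(self) -> dict:
        return {
            "entity": self.entity,
            "view": self.view,
            "scenarios": [self.scenario_a, self.scenario_b],
            "pillar_deltas": dict(self.pillar_deltas),
            "impact_delta": self.impact_delta,
            "transition": list(self.transition),
            "status": {self.scenario_a: self.status_a, self.scenario_b: self.status_b},
            "desirable_met": self.desirable_met,
            "acceptable_met": self.acceptable_met,
        }


def compare_scenarios(
    a: ImpactResult, b: ImpactResult, band: TargetBandwidth | None = None
) -> ComparisonReport:
    """Compare result ``b`` (e.g. desirable) against ``a`` (e.g. trend).

    Reports pillar deltas (b - a), the impact delta, the class transition,
    and each result's standing against the acceptability bandwidth.
    """
    band = band or TargetBandwidth()
    if a.view != b.view or a.entity != b.entity:
        raise ScenarioError(
            f"cannot compare {a.entity}/{a.view} with {b.entity}/{b.view}: "
            "entity and view must match"
        )
    deltas = {
        "hazard": b.hazard.value - a.hazard.value,
        "exposure": b.exposure.value - a.exposure.value,
        "vulnerability": b.vulnerability.value - a.vulnerability.value,
    }
    return ComparisonReport(
        entity=a.entity,
        view=a.view,
        scenario_a=a.scenario,
        scenario_b=b.scenario,
        pillar_deltas=deltas,
        impact_delta=b.impact - a.impact,
        transition=(a.klass, b.klass),
        status_a=band.status(a.klass),
        status_b=band.status(b.klass),
        desirable_met=band.status(b.klass) == "desirable",
        acceptable_met=band.status(b.klass) in ("desirable", "acceptable"),
    )


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read a scenario YAML file: ``{name, hazard_levels, overrides, narrative}``."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "name" not in doc:
        raise ScenarioError(f"{path}: scenario file must be a mapping with a 'name'")
    overrides = []
    for raw in doc.get("overrides") or []:
        overrides.append(
            Override(
                node=raw["node"],
                value=raw.get("value"),
                scale=raw.get("scale"),
                select=raw.get("select") or {},
            )
        )
    return ScenarioSpec(
        name=str(doc["name"]),
        hazard_levels=doc.get("hazard_levels") or {},
        overrides=tuple(overrides),
        narrative=str(doc.get("narrative", "")),
    )


def write_scenario(scenario: ScenarioSpec, path: str | Path) -> None:
    doc = {
        "name": scenario.name,
        "hazard_levels": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in scenario.hazard_levels.items()
        },
        "overrides": [
            {
                "node": ov.node,
                **({"value": ov.value} if ov.value is not None else {}),
                **({"scale": ov.scale} if ov.scale is not None else {}),
                **({"select": dict(ov.select)} if ov.select else {}),
            }
            for ov in scenario.overrides
        ],
        "narrative": scenario.narrative,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
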