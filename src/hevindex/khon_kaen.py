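"""The published Khon Kaen city worked example.

The study's indicator-level results for the trend and desirable scenarios,
in both the area-based and service-network views, ship here as a fixture so
the engine's algebra can be demonstrated and checked against the published
pillar and impact values.

Vulnerability (scale 1) and exposure (scale 2) pillar values are
recomputable from the indicator rows with equal weights.  The hazard pillar
values (0.827 area / 0.840 network) arise from an unpublished expert budget
allocation between floods and water scarcity and are therefore shipped as
fixture constants rather than recomputed; see ``docs/methods.md``.
"""

from __future__ import annotations

from .catalog import khon_kaen_catalog  # noqa: F401  (re-exported convenience)
from .scenario import EngineConfig, TargetBandwidth, impact_from_pillars
from .scoring import ImpactResult, WeightScheme, score_pillar

SCENARIOS = ("trend", "desirable")
VIEWS = ("area", "network")

#: exposure indicator values per (scenario, view) — display codes E1, E2
EXPOSURE_INDICATORS: dict[tuple[str, str], dict[str, float]] = {
    ("trend", "area"): {"E1": 1.040, "E2": 1.594},
    ("trend", "network"): {"E1": 1.017, "E2": 1.178},
    ("desirable", "area"): {"E1": 1.040, "E2": 0.263},
    ("desirable", "network"): {"E1": 1.017, "E2": 0.279},
}

#: hazard indicator values per (scenario, view) — display codes H1 (fluvial),
#: H2 (pluvial), H3 (water scarcity); identical across scenarios by the
#: conservative no-guaranteed-mitigation assumption
HAZARD_INDICATORS: dict[tuple[str, str], dict[str, float]] = {
    (scenario, "area"): {"H1": 0.588, "H2": 1.279, "H3": 1.442}
    for scenario in SCENARIOS
} | {
    (scenario, "network"): {"H1": 0.639, "H2": 1.279, "H3": 1.442}
    for scenario in SCENARIOS
}

#: published hazard pillar values (unpublished expert weighting; fixture constants)
HAZARD_PILLAR: dict[str, float] = {"area": 0.827, "network": 0.840}

#: vulnerability indicator values per (scenario, view), V1..V17
VULNERABILITY_INDICATORS: dict[tuple[str, str], dict[str, float]] = {
    ("trend", "area"): {
        "V1": 0.800, "V2": 0.683, "V3": 0.624, "V4": 0.064, "V5": 0.053,
        "V6": 0.456, "V7": 0.217, "V8": 0.416, "V9": 0.626, "V10": 0.359,
        "V11": 0.300, "V12": 0.388, "V13": 0.720, "V14": 0.742, "V15": 0.642,
        "V16": 0.440, "V17": 0.300,
    },
    ("trend", "network"): {
        "V1": 0.800, "V2": 0.778, "V3": 0.608, "V4": 0.033, "V5": 0.045,
        "V6": 0.480, "V7": 0.122, "V8": 0.397, "V9": 0.559, "V10": 0.535,
        "V11": 0.084, "V12": 0.424, "V13": 0.594, "V14": 0.808, "V15": 0.167,
        "V16": 0.487, "V17": 0.323,
    },
    ("desirable", "area"): {
        "V1": 0.480, "V2": 0.683, "V3": 0.440, "V4": 0.000, "V5": 0.053,
        "V6": 0.000, "V7": 0.047, "V8": 0.081, "V9": 0.000, "V10": 0.000,
        "V11": 0.000, "V12": 0.000, "V13": 0.000, "V14": 0.000, "V15": 0.000,
        "V16": 0.000, "V17": 0.000,
    },
    ("desirable", "network"): {
        "V1": 0.710, "V2": 0.778, "V3": 0.555, "V4": 0.000, "V5": 0.045,
        "V6": 0.000, "V7": 0.031, "V8": 0.097, "V9": 0.000, "V10": 0.000,
        "V11": 0.000, "V12": 0.000, "V13": 0.000, "V14": 0.000, "V15": 0.000,
        "V16": 0.000, "V17": 0.000,
    },
}

#: published pillar and impact values for cross-checking
PUBLISHED_PILLARS: dict[tuple[str, str], dict[str, float]] = {
    ("trend", "area"): {"H": 0.827, "E": 0.659, "V": 0.461, "impact": 0.251},
    ("trend", "network"): {"H": 0.840, "E": 0.549, "V": 0.426, "impact": 0.196},
    ("desirable", "area"): {"H": 0.827, "E": 0.326, "V": 0.105, "impact": 0.028},
    ("desirable", "network"): {"H": 0.840, "E": 0.324, "V": 0.130, "impact": 0.035},
}

#: the study's acceptability bandwidth: trend acceptable at "low",
#: desirable target "very_low"
BANDWIDTH = TargetBandwidth(acceptable="low", desirable="very_low")

EXPOSURE_SCALE = 2.0
VULNERABILITY_SCALE = 1.0


def assessment(
    scenario: str, view: str, weights: WeightScheme | None = None
) -> ImpactResult:
    """Recompute one column of the worked example from its indicator rows.

    Exposure and vulnerability pillars are aggregated with equal weights
    and their scale constants (2 and 1); the hazard pillar value is the
    shipped fixture constant.  The impact product and class are computed,
    never looked up.
    """
    key = (scenario, view)
    if key not in VULNERABILITY_INDICATORS:
        raise KeyError(f"unknown scenario/view {key}; scenarios {SCENARIOS}, views {VIEWS}")
    weights = weights or WeightScheme.equal()
    e = score_pillar(
        EXPOSURE_INDICATORS[key], weights=weights, scale=EXPOSURE_SCALE,
        pillar="exposure",
    )
    v = score_pillar(
        VULNERABILITY_INDICATORS[key], weights=weights, scale=VULNERABILITY_SCALE,
        pillar="vulnerability",
    )
    return impact_from_pillars(
        HAZARD_PILLAR[view], e.value, v.value,
        entity="khon-kaen", scenario_name=scenario, view=view,
    )


def full_assessment() -> dict[tuple[str, str], ImpactResult]:
    """All four scenario/view columns of the worked example."""
    return {
        (s, w): assessment(s, w) for s in SCENARIOS for w in VIEWS
    }
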