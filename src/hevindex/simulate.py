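"""Seeded synthetic facility surveys with the study's statistical structure.

The generator emulates the conditions of a medium-sized Thai city's public
health network survey:

* 36 facilities invited, ~69% response rate (25 completed returns by
  default); one tertiary CUP-host hospital, primary-care and SHPH
  (Sub-district Health Promotion Hospital) CUP units, and a few
  independently operated specialized facilities;
* zone-dependent hazard exposure (flood-prone eastern/southern zones 1-2,
  a dense inner-city zone 3, a safer zone 4), with water scarcity shared by
  all zones;
* three vulnerability blocks with contrasting internal structure: a
  *heterogeneous* sensitivity block and coping block (day-to-day operation
  data, low commonality) versus a *near-homogeneous* adaptive-capacity
  block (policy-checklist data on which most facilities report almost the
  same figures — high common-factor loading, low noise).

Each block follows a single-common-factor Gaussian model: item ``j`` of
facility ``i`` is ``target * (mu + sd * (lambda * f_i + sqrt(1 - lambda^2)
* e_ij))`` truncated at zero, so the population inter-item correlation
within a block is ``lambda^2`` and block Cronbach alphas are tunable.  The
ground truth (factors, loadings, implied correlations) is returned for
parameter-recovery tests.

All randomness flows from one root seed through a single generator; no
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .catalog import IndicatorCatalog, khon_kaen_catalog
from .scenario import NetworkSpec, Override, ScenarioSpec
from .survey import FacilityRecord, SurveyDataset

DEFAULT_N_FACILITIES = 36
DEFAULT_RESPONSE_RATE = 25.0 / 36.0


class ProfileError(ValueError):
    """A generator profile fails validation."""


@dataclass(frozen=True)
class BlockModel:
    """Single-common-factor model for one vulnerability component block.

    ``loading`` is the common-factor loading lambda (population inter-item
    correlation = lambda^2); ``mean_frac`` and ``sd_frac`` position the raw
    responses as fractions of each sub-indicator's target.
    """

    loading: float
    mean_frac: float
    sd_frac: float

    def __post_init__(self):
        if not (0.0 <= self.loading < 1.0):
            raise ProfileError(f"loading must be in [0, 1), got {self.loading}")
        if self.sd_frac <= 0 or self.mean_frac < 0:
            raise ProfileError("mean_frac must be >= 0 and sd_frac > 0")

    @property
    def target_correlation(self) -> float:
        return self.loading**2


def _default_blocks() -> dict[str, BlockModel]:
    # adaptive: policy checklists, near-identical across facilities;
    # sensitivity/coping: heterogeneous operational data
    return {
        "sensitivity": BlockModel(loading=0.20, mean_frac=0.50, sd_frac=0.20),
        "coping": BlockModel(loading=0.45, mean_frac=0.45, sd_frac=0.20),
        "adaptive": BlockModel(loading=0.95, mean_frac=0.55, sd_frac=0.10),
    }


def _default_hazard_levels() -> dict[str, float | dict[int, float]]:
    # zones 1-2 fluvial-flood prone, zone 3 pluvial + isolation, zone 4 low
    # flood exposure; water scarcity is a city-wide underlying threat
    return {
        "H1.1": {1: 1.20, 2: 1.00, 3: 0.45, 4: 0.15},
        "H1.2": 1.279,
        "H2.0": 1.442,
    }


@dataclass(frozen=True)
class GeneratorProfile:
    """All knobs of the synthetic survey generator (defaults = study
    conditions: 36 facilities, 25/36 response rate, one CUP host)."""

    n_facilities: int = DEFAULT_N_FACILITIES
    response_rate: float = DEFAULT_RESPONSE_RATE
    zone_probs: tuple[float, float, float, float] = (0.20, 0.20, 0.35, 0.25)
    n_primary: int = 5
    n_specialized: int = 3
    blocks: Mapping[str, BlockModel] = field(default_factory=_default_blocks)
    hazard_levels: Mapping[str, float | Mapping[int, float]] = field(
        default_factory=_default_hazard_levels
    )
    #: multiplier on exposure responses per zone (flood zones more exposed)
    exposure_zone_mult: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.5, 2: 1.3, 3: 1.1, 4: 0.5}
    )
    network_name: str = "CUP"
    seed: int = 42

    def __post_init__(self):
        if self.n_facilities < 4:
            raise ProfileError("need at least 4 facilities")
        if not (0.0 < self.response_rate <= 1.0):
            raise ProfileError(
                f"response_rate must be in (0, 1], got {self.response_rate}"
            )
        if abs(sum(self.zone_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.zone_probs):
            raise ProfileError("zone_probs must be a distribution over zones 1-4")
        if self.n_primary + self.n_specialized + 1 > self.n_facilities:
            raise ProfileError("facility type counts exceed n_facilities")
        for name in ("sensitivity", "coping", "adaptive"):
            if name not in self.blocks:
                raise ProfileError(f"missing block model {name!r}")

    @property
    def n_responding(self) -> int:
        return int(round(self.n_facilities * self.response_rate))


def _roles_and_types(profile: GeneratorProfile) -> list[tuple[str, str]]:
    """(type, cup_role) per facility: 1 tertiary host, specialized external,
    the rest primary/SHPH CUP units."""
    out = [("tertiary", "host")]
    out += [("specialized", "external")] * profile.n_specialized
    out += [("primary", "unit")] * profile.n_primary
    n_shph = profile.n_facilities - len(out)
    out += [("SHPH", "unit")] * n_shph
    return out


def generate_survey(
    profile: GeneratorProfile | None = None,
    catalog: IndicatorCatalog | None = None,
) -> tuple[SurveyDataset, dict]:
    """Generate a seeded synthetic survey dataset plus its ground truth.

    Returns ``round(n_facilities * response_rate)`` facility records with
    catalog-complete responses; the CUP host always responds (as in the
    study).  The ground-truth dict carries the latent block factors and the
    implied inter-item correlation per block for recovery tests.  The same
    profile (same seed) yields bit-identical output.
    """
    profile = profile or GeneratorProfile()
    catalog = catalog or khon_kaen_catalog()
    rng = np.random.default_rng(profile.seed)

    roles = _roles_and_types(profile)
    n = profile.n_facilities
    zones = rng.choice([1, 2, 3, 4], size=n, p=list(profile.zone_probs))
    # the tertiary host sits in the dense inner city
    zones[0] = 3

    sub_nodes = {s.id: s for s in catalog.sub_indicators()}
    vuln_subs_by_block = {
        comp: [s for s in catalog.sub_indicators() if s.component == comp]
        for comp in ("sensitivity", "coping", "adaptive")
    }
    exposure_subs = [s for s in catalog.sub_indicators() if s.pillar == "exposure"]

    factors = {
        comp: rng.standard_normal(n) for comp in ("sensitivity", "coping", "adaptive")
    }
    responses_all: list[dict[str, float]] = [dict() for _ in range(n)]

    for comp, subs in vuln_subs_by_block.items():
        model = profile.blocks[comp]
        lam = model.loading
        uniq = math.sqrt(1.0 - lam**2)
        noise = rng.standard_normal((n, len(subs)))
        z = lam * factors[comp][:, None] + uniq * noise
        for j, sub in enumerate(subs):
            raw = sub.target * (model.mean_frac + model.sd_frac * z[:, j])
            raw = np.clip(raw, 0.0, None)
            for i in range(n):
                responses_all[i][sub.id] = float(raw[i])

    # exposure: zone-driven, facility-level noise shared across a facility's
    # building items so building and working-system exposure co-vary
    fac_noise = rng.standard_normal(n)
    for sub in exposure_subs:
        item_noise = rng.standard_normal(n)
        for i in range(n):
            mult = profile.exposure_zone_mult.get(int(zones[i]), 1.0)
            raw = sub.target * mult * (
                0.7 + 0.2 * fac_noise[i] + 0.15 * item_noise[i]
            )
            responses_all[i][sub.id] = float(max(raw, 0.0))

    records = []
    for i, (ftype, role) in enumerate(roles):
        records.append(
            FacilityRecord(
                facility_id=f"F{i + 1:02d}",
                name=f"Facility {i + 1:02d} ({ftype})",
                type=ftype,
                cup_role=role,
                zone=int(zones[i]),
                responses=responses_all[i],
                network=profile.network_name if role in ("host", "unit") else "",
            )
        )

    # response sampling: the host always returns its questionnaire
    n_resp = profile.n_responding
    others = rng.permutation(np.arange(1, n))[: n_resp - 1]
    chosen = sorted([0] + [int(i) for i in others])
    responding = [records[i] for i in chosen]

    dataset = SurveyDataset(
        records=tuple(responding),
        catalog=catalog,
        provenance=f"synthetic survey (seed={profile.seed})",
    )
    network = NetworkSpec(
        name=profile.network_name,
        host=records[0].facility_id,
        units=tuple(r.facility_id for r in responding if r.cup_role == "unit"),
    )
    ground_truth = {
        "factors": factors,
        "zones": zones.copy(),
        "block_correlations": {
            comp: profile.blocks[comp].target_correlation
            for comp in ("sensitivity", "coping", "adaptive")
        },
        "responding_ids": [r.facility_id for r in responding],
        "network": network,
    }
    return dataset, ground_truth


def generate_scenario_pair(
    profile: GeneratorProfile | None = None,
    catalog: IndicatorCatalog | None = None,
) -> tuple[ScenarioSpec, ScenarioSpec]:
    """Trend and desirable scenario specifications for a generated survey.

    Both share identical hazard levels (city-wide mitigation cannot be
    guaranteed).  The desirable storyline zeroes the flexibility deficit
    (V6) and the responsiveness-through-monitoring deficits (V9-V17) for
    every facility, and scales working-system exposure (E2) down to a
    quarter for facilities in the flood-affected zones 1-3 (resilient
    upgrading and retreat).  All overrides are non-increasing, so facility
    impact under the desirable scenario never exceeds the trend impact.
    """
    profile = profile or GeneratorProfile()
    catalog = catalog or khon_kaen_catalog()
    hazard = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in profile.hazard_levels.items()
    }
    trend = ScenarioSpec(
        name="trend",
        hazard_levels=hazard,
        narrative="business-as-usual urbanization; no guaranteed mitigation",
    )
    zeroed = ["V6"] + [f"V{i}" for i in range(9, 18)]
    overrides = tuple(
        Override(node=node, value=0.0) for node in zeroed
    ) + (
        Override(node="E2", scale=0.25, select={"zone": [1, 2, 3]}),
    )
    desirable = ScenarioSpec(
        name="desirable",
        hazard_levels=hazard,
        overrides=overrides,
        narrative=(
            "capacity deficits eliminated sector-wide; working systems "
            "relocated out of flood-prone positions"
        ),
    )
    return trend, desirable
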