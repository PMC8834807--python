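"""Normalization, weighting, aggregation and impact classification.

The core algebra of the index:

* **sub-indicator layer** — distance-to-target normalization (``value /
  target``, deliberately *uncapped*: an indicator can exceed its target) and
  equal-weighted additive aggregation up to its indicator;
* **indicator layer** — proportionately-normalized weights (equal, budget
  allocation, or ascending-order ranks) and additive aggregation up to the
  pillar, divided by a per-pillar scale constant;
* **pillar layer** — multiplicative, non-compensable aggregation::

      potential impact = Hazard x Exposure x Vulnerability

  A zero in any pillar annihilates the impact; no other pillar can
  compensate.

Impact scores on [0, 1] fall into four classes whose boundaries are the
cubes of the quarter-points of a unit pillar scale: very low (0-0.016),
low (>0.016-0.125), medium (>0.125-0.422), high (>0.422-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "NoDataError",
    "WeightScheme",
    "PillarScore",
    "ImpactResult",
    "IMPACT_CLASSES",
    "CLASS_THRESHOLDS",
    "normalize_distance_to_target",
    "proportionate_weights",
    "rank_order_weights",
    "aggregate_additive",
    "score_pillar",
    "potential_impact",
    "classify_impact",
    "class_severity",
    "round_display",
]


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class NoDataError(ValueError):
    """Every value feeding an aggregation is missing."""


#: impact classes in increasing severity
IMPACT_CLASSES = ("very_low", "low", "medium", "high")

#: right-closed upper boundaries of very_low / low / medium
CLASS_THRESHOLDS = (0.016, 0.125, 0.422)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def normalize_distance_to_target(value: float | None, target: float) -> float | None:
    """Express ``value`` as a fraction of its reference ``target``.

    The ratio is *not* capped at 1: raw values beyond the target yield
    normalized scores above 1, preserving proportionality and trackability.
    A missing value stays missing (``None``) and is handled downstream by
    the missing-data rule of :func:`aggregate_additive`.
    """
    if not (target > 0):
        raise DomainError(f"target must be > 0, got {target}")
    if _is_missing(value):
        return None
    if value < 0:
        raise DomainError(f"raw value must be >= 0, got {value}")
    return float(value) / float(target)


def proportionate_weights(weights: Sequence[float]) -> np.ndarray:
    """Divide each weight by the sibling sum so the shares total 1."""
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0:
        raise DomainError("empty weight vector")
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DomainError("weight vector sums to zero")
    return w / total


def rank_order_weights(ranks: Sequence[int]) -> np.ndarray:
    """Convert ascending priority ranks (1 = highest) to rank-sum weights.

    Item with rank :math:`r_i` among :math:`n` items receives weight
    :math:`(n - r_i + 1) / \\sum_j (n - r_j + 1)`.
    """
    r = np.asarray(list(ranks), dtype=float)
    n = r.size
    if n == 0 or sorted(r.tolist()) != list(range(1, n + 1)):
        raise DomainError(f"ranks must be a permutation of 1..{n}, got {list(ranks)}")
    raw = n - r + 1
    return raw / raw.sum()


@dataclass(frozen=True)
class WeightScheme:
    """A sibling weighting rule: equal, budget allocation, or rank order.

    * ``equal`` — every sibling gets the same weight (the fallback when no
      expert scheme is available).
    * ``budget`` — experts distribute a fixed budget of points; the
      allocation shares become the weights.
    * ``rank`` — experts rank the siblings in ascending priority order
      (1 = most important); ranks become rank-sum weights.
    """

    kind: str = "equal"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("equal", "budget", "rank"):
            raise DomainError(f"unknown weight scheme kind {self.kind!r}")
        if self.kind == "budget":
            alloc = np.asarray(list(self.params.values()), dtype=float)
            if alloc.size == 0 or np.any(alloc < 0) or alloc.sum() <= 0:
                raise DomainError("budget allocations must be >= 0 with positive sum")
        if self.kind == "rank":
            ranks = list(self.params.values())
            if sorted(ranks) != list(range(1, len(ranks) + 1)):
                raise DomainError("ranks must be a permutation of 1..n")

    @classmethod
    def equal(cls) -> "WeightScheme":
        return cls("equal")

    @classmethod
    def budget(cls, allocations: Mapping[str, float]) -> "WeightScheme":
        return cls("budget", dict(allocations))

    @classmethod
    def rank(cls, ranks: Mapping[str, int]) -> "WeightScheme":
        return cls("rank", {k: int(v) for k, v in ranks.items()})

    def raw_weights(self, ids: Sequence[str]) -> np.ndarray:
        """Unnormalized weight per id; normalization happens at aggregation
        time so missing siblings renormalize correctly."""
        if self.kind == "equal":
            return np.ones(len(ids))
        if self.kind == "budget":
            missing = [i for i in ids if i not in self.params]
            if missing:
                raise DomainError(f"budget scheme lacks allocation for {missing}")
            return np.asarray([self.params[i] for i in ids], dtype=float)
        # rank: rank-sum over the scheme's full rank set
        missing = [i for i in ids if i not in self.params]
        if missing:
            raise DomainError(f"rank scheme lacks rank for {missing}")
        n = len(self.params)
        return np.asarray([n - self.params[i] + 1 for i in ids], dtype=float)


def aggregate_additive(
    values: Sequence[float | None] | Mapping[str, float | None],
    weights: Sequence[float] | WeightScheme | None = None,
) -> float:
    """Weighted additive aggregation with the missing-data rule.

    Missing entries (``None``/NaN) are excluded and the weights are
    proportionately renormalized over the present siblings — absence means
    "unknown", which is different from a zero ("no deficit").  Under equal
    weights this is the arithmetic mean of the present values.
    """
    if isinstance(values, Mapping):
        ids = list(values.keys())
        vals = [values[i] for i in ids]
    else:
        vals = list(values)
        ids = [str(i) for i in range(len(vals))]
    if isinstance(weights, WeightScheme):
        w = weights.raw_weights(ids)
    elif weights is None:
        w = np.ones(len(vals))
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.size != len(vals):
            raise DomainError("weights and values differ in length")
    present = [(v, wi) for v, wi in zip(vals, w) if not _is_missing(v)]
    if not present:
        raise NoDataError("no data for node: all sibling values missing")
    pv = np.asarray([p[0] for p in present], dtype=float)
    pw = proportionate_weights([p[1] for p in present])
    return float(pv @ pw)


@dataclass(frozen=True)
class PillarScore:
    """An aggregated pillar value plus its audit trail.

    ``value`` equals the weighted additive aggregate of ``contributions``
    divided by ``scale`` and is recomputable from them.
    """

    pillar: str
    value: float
    contributions: Mapping[str, float | None] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self):
        if self.value < 0:
            raise DomainError(f"pillar score must be >= 0, got {self.value}")


def score_pillar(
    indicator_values: Mapping[str, float | None],
    weights: WeightScheme | Sequence[float] | None = None,
    scale: float = 1.0,
    pillar: str = "",
) -> PillarScore:
    """Aggregate indicator values into one pillar score.

    The additive aggregate is divided by ``scale``, the pillar's range
    constant (vulnerability 1, exposure 2 in the shipped configuration;
    hazard is configurable).
    """
    if not (scale > 0):
        raise DomainError(f"pillar scale must be > 0, got {scale}")
    value = aggregate_additive(indicator_values, weights) / scale
    return PillarScore(pillar=pillar, value=value,
                       contributions=dict(indicator_values), scale=scale)


def potential_impact(h: float, e: float, v: float) -> float:
    """Non-compensable product Hazard x Exposure x Vulnerability.

    Zero iff any factor is zero: the absence of one pillar means no
    potential impact regardless of the others.
    """
    for name, x in (("hazard", h), ("exposure", e), ("vulnerability", v)):
        if _is_missing(x) or x < 0:
            raise DomainError(f"{name} score must be a number >= 0, got {x}")
    return float(h) * float(e) * float(v)


def classify_impact(impact: float) -> str:
    """Map an impact score on [0, 1] to its class.

    Intervals are closed on the right: very low [0, 0.016], low
    (0.016, 0.125], medium (0.125, 0.422], high (0.422, 1].  The unrounded
    score is classified; display rounding never feeds back.
    """
    if _is_missing(impact) or not (0.0 <= impact <= 1.0):
        raise DomainError(f"impact must be within [0, 1], got {impact}")
    for klass, upper in zip(IMPACT_CLASSES, CLASS_THRESHOLDS):
        if impact <= upper:
            return klass
    return IMPACT_CLASSES[-1]


def class_severity(klass: str) -> int:
    """Position of a class in the severity order very_low < low < medium < high."""
    try:
        return IMPACT_CLASSES.index(klass)
    except ValueError:
        raise DomainError(f"unknown impact class {klass!r}") from None


@dataclass(frozen=True)
class ImpactResult:
    """Pillar scores, potential impact and class for one assessed entity."""

    entity: str
    scenario: str
    view: str
    hazard: PillarScore
    exposure: PillarScore
    vulnerability: PillarScore
    impact: float = field(init=False)
    klass: str = field(init=False)

    def __post_init__(self):
        impact = potential_impact(
            self.hazard.value, self.exposure.value, self.vulnerability.value
        )
        object.__setattr__(self, "impact", impact)
        object.__setattr__(self, "klass", classify_impact(impact))

    def as_dict(self) -> dict:
        return {
            "entity": self.entity,
            "scenario": self.scenario,
            "view": self.view,
            "H": self.hazard.value,
            "E": self.exposure.value,
            "V": self.vulnerability.value,
            "impact": self.impact,
            "class": self.klass,
        }


def round_display(value: float, ndigits: int = 3) -> float:
    """Half-up decimal rounding for display (matching 3-decimal reporting).

    Computation always uses unrounded values; this is presentation only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
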